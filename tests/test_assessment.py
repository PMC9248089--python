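"""Model assessment: prevalence diagnostics, Pearson-type GOF and the
likelihood-ratio test."""

import numpy as np
import pandas as pd
import pytest

from cogfrail import (
    FIVE_STATE,
    FIVE_STATE_FREE_NSCF,
    PanelDataset,
    SimulationConfig,
    expected_prevalence,
    fit_panel_markov,
    likelihood_ratio_test,
    pearson_type_gof,
    simulate_cohort,
)
from cogfrail.assessment import _gof_statistic, plot_prevalence
from cogfrail.ctmc import FitResult
from cogfrail.reference import REFERENCE_INTENSITIES
from cogfrail.states import StateSpace

TWO_STATE = StateSpace({1: "Alive", 2: "Dead"}, ((1, 2),), frozenset({2}))


@pytest.fixture(scope="module")
def fitted(sim_panel):
    return fit_panel_markov(sim_panel, compute_cov=False)


def test_expected_prevalence_matches_baseline_at_t0(fitted, sim_panel):
    prev = expected_prevalence(fitted, sim_panel, [0.0, 2.0, 4.0])
    assert np.allclose(prev.expected.loc[0.0], prev.observed.loc[0.0], atol=1e-12)


def test_prevalence_rows_sum_to_one(fitted, sim_panel):
    prev = expected_prevalence(fitted, sim_panel, [0.0, 1.0, 2.0, 4.0])
    assert np.allclose(prev.expected.sum(axis=1), 1.0, atol=1e-8)
    # observed fractions exist only at visited times
    obs = prev.observed.loc[[0.0, 2.0, 4.0]]
    assert np.allclose(obs.sum(axis=1), 1.0, atol=1e-8)


def test_observed_tracks_expected_on_model_true_data(fitted, sim_panel):
    """Data simulated from (nearly) the fitted model: observed and
    expected prevalence agree within binomial error at every wave."""
    prev = expected_prevalence(fitted, sim_panel, [0.0, 2.0, 4.0])
    n = sim_panel.n_subjects
    for t in (2.0, 4.0):
        for s in prev.expected.columns:
            p = prev.expected.loc[t, s]
            se = np.sqrt(max(p * (1 - p), 1e-10) / n)
            assert abs(prev.observed.loc[t, s] - p) < max(4 * se, 0.01)


def test_death_prevalence_absorbs_everything():
    rates = {(1, 2): 0.0001, (1, 3): 0.0001, (1, 5): 0.5}
    fit = FitResult.from_rates({**{t: 0.0 for t in FIVE_STATE.allowed}, **rates})
    df = pd.DataFrame(
        {"subject_id": range(1, 51), "time_years": 0.0, "state": 1}
    )
    data = PanelDataset(df)
    prev = expected_prevalence(fit, data, [0.0, 100.0])
    assert prev.expected.loc[100.0, "Death"] == pytest.approx(1.0, abs=1e-3)


def test_empty_cohort_rejected(fitted):
    with pytest.raises(Exception):
        expected_prevalence(
            fitted,
            PanelDataset(pd.DataFrame(columns=["subject_id", "time_years", "state"])),
            [0.0],
        )


def test_plot_prevalence_writes_file(fitted, sim_panel, tmp_path):
    prev = expected_prevalence(fitted, sim_panel, [0.0, 2.0, 4.0])
    out = tmp_path / "prev.png"
    plot_prevalence(prev, out)
    assert out.stat().st_size > 0


# ----------------------------------------------------------------------
# Pearson-type GOF
# ----------------------------------------------------------------------


def test_gof_statistic_zero_when_observed_equals_expected():
    """A static cohort under a zero-rate generator: expected counts are
    exactly the observed counts, so the statistic is 0."""
    rows = [(sid, t, 1) for sid in range(1, 31) for t in (0.0, 2.0, 4.0)]
    data = PanelDataset(pd.DataFrame(rows, columns=["subject_id", "time_years", "state"]))
    fit = FitResult.from_rates({t: 0.0 for t in FIVE_STATE.allowed})
    stat, _ = _gof_statistic(fit, data)
    assert stat == pytest.approx(0.0, abs=1e-12)


def test_gof_statistic_hand_computed():
    """Two-state cohort against fixed rates: statistic equals the
    hand-computed Pearson sum."""
    rows = []
    for sid in range(1, 11):
        rows.append((sid, 0.0, 1))
        rows.append((sid, 1.0, 1 if sid <= 7 else 2))
    data = PanelDataset(
        pd.DataFrame(rows, columns=["subject_id", "time_years", "state"]), space=TWO_STATE
    )
    lam = 0.3
    fit = FitResult.from_rates({(1, 2): lam}, TWO_STATE)
    p_stay = np.exp(-lam)
    e_alive, e_dead = 10 * p_stay, 10 * (1 - p_stay)
    expected = (7 - e_alive) ** 2 / e_alive + (3 - e_dead) ** 2 / e_dead
    stat, table = _gof_statistic(fit, data)
    assert stat == pytest.approx(expected, rel=1e-12)
    assert len(table) == 2


def test_gof_calibrated_p_on_model_true_data():
    """Model-true data should not be rejected (a smoke-scale check of
    the bootstrap calibration; the full calibration run lives in the
    acceptance suite)."""
    panel = simulate_cohort(SimulationConfig(n_subjects=800, seed=31))
    fit = fit_panel_markov(panel, compute_cov=False)
    gof = pearson_type_gof(fit, panel, n_boot=30, seed=31)
    assert gof.p_value > 0.05
    assert gof.statistic >= 0


def test_gof_rejects_grossly_wrong_model():
    panel = simulate_cohort(SimulationConfig(n_subjects=2000, seed=32))
    wrong = {t: v * 4.0 for t, v in REFERENCE_INTENSITIES.items()}
    fit = FitResult.from_rates(wrong)
    stat_wrong, _ = _gof_statistic(fit, panel)
    good = fit_panel_markov(panel, compute_cov=False)
    stat_good, _ = _gof_statistic(good, panel)
    assert stat_wrong > 10 * stat_good


# ----------------------------------------------------------------------
# likelihood ratio test
# ----------------------------------------------------------------------


def test_lrt_identical_models(sim_panel):
    a = fit_panel_markov(sim_panel, compute_cov=False)
    b = fit_panel_markov(sim_panel, compute_cov=False)
    res = likelihood_ratio_test(a, b)
    assert res.G == pytest.approx(0.0, abs=1e-6)
    assert res.df == 0
    assert res.p_value == 1.0


def test_lrt_freed_nscf_has_df_two(sim_panel):
    restricted = fit_panel_markov(sim_panel, FIVE_STATE, compute_cov=False)
    free = fit_panel_markov(sim_panel, FIVE_STATE_FREE_NSCF, compute_cov=False)
    res = likelihood_ratio_test(free, restricted)
    assert res.df == 2
    assert res.G >= 0.0
    assert 0.0 <= res.p_value <= 1.0


def test_lrt_non_nested_rejected(sim_panel):
    restricted = fit_panel_markov(sim_panel, FIVE_STATE, compute_cov=False)
    free = fit_panel_markov(sim_panel, FIVE_STATE_FREE_NSCF, compute_cov=False)
    with pytest.raises(ValueError, match="nested"):
        likelihood_ratio_test(restricted, free)
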