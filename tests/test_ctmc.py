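"""Generator construction, transition probabilities, sojourn times,
panel likelihood and maximum-likelihood fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cogfrail import (
    FIVE_STATE,
    PanelDataset,
    StateSpace,
    StructuralZeroError,
    build_intensity_matrix,
    fit_panel_markov,
    mean_sojourn_times,
    panel_loglik,
    transition_probability,
)
from cogfrail.panel import PanelDataError
from cogfrail.reference import REFERENCE_INTENSITIES

from conftest import series_expm

TWO_STATE = StateSpace({1: "Alive", 2: "Dead"}, ((1, 2),), frozenset({2}))


# ----------------------------------------------------------------------
# generator
# ----------------------------------------------------------------------


def test_reference_generator_diagonal(reference_Q):
    assert reference_Q[0, 0] == pytest.approx(-(0.036 + 0.374 + 0.008))
    assert np.allclose(reference_Q.sum(axis=1), 0.0, atol=1e-12)
    assert np.all(reference_Q[4] == 0.0)
    # structural zeros
    for r, s in [(1, 4), (4, 1), (2, 3), (3, 2)]:
        assert reference_Q[r - 1, s - 1] == 0.0


def test_empty_rate_map_gives_zero_generator():
    assert np.all(build_intensity_matrix({}) == 0.0)


def test_forbidden_transition_rejected():
    with pytest.raises(StructuralZeroError):
        build_intensity_matrix({(1, 4): 0.1})
    with pytest.raises(ValueError):
        build_intensity_matrix({(1, 2): -0.1})


# ----------------------------------------------------------------------
# transition probabilities
# ----------------------------------------------------------------------


def test_zero_interval_is_identity(reference_Q):
    assert np.allclose(transition_probability(reference_Q, 0.0), np.eye(5))


def test_negative_interval_rejected(reference_Q):
    with pytest.raises(ValueError):
        transition_probability(reference_Q, -1.0)


def test_two_state_closed_form():
    Q = build_intensity_matrix({(1, 2): 0.5}, TWO_STATE)
    P = transition_probability(Q, 1.0)
    assert P[0, 0] == pytest.approx(np.exp(-0.5), abs=1e-12)


def test_matches_series_oracle():
    rng = np.random.default_rng(3)
    for _ in range(10):
        rates = {t: rng.uniform(0, 1.5) for t in FIVE_STATE.allowed}
        Q = build_intensity_matrix(rates)
        P = transition_probability(Q, 1.0)
        assert np.max(np.abs(P - series_expm(Q, 1.0))) < 1e-10
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)


_rates_strategy = st.lists(
    st.floats(0.0, 2.0, allow_nan=False), min_size=12, max_size=12
).map(lambda v: dict(zip(FIVE_STATE.allowed, v)))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(rates=_rates_strategy, u=st.floats(0.05, 5.0), v=st.floats(0.05, 5.0))
def test_chapman_kolmogorov(rates, u, v):
    Q = build_intensity_matrix(rates)
    P_uv = transition_probability(Q, u + v)
    assert np.max(
        np.abs(P_uv - transition_probability(Q, u) @ transition_probability(Q, v))
    ) < 1e-8


@settings(max_examples=25, deadline=None, derandomize=True)
@given(rates=_rates_strategy)
def test_row_stochastic_and_death_monotone(rates):
    Q = build_intensity_matrix(rates)
    prev_death = np.zeros(5)
    for u in (0.1, 1.0, 10.0):
        P = transition_probability(Q, u)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(P >= -1e-12) and np.all(P <= 1 + 1e-12)
        assert np.all(P[:, 4] >= prev_death - 1e-9)
        prev_death = P[:, 4]


# ----------------------------------------------------------------------
# sojourn times
# ----------------------------------------------------------------------


def test_reference_sojourn_times(reference_Q):
    soj = mean_sojourn_times(reference_Q)
    assert round(soj["NS"], 2) == 2.39
    assert round(soj["CI"], 2) == 0.94  # 1/(0.300+0.756+0.005)


def test_single_exit_sojourn():
    Q = build_intensity_matrix({(1, 2): 0.5}, TWO_STATE)
    assert mean_sojourn_times(Q, TWO_STATE)["Alive"] == pytest.approx(2.0)


def test_zero_exit_reports_infinite_sojourn():
    Q = build_intensity_matrix({}, TWO_STATE)
    assert mean_sojourn_times(Q, TWO_STATE)["Alive"] == np.inf


# ----------------------------------------------------------------------
# panel likelihood
# ----------------------------------------------------------------------


def _panel(rows, space=FIVE_STATE):
    return PanelDataset(
        pd.DataFrame(rows, columns=["subject_id", "time_years", "state"]), space=space
    )


def test_single_pair_loglik(reference_Q):
    data = _panel([(1, 0.0, 1), (1, 1.0, 1)])
    ll = panel_loglik(reference_Q, data)
    assert ll == pytest.approx(float(np.log(series_expm(reference_Q, 1.0)[0, 0])), abs=1e-10)
    assert ll == pytest.approx(np.log(0.702), abs=0.01)


def test_single_observation_contributes_zero(reference_Q):
    assert panel_loglik(reference_Q, _panel([(1, 0.0, 1)])) == 0.0


def test_loglik_maximal_at_truth(reference_Q, sim_panel):
    ll_true = panel_loglik(reference_Q, sim_panel)
    for t in [(1, 3), (2, 4), (4, 3)]:
        worse = dict(REFERENCE_INTENSITIES)
        worse[t] *= 1.5
        assert panel_loglik(build_intensity_matrix(worse), sim_panel) < ll_true


def test_duplicate_observation_times_rejected():
    with pytest.raises(PanelDataError):
        _panel([(1, 0.0, 1), (1, 0.0, 2)])


def test_exact_death_convention_uses_density(reference_Q):
    """Under the exact-time convention a death pair contributes
    sum_r P_{s,r}(dt) q_{r,death}, a density, not the interval
    probability."""
    data = _panel([(1, 0.0, 1), (1, 1.0, 5)])
    ll_interval = panel_loglik(reference_Q, data, death_convention="interval")
    P = series_expm(reference_Q, 1.0)
    assert ll_interval == pytest.approx(float(np.log(P[0, 4])), abs=1e-10)
    dens = float(P[0] @ reference_Q[:, 4])
    ll_exact = panel_loglik(reference_Q, data, death_convention="exact")
    assert ll_exact == pytest.approx(float(np.log(dens)), abs=1e-10)


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------


def test_two_state_fit_matches_closed_form():
    """Interval-censored exponential: the MLE of the death rate is
    -log(p_hat)/dt with p_hat the observed fraction of intervals
    survived."""
    rng = np.random.default_rng(8)
    lam, dt = 0.3, 2.0
    rows = []
    n_pairs = stay = 0
    for sid in range(1, 601):
        state, t = 1, 0.0
        rows.append((sid, t, state))
        for _ in range(2):
            if state == 2:
                break
            state = 1 if rng.random() < np.exp(-lam * dt) else 2
            t += dt
            rows.append((sid, t, state))
            n_pairs += 1
            stay += state == 1
    data = _panel(rows, TWO_STATE)
    fit = fit_panel_markov(data, TWO_STATE, init={(1, 2): 0.1})
    closed_form = -np.log(stay / n_pairs) / dt
    assert fit.rates()[(1, 2)] == pytest.approx(closed_form, rel=1e-4)
    assert fit.converged


def test_degenerate_static_data_drives_rates_to_zero():
    rows = [(sid, t, 1) for sid in range(1, 51) for t in (0.0, 2.0, 4.0)]
    fit = fit_panel_markov(_panel(rows), compute_cov=False)
    for t in [(1, 2), (1, 3), (1, 5)]:
        assert fit.rates()[t] < 1e-4
    assert fit.warnings  # pinned rates are reported, not silent


def test_fit_recovers_generating_rates(sim_panel):
    """Rates estimated from a simulated cohort sit near the generating
    values; the covariance is symmetric PSD at the optimum."""
    fit = fit_panel_markov(sim_panel)
    assert fit.converged
    tab = fit.rate_table()
    for _, row in tab.iterrows():
        truth = REFERENCE_INTENSITIES[(row["from_state"], row["to_state"])]
        if truth >= 0.05 and np.isfinite(row["ci_low"]):
            assert row["ci_low"] <= truth <= row["ci_high"], row["transition"]
    finite = ~np.isnan(np.diag(fit.cov))
    sub = fit.cov[np.ix_(finite, finite)]
    assert np.allclose(sub, sub.T, atol=1e-10)
    assert np.min(np.linalg.eigvalsh(sub)) > -1e-8


def test_missing_init_rate_rejected(sim_panel):
    with pytest.raises(ValueError, match="missing"):
        fit_panel_markov(sim_panel, init={(1, 2): 0.1})
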