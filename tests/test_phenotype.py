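"""Phenotype construction: cognition scoring, frailty scoring, state
assignment and covariate derivation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cogfrail import SimulationConfig, assign_state, classify_ci, classify_pf, cognition_total
from cogfrail.phenotype import (
    FRAILTY_COMPONENTS,
    CutoffTable,
    MeasureValidationError,
    age_band,
    build_panel,
    compute_norms,
    derive_covariates,
)
from cogfrail.simulate import simulate_raw_measures

NORMS = {"60-69": (14.0, 3.0)}


@pytest.mark.parametrize(
    "tics,imm,dele,pent,expected",
    [(10, 10, 10, 1, 21), (0, 0, 0, 0, 0), (6, 4, 2, 1, 10), (5, 3, 4, 0, 8.5)],
)
def test_cognition_total(tics, imm, dele, pent, expected):
    assert cognition_total(tics, imm, dele, pent) == expected


@pytest.mark.parametrize(
    "kwargs,field",
    [
        (dict(tics=11, immediate=0, delayed=0, pentagon=0), "tics"),
        (dict(tics=0, immediate=-1, delayed=0, pentagon=0), "immediate_recall"),
        (dict(tics=0, immediate=0, delayed=0, pentagon=2), "pentagon"),
    ],
)
def test_cognition_total_names_bad_field(kwargs, field):
    with pytest.raises(MeasureValidationError, match=field):
        cognition_total(**kwargs)


def test_classify_ci_strict_boundary():
    # exactly one SD below the norm is NOT impairment (strictly below is)
    assert classify_ci(11.0, "60-69", NORMS) == 0
    assert classify_ci(10.5, "60-69", NORMS) == 1


def test_classify_ci_missing_band_lists_available():
    with pytest.raises(MeasureValidationError, match="60-69"):
        classify_ci(10.0, "80+", NORMS)


def test_classify_ci_normal_tail_fraction():
    """Under normal scores and matching norms, roughly Phi(-1) ~ 15.9%
    of subjects fall more than one SD below the mean."""
    rng = np.random.default_rng(5)
    scores = rng.normal(14.0, 3.0, size=200_000)
    flagged = np.mean([classify_ci(s, "60-69", NORMS) for s in scores])
    assert abs(flagged - 0.1587) < 0.005


@pytest.mark.parametrize(
    "present,category,pf",
    [(0, "robust", 0), (1, "prefrail", 1), (2, "prefrail", 1), (3, "frail", 1), (5, "frail", 1)],
)
def test_classify_pf_categories(present, category, pf):
    comps = {c: int(i < present) for i, c in enumerate(FRAILTY_COMPONENTS)}
    assert classify_pf(comps) == (category, pf)


def test_classify_pf_no_partial_scoring():
    comps = {c: 0 for c in FRAILTY_COMPONENTS}
    del comps["slowness"]
    with pytest.raises(MeasureValidationError, match="slowness"):
        classify_pf(comps)


def test_classify_pf_monotone():
    """Adding a component never moves the category toward robust."""
    order = {"robust": 0, "prefrail": 1, "frail": 2}
    for bits in itertools.product((0, 1), repeat=5):
        comps = dict(zip(FRAILTY_COMPONENTS, bits))
        cat, _ = classify_pf(comps)
        for c in FRAILTY_COMPONENTS:
            if not comps[c]:
                more = {**comps, c: 1}
                cat2, _ = classify_pf(more)
                assert order[cat2] >= order[cat]


def test_assign_state_partitions_living():
    assert assign_state(1, 1) == 4
    assert assign_state(0, 0) == 1
    assert assign_state(0, 1) == 3
    assert assign_state(1, 0) == 2
    assert assign_state(1, 0, dead=1) == 5
    living = {assign_state(ci, pf) for ci in (0, 1) for pf in (0, 1)}
    assert living == {1, 2, 3, 4}


def _raw_row(**over):
    row = dict(
        age=65, female=0, cesd_total=4, sleep_hours=7.0, n_conditions=0,
        falls=0, injury=0, life_satisfied=1, literacy=1, rural=0,
    )
    row.update(over)
    return row


def test_derive_covariates_thresholds():
    assert derive_covariates(_raw_row(n_conditions=2))["multimorbidity"] == 1
    assert derive_covariates(_raw_row(n_conditions=1))["multimorbidity"] == 0
    assert derive_covariates(_raw_row(cesd_total=10))["depression"] == 1
    assert derive_covariates(_raw_row(cesd_total=9))["depression"] == 0
    # sleep boundaries: closed interval 6-9 is intermediate
    for h, short, long_ in [(9.0, 0, 0), (6.0, 0, 0), (5.9, 1, 0), (9.1, 0, 1)]:
        cv = derive_covariates(_raw_row(sleep_hours=h))
        assert (cv["sleep_short"], cv["sleep_long"]) == (short, long_)


def test_derive_covariates_validation():
    with pytest.raises(MeasureValidationError):
        derive_covariates(_raw_row(cesd_total=31))
    with pytest.raises(MeasureValidationError):
        derive_covariates(_raw_row(sleep_hours=-1))


def test_age_band_edges():
    assert [age_band(a) for a in (60, 69.9, 70, 79.9, 80, 95)] == [
        "60-69", "60-69", "70-79", "70-79", "80+", "80+"
    ]
    with pytest.raises(MeasureValidationError):
        age_band(59)


def test_cutoff_table_roundtrip(tmp_path):
    ct = CutoffTable()
    p = tmp_path / "cutoffs.yaml"
    ct.to_yaml(p)
    back = CutoffTable.from_yaml(p)
    assert back.grip == ct.grip
    assert back.gait_speed == ct.gait_speed
    assert back.bmi_shrinking_threshold == ct.bmi_shrinking_threshold


def test_build_panel_excludes_incomplete_subjects():
    rc = simulate_raw_measures(SimulationConfig(n_subjects=50, seed=11))
    raw = rc.raw.copy()
    victim = raw.loc[raw["dead"] == 0, "subject_id"].iloc[0]
    raw.loc[(raw["subject_id"] == victim) & (raw["dead"] == 0), "grip_kg"] = np.nan
    res = build_panel(raw, cutoffs=rc.cutoffs, norms=rc.norms)
    assert victim not in set(res.panel.data["subject_id"])
    assert (res.exclusions["subject_id"] == victim).any()


def test_build_panel_internal_norms():
    """With no external norms the pipeline computes within-sample
    age-band norms and still produces a valid panel."""
    rc = simulate_raw_measures(SimulationConfig(n_subjects=200, seed=12))
    res = build_panel(rc.raw, cutoffs=rc.cutoffs, norms=None)
    assert set(res.norms) <= {"60-69", "70-79", "80+"}
    for mean, sd in res.norms.values():
        assert 0 < mean < 21 and sd > 0
    assert set(res.panel.data["state"]) <= {1, 2, 3, 4, 5}


def test_state_mix_matches_generator_margins():
    """Phenotype states on generated raw measures reproduce the
    generator's configured baseline mix within binomial error."""
    cfg = SimulationConfig(n_subjects=1000, seed=13)
    rc = simulate_raw_measures(cfg)
    res = build_panel(rc.raw, cutoffs=rc.cutoffs, norms=rc.norms)
    counts = res.panel.baseline_state_counts()
    total = sum(cfg.baseline_counts.values())
    for s, c in cfg.baseline_counts.items():
        p = c / total
        se = np.sqrt(p * (1 - p) * 1000)
        assert abs(counts.get(s, 0) - 1000 * p) <= max(3 * se, 3)


def test_compute_norms_by_band():
    totals = pd.Series([10.0, 12.0, 14.0, 8.0, 9.0, 10.0])
    bands = pd.Series(["60-69"] * 3 + ["70-79"] * 3)
    norms = compute_norms(totals, bands)
    assert norms["60-69"][0] == pytest.approx(12.0)
    assert norms["70-79"][0] == pytest.approx(9.0)
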