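"""Construction of the four living states from raw component measures.

Cognition is scored 0-21 from a 10-point orientation/serial-subtraction
screen (TICS-10), 10-word immediate and delayed recall (averaged), and
pentagon figure drawing (0/1); cognitive impairment (CI) is a total
strictly more than one standard deviation below the age-band norm.
Physical frailty follows the modified Fried phenotype: shrinking,
weakness, slowness, low physical activity and exhaustion, each scored
0/1; pre-frail (1-2) and frail (3-5) are merged into a single PF state.
Cognitive frailty (CF) is the simultaneous presence of CI and PF; the
normal state (NS) is neither.  Death overrides everything.

The grip and gait cut-offs are population-specific and shipped here as
configurable defaults following the original Fried convention
(gender x BMI-quartile grip strength, gender x median-height gait
speed); age-band cognition norms default to within-sample means/SDs but
accept external normative tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .panel import PanelDataset
from .states import State

AGE_BANDS = ("60-69", "70-79", "80+")

RAW_COLUMNS = (
    "subject_id", "time_years", "dead", "age", "female",
    "tics", "recall_immediate", "recall_delayed", "pentagon",
    "bmi", "grip_kg", "gait_speed", "height_cm", "walks_10min",
    "cesd_effort", "cesd_get_going", "cesd_total", "sleep_hours",
    "n_conditions", "falls", "injury", "life_satisfied", "literacy", "rural",
)

FRAILTY_COMPONENTS = ("shrinking", "weakness", "slowness", "low_activity", "exhaustion")


class MeasureValidationError(ValueError):
    """A raw component measure is outside its admissible range."""


def age_band(age: float) -> str:
    if age < 60:
        raise MeasureValidationError(f"age {age} below the cohort minimum of 60")
    if age < 70:
        return "60-69"
    if age < 80:
        return "70-79"
    return "80+"


# ----------------------------------------------------------------------
# cut-offs
# ----------------------------------------------------------------------

_DEFAULT_GRIP = {
    # Fried-convention grip-strength cut-offs (kg) by gender and BMI quartile
    ("male", 1): 29.0, ("male", 2): 30.0, ("male", 3): 30.0, ("male", 4): 32.0,
    ("female", 1): 17.0, ("female", 2): 17.3, ("female", 3): 18.0, ("female", 4): 21.0,
}
_DEFAULT_GRIP_BMI_QUARTILES = {"male": (24.0, 26.0, 28.0), "female": (23.0, 26.0, 29.0)}
_DEFAULT_GAIT = {
    # walking-speed cut-offs (m/s) by gender and height stratum
    ("male", "short"): 0.653, ("male", "tall"): 0.762,
    ("female", "short"): 0.653, ("female", "tall"): 0.762,
}
_DEFAULT_HEIGHT_THRESHOLD = {"male": 173.0, "female": 159.0}


@dataclass(frozen=True)
class CutoffTable:
    """Cut-off values for the five frailty components.

    Defaults follow the Fried-phenotype convention and are meant to be
    replaced with population-specific values where available.
    """

    bmi_shrinking_threshold: float = 18.5
    grip: dict[tuple[str, int], float] = field(default_factory=lambda: dict(_DEFAULT_GRIP))
    grip_bmi_quartiles: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_GRIP_BMI_QUARTILES)
    )
    gait_speed: dict[tuple[str, str], float] = field(default_factory=lambda: dict(_DEFAULT_GAIT))
    height_threshold_cm: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_HEIGHT_THRESHOLD)
    )
    cesd_item_threshold: int = 2  # items coded 0-3; "3-4 days" and up count

    def bmi_stratum(self, gender: str, bmi: float) -> int:
        q = self.grip_bmi_quartiles[gender]
        return 1 + int(bmi > q[0]) + int(bmi > q[1]) + int(bmi > q[2])

    def grip_cutoff(self, gender: str, bmi: float) -> float:
        key = (gender, self.bmi_stratum(gender, bmi))
        if key not in self.grip:
            raise MeasureValidationError(f"no grip cut-off for stratum {key}")
        return self.grip[key]

    def gait_cutoff(self, gender: str, height_cm: float) -> float:
        stratum = "short" if height_cm <= self.height_threshold_cm[gender] else "tall"
        key = (gender, stratum)
        if key not in self.gait_speed:
            raise MeasureValidationError(f"no gait cut-off for stratum {key}")
        return self.gait_speed[key]

    # -- config-file round trip ----------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "bmi_shrinking_threshold": self.bmi_shrinking_threshold,
            "grip": {f"{g}:{q}": v for (g, q), v in self.grip.items()},
            "grip_bmi_quartiles": {g: list(v) for g, v in self.grip_bmi_quartiles.items()},
            "gait_speed": {f"{g}:{s}": v for (g, s), v in self.gait_speed.items()},
            "height_threshold_cm": dict(self.height_threshold_cm),
            "cesd_item_threshold": self.cesd_item_threshold,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "CutoffTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            bmi_shrinking_threshold=float(doc["bmi_shrinking_threshold"]),
            grip={
                (k.split(":")[0], int(k.split(":")[1])): float(v)
                for k, v in doc["grip"].items()
            },
            grip_bmi_quartiles={g: tuple(v) for g, v in doc["grip_bmi_quartiles"].items()},
            gait_speed={
                (k.split(":")[0], k.split(":")[1]): float(v)
                for k, v in doc["gait_speed"].items()
            },
            height_threshold_cm=dict(doc["height_threshold_cm"]),
            cesd_item_threshold=int(doc["cesd_item_threshold"]),
        )


# ----------------------------------------------------------------------
# scoring
# ----------------------------------------------------------------------


def cognition_total(tics: float, immediate: float, delayed: float, pentagon: int) -> float:
    """Total cognition score 0-21: TICS + mean of the two recalls + pentagon.

    Half points arise from averaging the immediate and delayed recall.
    """
    for name, v, hi in (
        ("tics", tics, 10), ("immediate_recall", immediate, 10),
        ("delayed_recall", delayed, 10), ("pentagon", pentagon, 1),
    ):
        if not 0 <= v <= hi:
            raise MeasureValidationError(f"{name}={v} outside its range 0-{hi}")
    return float(tics) + (float(immediate) + float(delayed)) / 2.0 + float(pentagon)


def classify_ci(total: float, band: str, norms: dict[str, tuple[float, float]]) -> int:
    """1 iff the total falls strictly more than one SD below the band norm."""
    if band not in norms:
        raise MeasureValidationError(
            f"no cognition norm for age band {band!r}; available bands: {sorted(norms)}"
        )
    mean, sd = norms[band]
    return int(total < mean - sd)


def classify_pf(components: dict[str, int]) -> tuple[str, int]:
    """Frailty category from the five components and the merged PF flag.

    Score 0 is robust (PF=0); 1-2 pre-frail and 3-5 frail, merged to PF=1.
    """
    missing = [c for c in FRAILTY_COMPONENTS if c not in components or pd.isna(components[c])]
    if missing:
        raise MeasureValidationError(f"missing frailty components {missing}; no partial scoring")
    vals = [int(components[c]) for c in FRAILTY_COMPONENTS]
    if any(v not in (0, 1) for v in vals):
        raise MeasureValidationError(f"frailty components must be 0/1, got {vals}")
    score = sum(vals)
    category = "robust" if score == 0 else ("prefrail" if score <= 2 else "frail")
    return category, int(score >= 1)


def assign_state(ci: int, pf: int, dead: int = 0) -> int:
    """Five-state label: death overrides; CF = CI and PF together."""
    if dead:
        return int(State.DEATH)
    if ci and pf:
        return int(State.CF)
    if pf:
        return int(State.PF)
    if ci:
        return int(State.CI)
    return int(State.NS)


def score_frailty(row: dict[str, Any], cutoffs: CutoffTable) -> dict[str, int]:
    """The five Fried components for a single subject-wave of raw measures."""
    gender = "female" if int(row["female"]) else "male"
    thr = cutoffs.cesd_item_threshold
    return {
        "shrinking": int(row["bmi"] <= cutoffs.bmi_shrinking_threshold),
        "weakness": int(row["grip_kg"] < cutoffs.grip_cutoff(gender, row["bmi"])),
        "slowness": int(row["gait_speed"] < cutoffs.gait_cutoff(gender, row["height_cm"])),
        "low_activity": int(not row["walks_10min"]),
        "exhaustion": int(row["cesd_effort"] >= thr or row["cesd_get_going"] >= thr),
    }


def derive_covariates(row: dict[str, Any]) -> dict[str, int]:
    """Baseline covariate indicators from raw measures.

    Depression is a CESD-10 total of 10 or more; multimorbidity is two
    or more diagnosed chronic conditions; sleep is short below 6 h,
    long above 9 h, intermediate on the closed interval 6-9 h.
    """
    cesd = float(row["cesd_total"])
    if not 0 <= cesd <= 30:
        raise MeasureValidationError(f"cesd_total={cesd} outside 0-30")
    hours = float(row["sleep_hours"])
    if hours < 0:
        raise MeasureValidationError(f"sleep_hours={hours} is negative")
    if float(row["n_conditions"]) < 0:
        raise MeasureValidationError("n_conditions is negative")
    band = age_band(float(row["age"]))
    return {
        "female": int(row["female"]),
        "literacy": int(row["literacy"]),
        "rural": int(row["rural"]),
        "dissatisfied": int(not row["life_satisfied"]),
        "depression": int(cesd >= 10),
        "multimorbidity": int(float(row["n_conditions"]) >= 2),
        "falls": int(row["falls"]),
        "injury": int(row["injury"]),
        "age_70_79": int(band == "70-79"),
        "age_80p": int(band == "80+"),
        "sleep_short": int(hours < 6),
        "sleep_long": int(hours > 9),
    }


COVARIATE_COLUMNS = (
    "female", "literacy", "rural", "dissatisfied", "depression", "multimorbidity",
    "falls", "injury", "age_70_79", "age_80p", "sleep_short", "sleep_long",
)


def compute_norms(totals: pd.Series, bands: pd.Series) -> dict[str, tuple[float, float]]:
    """Within-sample age-band cognition norms (mean, SD)."""
    out = {}
    for band, vals in totals.groupby(bands):
        out[band] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out


# ----------------------------------------------------------------------
# pipeline: raw measures -> analysis-ready panel
# ----------------------------------------------------------------------

_MEASURE_COLS = (
    "tics", "recall_immediate", "recall_delayed", "pentagon",
    "bmi", "grip_kg", "gait_speed", "height_cm", "walks_10min",
    "cesd_effort", "cesd_get_going",
)
_BASELINE_COLS = (
    "age", "female", "cesd_total", "sleep_hours", "n_conditions",
    "falls", "injury", "life_satisfied", "literacy", "rural",
)


@dataclass
class PhenotypeResult:
    panel: PanelDataset
    exclusions: pd.DataFrame  # subject_id, reason
    norms: dict[str, tuple[float, float]]
    cutoffs: CutoffTable


def build_panel(
    raw: pd.DataFrame,
    cutoffs: CutoffTable | None = None,
    norms: dict[str, tuple[float, float]] | None = None,
    column_map: dict[str, str] | None = None,
) -> PhenotypeResult:
    """Turn raw subject-wave measures into an analysis-ready state panel.

    Subjects with any incomplete living-wave measure or invalid baseline
    covariate are excluded entirely (complete-case analysis) and listed
    in the exclusion log.  When ``norms`` is omitted, age-band norms are
    the within-sample mean/SD of baseline cognition totals of subjects
    passing the completeness screen.

    Parameters
    ----------
    raw
        One row per subject per wave, canonical column names (see
        ``RAW_COLUMNS``); ``column_map`` renames input columns to
        canonical ones first.
    """
    cutoffs = cutoffs or CutoffTable()
    df = raw.rename(columns=column_map or {}).copy()
    needed = {"subject_id", "time_years", "dead"}
    missing = needed - set(df.columns)
    if missing:
        raise MeasureValidationError(f"raw data missing required columns {sorted(missing)}")
    df = df.sort_values(["subject_id", "time_years"], kind="stable")

    excluded: list[dict] = []
    records: list[dict] = []
    for sid, g in df.groupby("subject_id", sort=False):
        base = g.iloc[0]
        try:
            covs = derive_covariates(base)
            band = age_band(float(base["age"]))
        except (MeasureValidationError, KeyError, TypeError) as e:
            excluded.append({"subject_id": sid, "reason": f"baseline covariates: {e}"})
            continue
        if pd.isna([base.get(c, np.nan) for c in _BASELINE_COLS]).any():
            excluded.append({"subject_id": sid, "reason": "missing baseline covariate"})
            continue
        rows = []
        ok = True
        for _, r in g.iterrows():
            if int(r["dead"]):
                rows.append({"subject_id": sid, "time_years": float(r["time_years"]),
                             "total": np.nan, "pf": 0, "dead": 1, "band": band, **covs})
                break  # nothing observed after death
            if pd.isna([r.get(c, np.nan) for c in _MEASURE_COLS]).any():
                excluded.append(
                    {"subject_id": sid,
                     "reason": f"incomplete measures at t={r['time_years']}"}
                )
                ok = False
                break
            try:
                total = cognition_total(
                    r["tics"], r["recall_immediate"], r["recall_delayed"], r["pentagon"]
                )
                _, pf = classify_pf(score_frailty(r, cutoffs))
            except MeasureValidationError as e:
                excluded.append({"subject_id": sid, "reason": str(e)})
                ok = False
                break
            rows.append({"subject_id": sid, "time_years": float(r["time_years"]),
                         "total": total, "pf": pf, "dead": 0, "band": band, **covs})
        if ok:
            records.extend(rows)

    if not records:
        raise MeasureValidationError("no subjects survived the completeness screen")
    tab = pd.DataFrame(records)
    if norms is None:
        first = tab.groupby("subject_id", sort=False).head(1)
        living = first[first["dead"] == 0]
        norms = compute_norms(living["total"], living["band"])

    state = []
    for _, r in tab.iterrows():
        if r["dead"]:
            state.append(int(State.DEATH))
        else:
            ci = classify_ci(r["total"], r["band"], norms)
            state.append(assign_state(ci, int(r["pf"])))
    tab["state"] = state
    panel_df = tab[["subject_id", "time_years", "state", *COVARIATE_COLUMNS]].reset_index(
        drop=True
    )
    panel = PanelDataset(panel_df, covariates=COVARIATE_COLUMNS)
    exclusions = pd.DataFrame(excluded, columns=["subject_id", "reason"])
    return PhenotypeResult(panel, exclusions, norms, cutoffs)
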