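"""Cohort-level descriptive statistics of cognitive-frailty transitions:
incidence and improvement rates per 100 person-years, follow-up state
distributions, cumulative mortality, and baseline comparison tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import PanelDataset
from .states import State

PERSON_YEAR_CONVENTIONS = ("full", "censor_death", "censor_event")


@dataclass
class RateResult:
    """An event rate per ``per`` person-years.

    ``convention`` records the person-year accounting used:

    * ``full`` — every at-risk subject contributes the whole follow-up
      span regardless of death or event timing;
    * ``censor_death`` (default) — a subject observed dead at a wave
      contributes exposure to the midpoint of the interval in which the
      death occurred;
    * ``censor_event`` — additionally, a subject is censored at the
      midpoint of the interval in which the event is first observed.
    """

    events: int
    person_years: float
    rate: float
    convention: str
    per: float = 100.0


def _first_occurrence(panel: PanelDataset, target: set[int], at_risk_baseline: set[int]):
    """Per at-risk subject: follow-up rows, first-event time, death time."""
    df = panel.data
    base = panel.baseline()
    risk_ids = base.loc[base["state"].isin(at_risk_baseline), "subject_id"]
    if risk_ids.empty:
        raise ValueError("no subjects at risk at baseline")
    sub = df[df["subject_id"].isin(risk_ids)]
    t0 = sub.groupby("subject_id")["time_years"].transform("min")
    later = sub[sub["time_years"] > t0]
    return sub, later, risk_ids


def _interval_midpoint(sub: pd.DataFrame, sid, t_event: float) -> float:
    """Midpoint of (previous observation time, t_event) for one subject."""
    times = sub.loc[sub["subject_id"] == sid, "time_years"].sort_values().to_numpy()
    prev = times[times < t_event]
    lo = prev[-1] if prev.size else t_event
    return (lo + t_event) / 2.0


def _event_rate(
    panel: PanelDataset,
    at_risk: set[int],
    event_states: set[int],
    convention: str,
    per: float,
) -> RateResult:
    if convention not in PERSON_YEAR_CONVENTIONS:
        raise ValueError(f"convention must be one of {PERSON_YEAR_CONVENTIONS}")
    sub, later, risk_ids = _first_occurrence(panel, event_states, at_risk)
    t0 = float(panel.wave_times.min())
    span = float(panel.wave_times.max() - t0)

    ev = later[later["state"].isin(event_states)]
    first_event = ev.groupby("subject_id")["time_years"].min()
    dead = later[later["state"] == int(State.DEATH)]
    death_at = dead.groupby("subject_id")["time_years"].min()

    n = len(risk_ids)
    if convention == "full":
        py = n * span
    else:
        last_seen = sub.groupby("subject_id")["time_years"].max()
        py = 0.0
        for sid in risk_ids:
            # exposure runs to the last visit (loss to follow-up censors)
            t_end = float(last_seen[sid])
            if sid in death_at.index:
                t_end = _interval_midpoint(sub, sid, float(death_at[sid]))
            if convention == "censor_event" and sid in first_event.index:
                t_end = min(t_end, _interval_midpoint(sub, sid, float(first_event[sid])))
            py += t_end - t0
    events = int(first_event.size)
    if py <= 0:
        raise ValueError("person-years is zero")
    return RateResult(events, float(py), per * events / py, convention, per)


def incidence_rate_cf(
    panel: PanelDataset, convention: str = "censor_death", per: float = 100.0
) -> RateResult:
    """New CF cases among CF-free-at-baseline subjects per ``per``
    person-years (first observed occurrence counts)."""
    return _event_rate(
        panel, at_risk={1, 2, 3}, event_states={int(State.CF)}, convention=convention, per=per
    )


def improvement_rate_cf(
    panel: PanelDataset, convention: str = "censor_death", per: float = 100.0
) -> RateResult:
    """Baseline-CF subjects later observed CF-free (NS, CI or PF) per
    ``per`` person-years."""
    return _event_rate(
        panel, at_risk={int(State.CF)}, event_states={1, 2, 3}, convention=convention, per=per
    )


# ----------------------------------------------------------------------


@dataclass
class FollowupDistribution:
    """State distribution at the final wave by baseline state."""

    table: pd.DataFrame            # baseline state x follow-up state counts
    fractions: pd.DataFrame        # rows normalised to 1
    cf_free_to_cf_pct: float       # % of baseline CF-free subjects in CF at follow-up
    cf_to_cf_free_pct: float       # % of baseline CF subjects CF-free at follow-up
    n_unresolved: int              # subjects lost before the final wave


def followup_distribution(panel: PanelDataset) -> FollowupDistribution:
    df = panel.data
    t_end = float(panel.wave_times.max())
    base = panel.baseline().set_index("subject_id")["state"]
    final = df[df["time_years"] == t_end].set_index("subject_id")["state"]
    died = df[df["state"] == int(State.DEATH)].set_index("subject_id")["state"]
    followup = final.combine_first(died)  # death before the last wave carries forward

    resolved = followup.index.intersection(base.index)
    tab = pd.crosstab(base.loc[resolved], followup.loc[resolved])
    tab = tab.reindex(index=[1, 2, 3, 4], columns=[1, 2, 3, 4, 5], fill_value=0)
    frac = tab.div(tab.sum(axis=1).replace(0, np.nan), axis=0)

    cf_free = tab.loc[[1, 2, 3]].to_numpy()
    n_cf_free = cf_free.sum()
    cf_free_to_cf = tab.loc[[1, 2, 3], 4].sum()
    n_cf = tab.loc[4].sum()
    cf_to_free = tab.loc[4, [1, 2, 3]].sum()
    return FollowupDistribution(
        table=tab,
        fractions=frac,
        cf_free_to_cf_pct=float(100.0 * cf_free_to_cf / n_cf_free) if n_cf_free else np.nan,
        cf_to_cf_free_pct=float(100.0 * cf_to_free / n_cf) if n_cf else np.nan,
        n_unresolved=int(len(base) - len(resolved)),
    )


@dataclass
class MortalityResult:
    deaths_cf: int
    n_cf: int
    deaths_cf_free: int
    n_cf_free: int

    @property
    def cf_pct(self) -> float:
        return 100.0 * self.deaths_cf / self.n_cf if self.n_cf else 0.0

    @property
    def cf_free_pct(self) -> float:
        return 100.0 * self.deaths_cf_free / self.n_cf_free if self.n_cf_free else 0.0


def cumulative_mortality(panel: PanelDataset) -> MortalityResult:
    """Cumulative death fractions over follow-up, split by baseline CF
    status."""
    base = panel.baseline().set_index("subject_id")["state"]
    died = set(
        panel.data.loc[panel.data["state"] == int(State.DEATH), "subject_id"]
    )
    is_cf = base == int(State.CF)
    n_cf = int(is_cf.sum())
    n_free = int((~is_cf).sum())
    d_cf = sum(1 for sid in base.index[is_cf] if sid in died)
    d_free = sum(1 for sid in base.index[~is_cf] if sid in died)
    return MortalityResult(d_cf, n_cf, d_free, n_free)


# ----------------------------------------------------------------------


def baseline_table(
    data: pd.DataFrame,
    group_col: str = "state",
    continuous: tuple[str, ...] = (),
    categorical: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Baseline comparison table across groups.

    Continuous variables are summarised as mean +/- SD and compared
    with one-way ANOVA (F); categorical variables as count (%) compared
    with a chi-square test of independence.
    """
    groups = sorted(data[group_col].unique())
    rows = []
    for v in continuous:
        cells = {
            f"g{g}": f"{data.loc[data[group_col] == g, v].mean():.2f} "
            f"± {data.loc[data[group_col] == g, v].std(ddof=1):.2f}"
            for g in groups
        }
        samples = [data.loc[data[group_col] == g, v].dropna() for g in groups]
        if all(len(s) > 1 for s in samples) and len(samples) > 1:
            F, p = stats.f_oneway(*samples)
        else:
            F, p = np.nan, np.nan
        rows.append({"variable": v, "type": "continuous", **cells,
                     "statistic": float(F), "p_value": float(p)})
    for v in categorical:
        ct = pd.crosstab(data[group_col], data[v])
        cells = {}
        for g in groups:
            npos = int(data.loc[data[group_col] == g, v].sum())
            ntot = int((data[group_col] == g).sum())
            cells[f"g{g}"] = f"{npos} ({100 * npos / ntot:.2f}%)" if ntot else "0"
        if ct.shape[1] > 1 and (ct.to_numpy().sum(axis=0) > 0).all():
            chi2_stat, p, _, _ = stats.chi2_contingency(ct)
        else:
            chi2_stat, p = 0.0, 1.0
        rows.append({"variable": v, "type": "categorical", **cells,
                     "statistic": float(chi2_stat), "p_value": float(p)})
    return pd.DataFrame(rows)
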