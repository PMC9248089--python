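"""Synthetic-cohort generator: exact continuous-time trajectories under a
given generator matrix, observed at panel waves.

The defaults emulate a CHARLS-like cohort: 4051 subjects aged 60+, a
baseline mix of 1441 NS / 142 CI / 2001 PF / 467 CF, three waves at
0/2/4 years, reference per-year intensities, and independent baseline
covariates at their observed marginal prevalences.  Trajectories are
simulated exactly by competing risks — exponential holding times with
mean -1/q_rr and next-state probabilities q_rs/(-q_rr) — and read off
at the wave times; a death is recorded at the first scheduled wave
after the death jump (interval reporting, as in an exit interview) and
nothing is recorded afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference as ref
from .covariates import apply_covariates
from .ctmc import build_intensity_matrix
from .panel import PanelDataset
from .phenotype import COVARIATE_COLUMNS, CutoffTable
from .states import FIVE_STATE, StateSpace


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    ``hazard_ratios`` maps (transition, covariate name) to the true
    multiplicative effect of that binary covariate on that transition's
    intensity; covariates are drawn independently at their marginal
    prevalences (a joint distribution can be injected by overriding
    ``draw_covariates``-level inputs downstream).
    """

    n_subjects: int = 4051
    baseline_counts: dict[int, int] = field(
        default_factory=lambda: dict(ref.REFERENCE_BASELINE_COUNTS)
    )
    wave_times: tuple[float, ...] = (0.0, 2.0, 4.0)
    rates: dict[tuple[int, int], float] = field(
        default_factory=lambda: dict(ref.REFERENCE_INTENSITIES)
    )
    covariate_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(ref.REFERENCE_COVARIATE_PREVALENCE)
    )
    sleep_probs: dict[str, float] = field(default_factory=lambda: dict(ref.REFERENCE_SLEEP_PROBS))
    age_band_probs: dict[str, float] = field(
        default_factory=lambda: dict(ref.REFERENCE_AGE_BAND_PROBS)
    )
    hazard_ratios: dict[tuple[tuple[int, int], str], float] = field(default_factory=dict)
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.wave_times) != sorted(set(self.wave_times)):
            raise ValueError("wave times must be strictly increasing")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be a probability below 1")

    def truth(self) -> dict:
        """Generating parameters for test harnesses, JSON-serialisable."""
        return {
            "seed": self.seed,
            "rates": {f"{r}->{s}": v for (r, s), v in self.rates.items()},
            "hazard_ratios": {f"{r}->{s}:{c}": v for ((r, s), c), v in self.hazard_ratios.items()},
            "baseline_counts": {str(k): v for k, v in self.baseline_counts.items()},
            "wave_times": list(self.wave_times),
            "n_subjects": self.n_subjects,
            "dropout": self.dropout,
        }


# ----------------------------------------------------------------------
# exact trajectory simulation
# ----------------------------------------------------------------------


def simulate_trajectory(
    Q: np.ndarray, t_max: float, rng: np.random.Generator, start_state: int = 1, t0: float = 0.0
) -> list[tuple[float, int]]:
    """One exact jump path: [(time, state)] starting at (t0, start_state).

    Holding times are exponential with rate -q_rr; the next state is
    drawn with probability q_rs / (-q_rr).  Stops at ``t_max`` or on
    entering a state with no exits.
    """
    Q = np.asarray(Q, dtype=float)
    path = [(float(t0), int(start_state))]
    t, state = float(t0), int(start_state)
    while True:
        exit_rate = -Q[state - 1, state - 1]
        if exit_rate <= 0:
            return path
        t = t + rng.exponential(1.0 / exit_rate)
        if t > t_max:
            return path
        probs = Q[state - 1].clip(min=0.0)
        probs[state - 1] = 0.0
        state = int(rng.choice(len(probs), p=probs / probs.sum())) + 1
        path.append((t, state))


def _advance(
    Q: np.ndarray, states: np.ndarray, duration: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised exact simulation: state of each subject after ``duration``."""
    Q = np.asarray(Q, dtype=float)
    exit_rates = -np.diag(Q)
    jump = Q.clip(min=0.0)
    np.fill_diagonal(jump, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        jump = np.where(exit_rates[:, None] > 0, jump / exit_rates[:, None], 0.0)
    cum = jump.cumsum(axis=1)

    states = np.asarray(states, dtype=int).copy()
    remaining = np.full(len(states), float(duration))
    active = exit_rates[states - 1] > 0
    while active.any():
        idx = np.flatnonzero(active)
        er = exit_rates[states[idx] - 1]
        dwell = rng.exponential(1.0 / er)
        stays = dwell >= remaining[idx]
        active[idx[stays]] = False
        moving = idx[~stays]
        if moving.size:
            remaining[moving] -= dwell[~stays]
            u = rng.random(moving.size)
            nxt = (u[:, None] >= cum[states[moving] - 1]).sum(axis=1) + 1
            states[moving] = nxt
            active[moving] = exit_rates[nxt - 1] > 0
    return states


# ----------------------------------------------------------------------
# cohort simulation
# ----------------------------------------------------------------------


def _allocate_baseline(counts: dict[int, int], n: int) -> np.ndarray:
    """Baseline states at the configured mix, scaled to n by largest
    remainder so the counts are exact and deterministic."""
    total = sum(counts.values())
    states = sorted(counts)
    if total == n:
        alloc = {s: counts[s] for s in states}
    else:
        exact = {s: counts[s] * n / total for s in states}
        alloc = {s: int(np.floor(v)) for s, v in exact.items()}
        shortfall = n - sum(alloc.values())
        for s in sorted(states, key=lambda s: exact[s] - alloc[s], reverse=True)[:shortfall]:
            alloc[s] += 1
    return np.repeat(list(alloc.keys()), list(alloc.values()))


def draw_covariates(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Independent baseline covariate indicators at their marginal
    prevalences, plus age-band and sleep-category indicators."""
    n = cfg.n_subjects
    cols = {c: (rng.random(n) < p).astype(int) for c, p in cfg.covariate_prevalence.items()}
    bands = list(cfg.age_band_probs)
    band = rng.choice(len(bands), size=n, p=np.array(list(cfg.age_band_probs.values())))
    cols["age_70_79"] = (band == bands.index("70-79")).astype(int)
    cols["age_80p"] = (band == bands.index("80+")).astype(int)
    sleeps = list(cfg.sleep_probs)
    sl = rng.choice(len(sleeps), size=n, p=np.array(list(cfg.sleep_probs.values())))
    cols["sleep_short"] = (sl == sleeps.index("short")).astype(int)
    cols["sleep_long"] = (sl == sleeps.index("long")).astype(int)
    return pd.DataFrame(cols)[list(COVARIATE_COLUMNS)]


def simulate_cohort(
    cfg: SimulationConfig, space: StateSpace = FIVE_STATE
) -> PanelDataset:
    """Simulate a panel-observed cohort under the configured conditions.

    Subjects are assigned baseline states at the exact configured mix,
    covariates are drawn independently, each subject's generator is the
    baseline generator scaled by its covariate hazard ratios, and exact
    trajectories are read off at the wave times.  Death appears once, at
    the first wave after the death jump; with positive ``dropout`` a
    subject is censored from a wave onward with that per-wave
    probability.
    """
    rng = np.random.default_rng(cfg.seed)
    n, waves = cfg.n_subjects, list(cfg.wave_times)
    states0 = _allocate_baseline(cfg.baseline_counts, n)
    covs = draw_covariates(cfg, rng)

    Q0 = build_intensity_matrix(cfg.rates, space)
    beta = {(t, c): float(np.log(hr)) for (t, c), hr in cfg.hazard_ratios.items()}
    effect_covs = sorted({c for _, c in beta})

    wave_states = np.zeros((n, len(waves)), dtype=int)
    wave_states[:, 0] = states0
    if effect_covs:
        pattern_ids = covs[effect_covs].astype(int)
        groups = pattern_ids.groupby(effect_covs, sort=True).indices
        # dict key is scalar when a single covariate is used
        norm_groups = {
            (k if isinstance(k, tuple) else (k,)): np.asarray(v) for k, v in groups.items()
        }
    else:
        norm_groups = {(): np.arange(n)}

    for key, idx in sorted(norm_groups.items()):
        x = dict(zip(effect_covs, key))
        Qx = apply_covariates(Q0, beta, x, space) if beta else Q0
        cur = wave_states[idx, 0]
        for w in range(1, len(waves)):
            cur = _advance(Qx, cur, waves[w] - waves[w - 1], rng)
            wave_states[idx, w] = cur

    keep = np.ones((n, len(waves)), dtype=bool)
    if cfg.dropout > 0:
        drop = rng.random((n, len(waves))) < cfg.dropout
        drop[:, 0] = False
        keep &= ~np.maximum.accumulate(drop, axis=1)

    death = set(space.absorbing)
    rows = []
    for i in range(n):
        for w, t in enumerate(waves):
            if not keep[i, w]:
                break
            s = int(wave_states[i, w])
            rows.append((i + 1, float(t), s))
            if s in death:
                break
    df = pd.DataFrame(rows, columns=["subject_id", "time_years", "state"])
    df = df.merge(
        covs.assign(subject_id=np.arange(1, n + 1)), on="subject_id", how="left"
    )
    return PanelDataset(df, covariates=tuple(COVARIATE_COLUMNS), space=space)


# ----------------------------------------------------------------------
# raw-measure simulation (input for the phenotype pipeline)
# ----------------------------------------------------------------------

#: Age-band cognition norms used when generating raw scores; emitted with
#: the cohort so the phenotype pipeline can reproduce the latent states.
DEFAULT_SIM_NORMS: dict[str, tuple[float, float]] = {
    "60-69": (14.0, 3.0),
    "70-79": (13.5, 3.0),
    "80+": (13.0, 3.0),
}

_FRAILTY_SCORE_PROBS = np.array([0.45, 0.30, 0.15, 0.07, 0.03])  # score 1..5 given PF


@dataclass
class RawMeasureCohort:
    raw: pd.DataFrame
    panel: PanelDataset
    norms: dict[str, tuple[float, float]]
    cutoffs: CutoffTable
    config: SimulationConfig


def _half_point_between(lo: float, hi: float, rng: np.random.Generator) -> float:
    """A uniformly drawn multiple of 0.5 in [lo, hi]."""
    lo2, hi2 = int(np.ceil(lo * 2)), int(np.floor(hi * 2))
    return rng.integers(lo2, hi2 + 1) / 2.0


def _decompose_cognition(total: float, rng: np.random.Generator) -> tuple[int, int, int, int]:
    """Split a 0-21 total (half points allowed) into TICS, immediate and
    delayed recall and pentagon, each within range."""
    pentagon = int(total >= 11)
    rem = total - pentagon
    # recall average (rem - tics) must stay within 0..10
    tics = int(min(10, max(np.ceil(rem - 10), rem // 2)))
    w2 = int(round((rem - tics) * 2))  # twice the recall average, 0..20
    imm = min(10, w2)
    dele = w2 - imm
    return tics, imm, dele, pentagon


def simulate_raw_measures(
    cfg: SimulationConfig,
    cutoffs: CutoffTable | None = None,
    norms: dict[str, tuple[float, float]] | None = None,
) -> RawMeasureCohort:
    """Raw component measures consistent with a simulated latent panel.

    For every living subject-wave the generated cognition subscores and
    frailty-component measures land on the correct side of the supplied
    norms and cut-offs, so running the phenotype pipeline on the output
    (with these same norms and cut-offs) reproduces the latent states
    exactly.  Baseline covariate measures (CESD total, sleep hours,
    condition count, ...) are generated consistent with the covariate
    indicators drawn for the panel.
    """
    cutoffs = cutoffs or CutoffTable()
    norms = norms or dict(DEFAULT_SIM_NORMS)
    panel = simulate_cohort(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 917]))
    df = panel.data

    base = panel.baseline().set_index("subject_id")
    n_subj = len(base)
    ids = base.index.to_numpy()

    # per-subject time-constant attributes
    band = np.where(base["age_80p"], "80+", np.where(base["age_70_79"], "70-79", "60-69"))
    age = np.select(
        [band == "60-69", band == "70-79"],
        [rng.integers(60, 70, n_subj), rng.integers(70, 80, n_subj)],
        rng.integers(80, 95, n_subj),
    )
    female = base["female"].to_numpy()
    height = np.where(
        female, rng.normal(156, 6, n_subj), rng.normal(168, 6, n_subj)
    ).round(1)
    cesd = np.where(
        base["depression"], rng.integers(10, 31, n_subj), rng.integers(0, 10, n_subj)
    )
    sleep = np.select(
        [base["sleep_short"].astype(bool), base["sleep_long"].astype(bool)],
        [rng.uniform(3.5, 5.5, n_subj).round(1), rng.uniform(9.5, 11.5, n_subj).round(1)],
        rng.uniform(6.0, 9.0, n_subj).round(1),
    )
    ncond = np.where(
        base["multimorbidity"], rng.integers(2, 6, n_subj), rng.integers(0, 2, n_subj)
    )
    subj_attr = pd.DataFrame(
        {
            "age": age, "band": band, "height_cm": height, "cesd_total": cesd,
            "sleep_hours": sleep, "n_conditions": ncond, "female": female,
            "falls": base["falls"].to_numpy(), "injury": base["injury"].to_numpy(),
            "life_satisfied": 1 - base["dissatisfied"].to_numpy(),
            "literacy": base["literacy"].to_numpy(), "rural": base["rural"].to_numpy(),
        },
        index=ids,
    )

    rows = []
    for _, r in df.iterrows():
        sid = int(r["subject_id"])
        a = subj_attr.loc[sid]
        rec: dict = {
            "subject_id": sid, "time_years": float(r["time_years"]),
            "dead": int(r["state"] == 5),
            "age": int(a["age"]), "female": int(a["female"]),
            "height_cm": float(a["height_cm"]), "cesd_total": int(a["cesd_total"]),
            "sleep_hours": float(a["sleep_hours"]), "n_conditions": int(a["n_conditions"]),
            "falls": int(a["falls"]), "injury": int(a["injury"]),
            "life_satisfied": int(a["life_satisfied"]),
            "literacy": int(a["literacy"]), "rural": int(a["rural"]),
        }
        if rec["dead"]:
            rows.append(rec)
            continue
        state = int(r["state"])
        is_ci, is_pf = state in (2, 4), state in (3, 4)

        mean, sd = norms[str(a["band"])]
        thr = mean - sd
        if is_ci:
            total = _half_point_between(max(0.0, thr - 2 * sd), thr - 0.5, rng)
        else:
            total = _half_point_between(thr, 21.0, rng)
        tics, imm, dele, pent = _decompose_cognition(total, rng)
        rec.update(tics=tics, recall_immediate=imm, recall_delayed=dele, pentagon=pent)

        if is_pf:
            score = int(rng.choice(5, p=_FRAILTY_SCORE_PROBS)) + 1
            which = rng.choice(5, size=score, replace=False)
            comp = np.zeros(5, dtype=int)
            comp[which] = 1
        else:
            comp = np.zeros(5, dtype=int)
        shrink, weak, slow, lowact, exh = comp
        gender = "female" if rec["female"] else "male"
        bmi = (
            round(rng.uniform(16.0, cutoffs.bmi_shrinking_threshold - 0.1), 1)
            if shrink
            else round(rng.uniform(19.5, 32.0), 1)
        )
        gcut = cutoffs.grip_cutoff(gender, bmi)
        grip = round(gcut - rng.uniform(2, 8), 1) if weak else round(gcut + rng.uniform(2, 15), 1)
        scut = cutoffs.gait_cutoff(gender, rec["height_cm"])
        gait = (
            round(max(0.05, scut - rng.uniform(0.1, 0.4)), 3)
            if slow
            else round(scut + rng.uniform(0.05, 0.6), 3)
        )
        t_item = cutoffs.cesd_item_threshold
        if exh:
            eff, gg = int(rng.integers(t_item, 4)), int(rng.integers(0, 4))
            if gg >= t_item and rng.random() < 0.5:
                gg = int(rng.integers(0, t_item))
        else:
            eff, gg = int(rng.integers(0, t_item)), int(rng.integers(0, t_item))
        rec.update(
            bmi=bmi, grip_kg=max(grip, 1.0), gait_speed=gait, walks_10min=int(not lowact),
            cesd_effort=eff, cesd_get_going=gg,
        )
        rows.append(rec)

    raw = pd.DataFrame(rows)
    return RawMeasureCohort(raw=raw, panel=panel, norms=norms, cutoffs=cutoffs, config=cfg)
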