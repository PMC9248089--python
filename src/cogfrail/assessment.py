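"""Model assessment: observed vs expected prevalence, a Pearson-type
goodness-of-fit test with a parametric-bootstrap p-value, and the
likelihood-ratio test for nested transition structures."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.stats import chi2

from .ctmc import FitResult, fit_panel_markov, transition_probability
from .panel import PanelDataset
from .states import StateSpace


# ----------------------------------------------------------------------
# prevalence
# ----------------------------------------------------------------------


@dataclass
class PrevalenceSeries:
    """Observed and model-expected state prevalence at evaluation times.

    Expected prevalence conditions on the observed baseline state
    distribution: expected(s, t) = sum_r pi_r(0) P_{r,s}(t).  Observed
    prevalence counts subjects by recorded state at each time, with
    deaths carried forward (death is a state, so the denominator keeps
    the dead)."""

    times: np.ndarray
    observed_counts: pd.DataFrame  # index times, columns state names
    observed: pd.DataFrame         # fractions
    expected: pd.DataFrame         # fractions


def expected_prevalence(
    fit: FitResult, data: PanelDataset, times: list[float]
) -> PrevalenceSeries:
    if data.n_subjects == 0:
        raise ValueError("empty cohort")
    space = fit.space
    names = [space.name(c) for c in sorted(space.labels)]
    base = data.baseline()
    t0 = float(base["time_years"].min())
    pi0 = np.zeros(space.n_states)
    for s, c in base["state"].value_counts().items():
        pi0[int(s) - 1] = c
    pi0 = pi0 / pi0.sum()

    exp_rows, obs_rows = [], []
    df = data.data
    death_states = set(space.absorbing)
    death_time = {
        sid: t for sid, t, s in zip(df["subject_id"], df["time_years"], df["state"])
        if s in death_states
    }
    for t in times:
        P = fit.transition_probability(t - t0)
        exp_rows.append(pi0 @ P)
        at_t = df[df["time_years"] == t]
        counts = np.zeros(space.n_states)
        for s, c in at_t["state"].value_counts().items():
            counts[int(s) - 1] += c
        seen = set(at_t["subject_id"])
        for sid, td in death_time.items():
            if td < t and sid not in seen:
                counts[next(iter(death_states)) - 1] += 1
        obs_rows.append(counts)

    times_arr = np.asarray(times, dtype=float)
    obs_counts = pd.DataFrame(obs_rows, index=times_arr, columns=names)
    denom = obs_counts.sum(axis=1)
    observed = obs_counts.div(denom.replace(0, np.nan), axis=0)
    expected = pd.DataFrame(exp_rows, index=times_arr, columns=names)
    return PrevalenceSeries(times_arr, obs_counts, observed, expected)


def plot_prevalence(series: PrevalenceSeries, path) -> None:
    """Diagnostic plot: observed prevalence (points) against the model's
    expected prevalence (lines) per state."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    states = list(series.expected.columns)
    fig, axes = plt.subplots(1, len(states), figsize=(3 * len(states), 3), sharey=True)
    for ax, s in zip(np.atleast_1d(axes), states):
        ax.plot(series.expected.index, series.expected[s], "-", label="expected")
        ax.plot(series.observed.index, series.observed[s], "o", label="observed")
        ax.set_title(s)
        ax.set_xlabel("years")
    np.atleast_1d(axes)[0].set_ylabel("prevalence")
    np.atleast_1d(axes)[0].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ----------------------------------------------------------------------
# Pearson-type goodness of fit
# ----------------------------------------------------------------------


@dataclass
class GofResult:
    """Pearson-type statistic over (from-state, to-state, interval) cells
    with a parametric-bootstrap p-value."""

    statistic: float
    p_value: float
    table: pd.DataFrame  # cell-level observed and expected counts
    n_boot: int


def _gof_statistic(fit: FitResult, data: PanelDataset) -> tuple[float, pd.DataFrame]:
    space = fit.space
    pairs = data.transition_pairs()
    rows = []
    stat = 0.0
    for (dt, r), g in pairs.groupby(["dt", "from_state"], sort=True):
        n_r = len(g)
        P = fit.transition_probability(float(dt))
        obs = g["to_state"].value_counts()
        for s in sorted(space.labels):
            e = n_r * float(P[int(r) - 1, s - 1])
            o = float(obs.get(s, 0))
            if e <= 0:
                if o > 0:
                    warnings.warn(
                        f"observed transitions in a zero-expectation cell "
                        f"({r}->{s}, dt={dt}); cell collapsed", RuntimeWarning
                    )
                continue
            stat += (o - e) ** 2 / e
            rows.append(
                {"dt": float(dt), "from_state": int(r), "to_state": int(s),
                 "observed": o, "expected": e}
            )
    return stat, pd.DataFrame(rows)


def _resample_panel(
    Q: np.ndarray,
    baseline_states: np.ndarray,
    wave_times: np.ndarray,
    space: StateSpace,
    rng: np.random.Generator,
) -> PanelDataset:
    """Panel data simulated from generator Q on a common wave grid —
    multinomial stepping with P(dt), which is the exact panel law."""
    n, W = len(baseline_states), len(wave_times)
    states = np.zeros((n, W), dtype=int)
    states[:, 0] = baseline_states
    for w in range(1, W):
        P = expm(Q * (wave_times[w] - wave_times[w - 1]))
        cur = states[:, w - 1]
        nxt = np.zeros(n, dtype=int)
        for s in np.unique(cur):
            idx = np.flatnonzero(cur == s)
            p = np.clip(P[s - 1], 0, None)
            nxt[idx] = rng.choice(space.n_states, size=idx.size, p=p / p.sum()) + 1
        states[:, w] = nxt
    death = set(space.absorbing)
    rows = []
    for i in range(n):
        for w in range(W):
            s = int(states[i, w])
            rows.append((i + 1, float(wave_times[w]), s))
            if s in death:
                break
    return PanelDataset(
        pd.DataFrame(rows, columns=["subject_id", "time_years", "state"]),
        covariates=(),
        space=space,
    )


def pearson_type_gof(
    fit: FitResult,
    data: PanelDataset,
    n_boot: int = 200,
    seed: int | None = None,
) -> GofResult:
    """Pearson-type goodness-of-fit test for the fitted panel model.

    Cells are one per (from-state, to-state, observation-interval
    length); the statistic is sum (obs - exp)^2 / exp.  Because the
    statistic's null distribution is not chi-square under panel
    observation, the p-value is computed by parametric bootstrap:
    ``n_boot`` cohorts are simulated from the fitted generator on the
    cohort's wave grid (same baseline states), the model refit to each,
    and the statistic recomputed.  Subject-specific covariate effects
    are not supported — the test applies to the baseline model.
    """
    if fit.effects:
        raise NotImplementedError("goodness-of-fit bootstrap applies to the baseline model")
    stat, table = _gof_statistic(fit, data)
    rng = np.random.default_rng(seed)
    Q = fit.intensity_matrix()
    baseline_states = data.baseline()["state"].to_numpy(int)
    waves = data.wave_times
    init = fit.rates()
    exceed = 0
    for _ in range(n_boot):
        sim = _resample_panel(Q, baseline_states, waves, fit.space, rng)
        refit = fit_panel_markov(
            sim, fit.space, init=init, death_convention=fit.death_convention,
            compute_cov=False,
        )
        stat_b, _ = _gof_statistic(refit, sim)
        if stat_b >= stat:
            exceed += 1
    p = (1 + exceed) / (n_boot + 1)
    return GofResult(statistic=float(stat), p_value=float(p), table=table, n_boot=n_boot)


# ----------------------------------------------------------------------
# likelihood ratio test
# ----------------------------------------------------------------------


@dataclass
class LrtResult:
    G: float
    df: int
    p_value: float


def likelihood_ratio_test(fit_full: FitResult, fit_nested: FitResult) -> LrtResult:
    """G = 2 (loglik_full - loglik_nested) against chi-square(df), df =
    difference in free parameter count.

    The nested model's transitions and covariate effects must be subsets
    of the full model's, fitted to the same data under the same death
    convention.
    """
    full_t, nested_t = set(fit_full.transitions), set(fit_nested.transitions)
    full_e = {(t, c) for t, cs in fit_full.effects.items() for c in cs}
    nested_e = {(t, c) for t, cs in fit_nested.effects.items() for c in cs}
    if not (nested_t <= full_t and nested_e <= full_e):
        raise ValueError("models are not nested (transitions/effects not a subset)")
    if (fit_full.n_subjects, fit_full.death_convention) != (
        fit_nested.n_subjects, fit_nested.death_convention
    ):
        raise ValueError("models appear to be fitted to different data")
    # small negatives arise from finite optimizer tolerance when the extra
    # parameters are uninformative; clip those, flag anything larger
    G = 2.0 * (fit_full.loglik - fit_nested.loglik)
    if G < -0.01:
        raise ValueError(
            f"full model has lower likelihood than nested (G={G:.3g}); "
            "check optimizer convergence"
        )
    G = max(G, 0.0)
    df = fit_full.n_params - fit_nested.n_params
    p = float(chi2.sf(G, df)) if df >= 1 else 1.0
    return LrtResult(G=float(G), df=int(df), p_value=p)
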