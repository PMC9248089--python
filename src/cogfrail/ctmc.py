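"""Continuous-time Markov machinery for panel-observed multi-state data.

The model is time-homogeneous: movement on the state space is governed
by a generator (transition-intensity) matrix Q whose off-diagonal entry
q_rs is the instantaneous per-year rate of moving from state r to state
s, with diagonal q_rr = -sum of the exit rates.  Transition
probabilities over an interval of length u solve the Kolmogorov
differential equations, P(u) = expm(Q u), and the time spent in a
single stay in state r is exponential with mean -1/q_rr.

Subjects are observed only at discrete visit times (panel data), so the
likelihood of a subject's path is the product of P_{s_i, s_{i+1}}(dt_i)
over consecutive observation pairs; exact transition times are never
used except, optionally, for death (see ``death_convention``).
Intensities are estimated by maximising this likelihood over log-rates,
so positivity is structural.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .panel import PanelDataset
from .states import FIVE_STATE, StateSpace, StructuralZeroError

DEATH_CONVENTIONS = ("interval", "exact")

# ----------------------------------------------------------------------
# generator construction and elementary quantities
# ----------------------------------------------------------------------


def build_intensity_matrix(
    rates: dict[tuple[int, int], float], space: StateSpace = FIVE_STATE
) -> np.ndarray:
    """Assemble the full generator matrix from per-transition rates.

    Structural zeros are enforced: supplying a rate for a forbidden
    transition raises :class:`StructuralZeroError`.  The diagonal is
    computed as minus the row sum of exit rates, and absorbing rows are
    identically zero.
    """
    n = space.n_states
    allowed = set(space.allowed)
    Q = np.zeros((n, n))
    for (r, s), v in rates.items():
        if (r, s) not in allowed:
            raise StructuralZeroError(
                f"transition ({r},{s}) = "
                f"({space.name(r)}->{space.name(s)}) is structurally forbidden"
            )
        if v < 0:
            raise ValueError(f"negative intensity for transition ({r},{s}): {v}")
        Q[r - 1, s - 1] = v
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_probability(Q: np.ndarray, u: float) -> np.ndarray:
    """Transition-probability matrix P(u) = expm(Q u) for interval u >= 0."""
    if u < 0:
        raise ValueError(f"interval length must be non-negative, got {u}")
    return expm(np.asarray(Q, dtype=float) * float(u))


def mean_sojourn_times(Q: np.ndarray, space: StateSpace = FIVE_STATE) -> dict[str, float]:
    """Mean sojourn time -1/q_rr per transient state, in years.

    A state with zero total exit rate has an infinite mean sojourn,
    reported as ``inf`` rather than an error.
    """
    Q = np.asarray(Q, dtype=float)
    out: dict[str, float] = {}
    for r in space.transient:
        exit_rate = -Q[r - 1, r - 1]
        out[space.name(r)] = float(1.0 / exit_rate) if exit_rate > 0 else float("inf")
    return out


# ----------------------------------------------------------------------
# panel likelihood
# ----------------------------------------------------------------------


class _PanelLikelihood:
    """Aggregated panel log-likelihood over log-rates and covariate effects.

    Observation pairs are grouped by (covariate pattern, interval
    length, from-state, to-state); the log-likelihood is then a weighted
    sum of log P entries with one matrix exponential per (pattern,
    interval) — the expensive part is independent of cohort size.
    """

    def __init__(
        self,
        data: PanelDataset,
        space: StateSpace,
        effects: dict[tuple[int, int], tuple[str, ...]] | None = None,
        death_convention: str = "interval",
    ) -> None:
        if death_convention not in DEATH_CONVENTIONS:
            raise ValueError(f"death_convention must be one of {DEATH_CONVENTIONS}")
        self.space = space
        self.effects = {t: tuple(v) for t, v in (effects or {}).items()}
        for t in self.effects:
            if t not in set(space.allowed):
                raise StructuralZeroError(f"covariate effect on forbidden transition {t}")
        self.death_convention = death_convention
        self.transitions = list(space.allowed)
        self.cov_names = sorted({c for cs in self.effects.values() for c in cs})
        missing = [c for c in self.cov_names if c not in data.covariates]
        if missing:
            raise ValueError(f"covariates named in the model are absent from the data: {missing}")

        self.param_names = [
            f"log_q_{space.name(r)}->{space.name(s)}" for r, s in self.transitions
        ] + [f"beta_{space.name(r)}->{space.name(s)}:{c}"
             for (r, s), cs in sorted(self.effects.items()) for c in cs]
        self._beta_slots = [
            (t, c) for t, cs in sorted(self.effects.items()) for c in cs
        ]
        self.n_params = len(self.param_names)

        pairs = data.transition_pairs()
        self.n_pairs = len(pairs)
        self.n_subjects = data.n_subjects

        key_cols = self.cov_names if self.cov_names else []
        if key_cols:
            grouped = pairs.groupby(key_cols, sort=True)
            groups = [(k if isinstance(k, tuple) else (k,), g) for k, g in grouped]
        else:
            groups = [((), pairs)]

        absorbing = set(space.absorbing)
        self._patterns = []
        for key, g in groups:
            x = dict(zip(key_cols, key))
            interval: dict[float, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
            exact: dict[tuple[float, int], tuple[np.ndarray, np.ndarray]] = {}
            if death_convention == "exact":
                is_death = g["to_state"].isin(absorbing)
                death_part, g = g[is_death], g[~is_death]
                for (dt, a), gg in death_part.groupby(["dt", "to_state"], sort=True):
                    cnt = gg.groupby("from_state").size()
                    exact[(float(dt), int(a))] = (
                        cnt.index.to_numpy(int) - 1,
                        cnt.to_numpy(float),
                    )
            for dt, gg in g.groupby("dt", sort=True):
                cnt = gg.groupby(["from_state", "to_state"]).size()
                idx = np.array([list(i) for i in cnt.index], dtype=int) - 1
                interval[float(dt)] = (idx[:, 0], idx[:, 1], cnt.to_numpy(float))
            self._patterns.append((x, interval, exact))

    # -- parameter plumbing --------------------------------------------
    def split(self, theta: np.ndarray) -> tuple[dict, dict]:
        nq = len(self.transitions)
        rates = {t: float(np.exp(v)) for t, v in zip(self.transitions, theta[:nq])}
        beta = {slot: float(v) for slot, v in zip(self._beta_slots, theta[nq:])}
        return rates, beta

    def pattern_generator(self, theta: np.ndarray, x: dict) -> np.ndarray:
        rates, beta = self.split(theta)
        adj = dict(rates)
        for (t, c), b in beta.items():
            adj[t] = adj[t] * float(np.exp(b * float(x.get(c, 0.0))))
        return build_intensity_matrix(adj, self.space)

    # -- the objective -------------------------------------------------
    def loglik(self, theta: np.ndarray) -> float:
        total = 0.0
        for x, interval, exact in self._patterns:
            Q = self.pattern_generator(theta, x)
            dts = {dt for dt in interval} | {dt for dt, _ in exact}
            for dt in sorted(dts):
                P = expm(Q * dt)
                if dt in interval:
                    i, j, cnt = interval[dt]
                    p = np.clip(P[i, j], 1e-300, None)
                    total += float(cnt @ np.log(p))
                for (dt_d, a), (i, cnt) in exact.items():
                    if dt_d == dt:
                        dens = np.clip(P @ Q[:, a - 1], 1e-300, None)
                        total += float(cnt @ np.log(dens[i]))
        return total if np.isfinite(total) else -1e12

    def negloglik(self, theta: np.ndarray) -> float:
        return -self.loglik(theta)


def panel_loglik(
    Q: np.ndarray,
    data: PanelDataset,
    space: StateSpace = FIVE_STATE,
    death_convention: str = "interval",
) -> float:
    """Log-likelihood of panel data under a fixed generator Q.

    Each subject contributes the sum of log P_{s_i,s_{i+1}}(dt_i) over
    its consecutive observation pairs; a subject with a single
    observation contributes 0.  Under ``death_convention="exact"`` a
    pair ending in death instead contributes
    log( sum_r P_{s_i,r}(dt) q_{r,death} ), treating the death time as
    known up to the visit interval but the pre-death state as unknown.
    """
    Q = np.asarray(Q, dtype=float)
    lik = _PanelLikelihood(data, space, None, death_convention)
    theta = np.log(np.clip([Q[r - 1, s - 1] for r, s in lik.transitions], 1e-300, None))
    return lik.loglik(np.asarray(theta))


# ----------------------------------------------------------------------
# fit result
# ----------------------------------------------------------------------


@dataclass
class FitResult:
    """Maximum-likelihood fit of a panel multi-state Markov model."""

    space: StateSpace
    transitions: list[tuple[int, int]]
    effects: dict[tuple[int, int], tuple[str, ...]]
    param_names: list[str]
    theta: np.ndarray
    cov: np.ndarray | None
    loglik: float
    converged: bool
    n_iter: int
    message: str
    death_convention: str
    n_subjects: int
    n_pairs: int
    warnings: list[str] = field(default_factory=list)
    trace: list[float] = field(default_factory=list)

    # ------------------------------------------------------------------
    @classmethod
    def from_rates(
        cls,
        rates: dict[tuple[int, int], float],
        space: StateSpace = FIVE_STATE,
        death_convention: str = "interval",
    ) -> "FitResult":
        """Wrap known intensities as a (non-fitted) result, e.g. to
        evaluate model-implied quantities at externally given rates."""
        transitions = list(space.allowed)
        theta = np.log(np.clip([rates.get(t, 0.0) for t in transitions], 1e-300, None))
        return cls(
            space=space,
            transitions=transitions,
            effects={},
            param_names=[
                f"log_q_{space.name(r)}->{space.name(s)}" for r, s in transitions
            ],
            theta=np.asarray(theta),
            cov=None,
            loglik=float("nan"),
            converged=True,
            n_iter=0,
            message="fixed rates (not fitted)",
            death_convention=death_convention,
            n_subjects=0,
            n_pairs=0,
        )

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def se(self) -> np.ndarray:
        if self.cov is None:
            return np.full(self.n_params, np.nan)
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def rates(self) -> dict[tuple[int, int], float]:
        """Baseline intensity estimates on the rate scale."""
        nq = len(self.transitions)
        return {t: float(np.exp(v)) for t, v in zip(self.transitions, self.theta[:nq])}

    def betas(self) -> dict[tuple[tuple[int, int], str], float]:
        nq = len(self.transitions)
        slots = [(t, c) for t, cs in sorted(self.effects.items()) for c in cs]
        return {s: float(v) for s, v in zip(slots, self.theta[nq:])}

    def intensity_matrix(self, x: dict | None = None) -> np.ndarray:
        """Fitted generator, optionally at covariate vector ``x``
        (reference level x=0 when omitted)."""
        rates = self.rates()
        if x:
            for (t, c), b in self.betas().items():
                rates[t] = rates[t] * float(np.exp(b * float(x.get(c, 0.0))))
        return build_intensity_matrix(rates, self.space)

    def transition_probability(self, u: float, x: dict | None = None) -> np.ndarray:
        return transition_probability(self.intensity_matrix(x), u)

    def rate_table(self, level: float = 0.95) -> pd.DataFrame:
        """Intensity estimates with log-normal confidence intervals
        (symmetric on the log scale, hence asymmetric on the rate scale)."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        se = self.se
        rows = []
        for k, (r, s) in enumerate(self.transitions):
            est = np.exp(self.theta[k])
            lo, hi = np.exp(self.theta[k] - z * se[k]), np.exp(self.theta[k] + z * se[k])
            rows.append(
                {
                    "transition": f"{self.space.name(r)}-{self.space.name(s)}",
                    "from_state": r,
                    "to_state": s,
                    "intensity": est,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
        return pd.DataFrame(rows)

    def probability_table(self, u: float = 1.0, level: float = 0.95) -> pd.DataFrame:
        """Transition probabilities over an interval of length ``u``
        (point estimates; reference covariate level)."""
        P = self.transition_probability(u)
        rows = []
        for r in self.space.transient:
            for s in sorted(self.space.labels):
                rows.append(
                    {
                        "transition": f"{self.space.name(r)}-{self.space.name(s)}",
                        "from_state": r,
                        "to_state": s,
                        "probability": float(P[r - 1, s - 1]),
                    }
                )
        return pd.DataFrame(rows)

    def sojourn_table(self) -> pd.DataFrame:
        soj = mean_sojourn_times(self.intensity_matrix(), self.space)
        return pd.DataFrame(
            [{"state": k, "mean_sojourn_years": v} for k, v in soj.items()]
        )

    def hazard_ratios(self, level: float = 0.95) -> pd.DataFrame:
        """Wald hazard-ratio table: exp(beta) with symmetric-on-log CIs."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        nq = len(self.transitions)
        se = self.se
        rows = []
        for k, ((r, s), c) in enumerate(
            [(t, c) for t, cs in sorted(self.effects.items()) for c in cs]
        ):
            b, sb = self.theta[nq + k], se[nq + k]
            pz = 2 * norm.sf(abs(b / sb)) if sb > 0 else np.nan
            rows.append(
                {
                    "transition": f"{self.space.name(r)}-{self.space.name(s)}",
                    "from_state": r,
                    "to_state": s,
                    "covariate": c,
                    "hr": float(np.exp(b)),
                    "ci_low": float(np.exp(b - z * sb)),
                    "ci_high": float(np.exp(b + z * sb)),
                    "p_value": float(pz),
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "param_names": self.param_names,
            "estimates": [float(v) for v in self.theta],
            "se": [float(v) for v in self.se],
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "n_subjects": int(self.n_subjects),
            "n_pairs": int(self.n_pairs),
            "death_convention": self.death_convention,
            "warnings": list(self.warnings),
        }


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

_LOG_RATE_BOUNDS = (-12.0, 4.0)
_BETA_BOUNDS = (-8.0, 8.0)


def crude_rates(data: PanelDataset, space: StateSpace, floor: float = 1e-3) -> dict:
    """Crude initial rates: observed r->s panel pairs divided by
    person-years spent with state r at the interval start, floored."""
    pairs = data.transition_pairs()
    py = pairs.groupby("from_state")["dt"].sum()
    cnt = pairs.groupby(["from_state", "to_state"]).size()
    init = {}
    for r, s in space.allowed:
        c = float(cnt.get((r, s), 0.0))
        denom = float(py.get(r, 0.0))
        init[(r, s)] = max(c / denom, floor) if denom > 0 else 0.1
    return init


def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    p = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _covariance_from_hessian(lik: _PanelLikelihood, theta: np.ndarray, warn: list[str]):
    H = _numerical_hessian(lik.negloglik, theta)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        warn.append("observed information singular; covariance from pseudo-inverse")
    cov = (cov + cov.T) / 2
    if np.any(np.diag(cov) < 0):
        warn.append(
            "negative variance from observed information (flat likelihood "
            "direction); affected intervals unreliable"
        )
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        cov = cov.copy()
        np.fill_diagonal(cov, d)
    return cov


def _fit(
    lik: _PanelLikelihood,
    init_theta: np.ndarray,
    compute_cov: bool,
    maxiter: int,
) -> FitResult:
    bounds = [_LOG_RATE_BOUNDS] * len(lik.transitions) + [_BETA_BOUNDS] * (
        lik.n_params - len(lik.transitions)
    )
    trace: list[float] = []

    def obj(th):
        v = lik.negloglik(th)
        trace.append(-v)
        return v

    res = minimize(
        obj,
        init_theta,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
    )
    warn: list[str] = []
    if not res.success:
        warn.append(f"optimizer did not report convergence: {res.message}")
    nq = len(lik.transitions)
    at_bound = [
        lik.transitions[k]
        for k in range(nq)
        if res.x[k] <= _LOG_RATE_BOUNDS[0] + 1e-6
    ]
    for t in at_bound:
        warn.append(
            f"rate for transition {t} pinned at the lower bound "
            f"(~{np.exp(_LOG_RATE_BOUNDS[0]):.1e}/yr); no information in the data"
        )
    cov = _covariance_from_hessian(lik, res.x, warn) if compute_cov else None
    return FitResult(
        space=lik.space,
        transitions=list(lik.transitions),
        effects=dict(lik.effects),
        param_names=list(lik.param_names),
        theta=np.asarray(res.x, dtype=float),
        cov=cov,
        loglik=float(-res.fun),
        converged=bool(res.success),
        n_iter=int(res.nit),
        message=str(res.message),
        death_convention=lik.death_convention,
        n_subjects=lik.n_subjects,
        n_pairs=lik.n_pairs,
        warnings=warn,
        trace=trace,
    )


def fit_panel_markov(
    data: PanelDataset,
    space: StateSpace = FIVE_STATE,
    init: dict[tuple[int, int], float] | None = None,
    death_convention: str = "interval",
    effects: dict[tuple[int, int], tuple[str, ...]] | None = None,
    compute_cov: bool = True,
    maxiter: int = 500,
) -> FitResult:
    """Fit the panel multi-state Markov model by maximum likelihood.

    Parameters
    ----------
    data
        Panel observations; every contributing subject needs >= 2 visits.
    space
        State space with allowed transitions; structural zeros are held
        at exactly zero.
    init
        Starting rates per allowed transition.  Defaults to crude rates
        (observed pair counts over person-years at risk, floored at 1e-3).
    death_convention
        "interval" (default): a death observed at a visit is treated
        like any other panel transition.  "exact": the death time is
        taken as exactly the recorded time, with the pre-death state
        marginalised out.
    effects
        Optional proportional-intensity covariate structure, mapping a
        transition to the covariate names multiplying its rate by
        exp(beta' x); fitted jointly with the baseline rates.
    compute_cov
        Compute the observed-information covariance (numerical Hessian).
        Disable for speed inside bootstrap loops.

    Returns
    -------
    FitResult
        Estimates on the log/linear-predictor scale with covariance,
        maximised log-likelihood and convergence diagnostics.  A failed
        line search or iteration cap is flagged via ``converged`` and
        ``warnings``, never silently ignored.
    """
    lik = _PanelLikelihood(data, space, effects, death_convention)
    if lik.n_pairs == 0:
        raise ValueError("no transition pairs: every subject has fewer than 2 observations")
    start = crude_rates(data, space) if init is None else dict(init)
    missing = [t for t in lik.transitions if t not in start]
    if missing:
        raise ValueError(f"initial rates missing for transitions {missing}")
    theta0 = np.log(np.clip([start[t] for t in lik.transitions], 1e-5, None))
    theta0 = np.concatenate([theta0, np.zeros(lik.n_params - len(lik.transitions))])
    result = _fit(lik, theta0, compute_cov, maxiter)
    if not result.converged:
        _warnings.warn(
            f"multi-state fit did not converge: {result.message}", RuntimeWarning
        )
    return result
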