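"""Proportional-intensity covariate effects on transition rates.

A baseline intensity q_rs is multiplied by exp(beta_rs' x) for a
subject with baseline covariate vector x, so exp(beta) is the hazard
ratio of the covariate for that particular transition.  Covariates are
measured at baseline only (no time-varying effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ctmc import FitResult, build_intensity_matrix, fit_panel_markov
from .panel import PanelDataset
from .states import FIVE_STATE, StateSpace

#: The four transitions covariate effects are reported on by default:
#: progression to CF (from CI and from PF) and improvement out of CF
#: (to CI and to PF).
DEFAULT_EFFECT_TRANSITIONS: tuple[tuple[int, int], ...] = ((2, 4), (3, 4), (4, 2), (4, 3))


@dataclass(frozen=True)
class CovariateModelSpec:
    """Which covariates act on which transitions.

    ``effects`` maps an allowed transition to the tuple of covariate
    column names whose linear combination scales that transition's
    baseline rate.
    """

    effects: dict[tuple[int, int], tuple[str, ...]] = field(default_factory=dict)

    @classmethod
    def uniform(
        cls,
        covariates: tuple[str, ...] | list[str],
        transitions: tuple[tuple[int, int], ...] = DEFAULT_EFFECT_TRANSITIONS,
    ) -> "CovariateModelSpec":
        """Same covariate list on every listed transition."""
        return cls({t: tuple(covariates) for t in transitions})

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(sorted({c for cs in self.effects.values() for c in cs}))

    def validate(self, data: PanelDataset, space: StateSpace) -> None:
        allowed = set(space.allowed)
        for t in self.effects:
            if t not in allowed:
                raise ValueError(f"covariate effect on forbidden transition {t}")
        for c in self.covariate_names:
            if c not in data.covariates:
                raise ValueError(
                    f"covariate {c!r} not in the dataset (available: {list(data.covariates)})"
                )


def apply_covariates(
    Q0: np.ndarray,
    beta: dict[tuple[tuple[int, int], str], float],
    x: dict[str, float],
    space: StateSpace = FIVE_STATE,
) -> np.ndarray:
    """Subject-specific generator q_rs(x) = q_rs0 * exp(beta_rs' x).

    Structural zeros are preserved and the diagonal recomputed.  With
    all betas zero, or x at the reference level (all zeros), Q0 is
    returned unchanged.
    """
    Q0 = np.asarray(Q0, dtype=float)
    rates = {(r, s): float(Q0[r - 1, s - 1]) for r, s in space.allowed}
    for ((r, s), c), b in beta.items():
        if (r, s) not in rates:
            raise ValueError(f"beta supplied for forbidden transition ({r},{s})")
        if c not in x:
            raise KeyError(f"covariate {c!r} missing from the covariate vector")
        rates[(r, s)] *= float(np.exp(b * float(x[c])))
    return build_intensity_matrix(rates, space)


def fit_covariate_model(
    data: PanelDataset,
    spec: CovariateModelSpec,
    space: StateSpace = FIVE_STATE,
    init: dict[tuple[int, int], float] | None = None,
    death_convention: str = "interval",
    compute_cov: bool = True,
    maxiter: int = 500,
) -> FitResult:
    """Joint maximum likelihood over baseline log-rates and betas.

    Degenerate covariate columns (constant over subjects) carry no
    information and raise immediately; a covariate level with no events
    on its transition yields a separation-style unstable estimate,
    flagged through ``FitResult.warnings`` when |beta| or its standard
    error is extreme.
    """
    spec.validate(data, space)
    base = data.baseline()
    for c in spec.covariate_names:
        if base[c].nunique() <= 1:
            raise ValueError(
                f"covariate {c!r} is constant at baseline; its effect is not estimable"
            )
    fit = fit_panel_markov(
        data,
        space=space,
        init=init,
        death_convention=death_convention,
        effects=spec.effects,
        compute_cov=compute_cov,
        maxiter=maxiter,
    )
    nq = len(fit.transitions)
    se = fit.se
    for k, name in enumerate(fit.param_names[nq:]):
        b, sb = fit.theta[nq + k], se[nq + k]
        if abs(b) > 5 or (np.isfinite(sb) and sb > 10):
            fit.warnings.append(
                f"{name}: unstable estimate (|beta|={abs(b):.2f}, se={sb:.2f}); "
                "possible separation — a covariate level with no events on this transition"
            )
    return fit


def hazard_ratio_table(fit: FitResult) -> pd.DataFrame:
    """Per-transition hazard ratios with Wald 95% intervals, grouped as
    progression (into CF) and improvement (out of CF) transitions."""
    tab = fit.hazard_ratios()
    direction = {
        (2, 4): "progression", (3, 4): "progression",
        (4, 2): "improvement", (4, 3): "improvement",
    }
    tab["direction"] = [
        direction.get((r, s), "other") for r, s in zip(tab["from_state"], tab["to_state"])
    ]
    return tab


@dataclass
class ScreenResult:
    """Outcome of the two-step (univariate then multivariate) procedure."""

    stage1: dict[str, pd.DataFrame]
    selected: list[str]
    final_fit: FitResult | None
    final_table: pd.DataFrame
    note: str = ""


def screen_then_fit(
    data: PanelDataset,
    candidates: list[str],
    transitions: tuple[tuple[int, int], ...] = DEFAULT_EFFECT_TRANSITIONS,
    alpha: float = 0.05,
    space: StateSpace = FIVE_STATE,
    death_convention: str = "interval",
) -> ScreenResult:
    """Univariate screening followed by a joint multivariate fit.

    Stage 1 fits one covariate at a time (on all ``transitions``) and
    keeps those with a Wald p-value below ``alpha`` on any modelled
    transition.  Stage 2 refits the kept covariates jointly; if nothing
    survives screening the stage-1 table is returned with a note.
    """
    if not candidates:
        raise ValueError("candidate covariate list is empty")
    stage1: dict[str, pd.DataFrame] = {}
    selected: list[str] = []
    for c in candidates:
        fit = fit_covariate_model(
            data, CovariateModelSpec.uniform([c], transitions), space,
            death_convention=death_convention,
        )
        tab = hazard_ratio_table(fit)
        stage1[c] = tab
        if (tab["p_value"] < alpha).any():
            selected.append(c)
    if not selected:
        combined = pd.concat(stage1.values(), ignore_index=True)
        return ScreenResult(
            stage1, [], None, combined,
            note="no covariate significant in univariate screening; "
            "returning stage-1 table",
        )
    if len(selected) == len(candidates) == 1:
        # single candidate: the multivariate model is the univariate one
        only = candidates[0]
        return ScreenResult(stage1, selected, None, stage1[only])
    final = fit_covariate_model(
        data, CovariateModelSpec.uniform(selected, transitions), space,
        death_convention=death_convention,
    )
    return ScreenResult(stage1, selected, final, hazard_ratio_table(final))
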