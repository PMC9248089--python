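"""End-to-end analysis pipeline: simulate (or read) a panel, fit the
baseline multi-state model, fit covariate effects, assess fit, and
summarise descriptives, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .assessment import expected_prevalence, likelihood_ratio_test, pearson_type_gof, plot_prevalence
from .covariates import DEFAULT_EFFECT_TRANSITIONS, screen_then_fit
from .ctmc import fit_panel_markov
from .descriptive import (
    baseline_table,
    cumulative_mortality,
    followup_distribution,
    improvement_rate_cf,
    incidence_rate_cf,
)
from .io import read_panel, write_fit, write_panel
from .panel import PanelDataset
from .simulate import SimulationConfig, simulate_cohort
from .states import FIVE_STATE, FIVE_STATE_FREE_NSCF

log = logging.getLogger("cogfrail")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: str = "cogfrail_out"
    panel_path: str | None = None      # read a panel instead of simulating
    n_subjects: int = 4051
    seed: int = 0
    death_convention: str = "interval"
    py_convention: str = "censor_death"
    covariates: tuple[str, ...] = ("depression", "literacy")
    gof_boot: int = 50
    stages: tuple[str, ...] = ("simulate", "fit", "covariates", "assess", "describe")
    dropout: float = 0.0

    def config_hash(self) -> str:
        doc = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in order and write all artifacts.

    Returns the manifest (also written to ``manifest.json``): config
    hash, seed, package version and the artifact paths of each
    completed stage.  A stage failure raises :class:`StageError` after
    writing a partial manifest.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "artifacts": {},
    }

    def _finish(stage, paths):
        manifest["artifacts"][stage] = {k: str(v) for k, v in paths.items()}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    panel: PanelDataset | None = None
    fit = None
    try:
        stage = "simulate"
        if "simulate" in cfg.stages and cfg.panel_path is None:
            sim_cfg = SimulationConfig(
                n_subjects=cfg.n_subjects, seed=cfg.seed, dropout=cfg.dropout
            )
            panel = simulate_cohort(sim_cfg)
            p = out / "panel.csv"
            write_panel(panel, p)
            (out / "truth.json").write_text(json.dumps(sim_cfg.truth(), indent=2))
            log.info("simulated %d subjects, %d rows", panel.n_subjects, len(panel.data))
            _finish(stage, {"panel": p, "truth": out / "truth.json"})
        else:
            panel = read_panel(cfg.panel_path)
            log.info("read %d subjects from %s", panel.n_subjects, cfg.panel_path)
            _finish("read", {"panel": cfg.panel_path})

        if "fit" in cfg.stages:
            stage = "fit"
            fit = fit_panel_markov(panel, FIVE_STATE, death_convention=cfg.death_convention)
            paths = write_fit(fit, out, "fit_baseline")
            _finish(stage, paths)

        if "covariates" in cfg.stages and cfg.covariates:
            stage = "covariates"
            screen = screen_then_fit(
                panel, list(cfg.covariates), DEFAULT_EFFECT_TRANSITIONS,
                death_convention=cfg.death_convention,
            )
            p = out / "hazard_ratios.csv"
            screen.final_table.to_csv(p, index=False)
            note = out / "covariate_note.txt"
            note.write_text(
                (screen.note or f"selected covariates: {screen.selected}") + "\n"
            )
            _finish(stage, {"hazard_ratios": p, "note": note})

        if "assess" in cfg.stages:
            stage = "assess"
            if fit is None:
                fit = fit_panel_markov(panel, FIVE_STATE, death_convention=cfg.death_convention)
            times = [float(t) for t in panel.wave_times]
            prev = expected_prevalence(fit, panel, times)
            pp = out / "prevalence.csv"
            merged = prev.observed.add_prefix("observed_").join(
                prev.expected.add_prefix("expected_")
            )
            merged.to_csv(pp, index_label="time_years")
            plot = out / "prevalence.png"
            plot_prevalence(prev, plot)
            gof = pearson_type_gof(fit, panel, n_boot=cfg.gof_boot, seed=cfg.seed)
            gp = out / "gof.json"
            gp.write_text(
                json.dumps(
                    {"statistic": gof.statistic, "p_value": gof.p_value, "B": gof.n_boot},
                    indent=2,
                )
            )
            fit_free = fit_panel_markov(
                panel, FIVE_STATE_FREE_NSCF, death_convention=cfg.death_convention
            )
            lrt = likelihood_ratio_test(fit_free, fit)
            lp = out / "lrt.json"
            lp.write_text(
                json.dumps({"G": lrt.G, "df": lrt.df, "p_value": lrt.p_value}, indent=2)
            )
            _finish(stage, {"prevalence": pp, "plot": plot, "gof": gp, "lrt": lp})

        if "describe" in cfg.stages:
            stage = "describe"
            inc = incidence_rate_cf(panel, cfg.py_convention)
            imp = improvement_rate_cf(panel, cfg.py_convention)
            fu = followup_distribution(panel)
            mort = cumulative_mortality(panel)
            dp = out / "descriptives.json"
            dp.write_text(
                json.dumps(
                    {
                        "incidence_rate_per100py": inc.rate,
                        "incidence_events": inc.events,
                        "improvement_rate_per100py": imp.rate,
                        "improvement_events": imp.events,
                        "person_year_convention": inc.convention,
                        "cf_free_to_cf_pct": fu.cf_free_to_cf_pct,
                        "cf_to_cf_free_pct": fu.cf_to_cf_free_pct,
                        "cumulative_mortality_cf_pct": mort.cf_pct,
                        "cumulative_mortality_cf_free_pct": mort.cf_free_pct,
                    },
                    indent=2,
                )
            )
            bt = baseline_table(
                panel.baseline(), "state",
                categorical=tuple(c for c in panel.covariates),
            )
            bp = out / "baseline_table.csv"
            bt.to_csv(bp, index=False)
            fp = out / "followup_distribution.csv"
            fu.table.to_csv(fp)
            _finish(stage, {"descriptives": dp, "baseline_table": bp, "followup": fp})
    except Exception as e:  # noqa: BLE001 - re-raised with stage context
        if isinstance(e, StageError):
            raise
        raise StageError(stage, e) from e
    return manifest
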