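"""Readers and writers: panel CSV, raw-measure CSV, fit results and
summary tables.  All files are UTF-8 CSV with a header, '.' decimal,
times in decimal years; empty fields in required columns are rejected."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .ctmc import FitResult
from .panel import PanelDataset
from .states import FIVE_STATE, StateSpace


def read_panel(
    path, covariates: tuple[str, ...] | None = None, space: StateSpace = FIVE_STATE
) -> PanelDataset:
    """Read and validate a long-format panel CSV.

    Validation (required columns present and non-missing, states in the
    label set, strictly increasing times per subject, nothing after
    death) happens in :class:`PanelDataset`; errors name the offence.
    """
    df = pd.read_csv(path)
    return PanelDataset(df, covariates=covariates or (), space=space)


def write_panel(dataset: PanelDataset, path) -> None:
    dataset.data.to_csv(path, index=False)


def write_fit(fit: FitResult, out_dir, stem: str = "fit") -> dict[str, Path]:
    """Serialise a fit: JSON (estimates, CIs, loglik, convergence) plus
    CSV tables of intensities and 1-year probabilities."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    j = out_dir / f"{stem}.json"
    doc = fit.to_dict()
    doc["rate_table"] = fit.rate_table().to_dict(orient="records")
    if fit.effects:
        doc["hazard_ratios"] = fit.hazard_ratios().to_dict(orient="records")
    j.write_text(json.dumps(doc, indent=2))
    paths["json"] = j
    t = out_dir / f"{stem}_intensities.csv"
    fit.rate_table().to_csv(t, index=False)
    paths["intensities"] = t
    p = out_dir / f"{stem}_probabilities_1yr.csv"
    fit.probability_table(1.0).to_csv(p, index=False)
    paths["probabilities"] = p
    s = out_dir / f"{stem}_sojourn.csv"
    fit.sojourn_table().to_csv(s, index=False)
    paths["sojourn"] = s
    return paths


def read_norms(path) -> dict[str, tuple[float, float]]:
    """Age-band cognition norms from a YAML mapping band -> [mean, sd]."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return {str(k): (float(v[0]), float(v[1])) for k, v in doc.items()}


def write_norms(norms: dict[str, tuple[float, float]], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: [float(a), float(b)] for k, (a, b) in norms.items()}, fh)
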