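"""Multi-instrument calibration-transfer experiment.

Calibrations are built from season-A spectra using every non-empty subset of
instruments (for three instruments: 1, 2, 3, 1&2, 2&3, 1&3, All) and each is
validated against season-B spectra from every single instrument plus the
pooled "All" target.  Replicate scans are averaged per (ear, instrument) in
the reflectance domain, converted to absorbance, and pooled across the
subset's instruments, so a three-instrument calibration on N ears sees 3·N
averaged spectra.

The latent-variable count is re-selected per subset by Venetian-blinds CV;
the pretreatment is shared across subsets by default (one survey-chosen or
user-fixed pretreatment, as in a single-table report) but can be re-surveyed
per subset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import evaluate, round_reported
from .pls import CVScheme, PLSModel, calibrate
from .preprocess import PreprocessSpec, optimize_preprocessing
from .spectra import SpectraSet, average_replicates, to_absorbance

__all__ = [
    "TransferDesign",
    "TransferConfig",
    "TransferReport",
    "run_transfer",
    "render_tables",
]


@dataclass(frozen=True)
class TransferDesign:
    """Calibration subsets and validation targets over instrument ids."""

    instrument_ids: tuple

    def __post_init__(self):
        if len(set(self.instrument_ids)) != len(self.instrument_ids):
            raise ValueError("duplicate instrument ids in design")
        if not self.instrument_ids:
            raise ValueError("design needs at least one instrument")

    @property
    def calibration_subsets(self) -> list[tuple]:
        ids = self.instrument_ids
        subsets = []
        for r in range(1, len(ids) + 1):
            subsets.extend(itertools.combinations(ids, r))
        return subsets

    @property
    def validation_targets(self) -> list:
        return list(self.instrument_ids) + ["All"]

    def label(self, subset: tuple) -> str:
        if len(subset) == len(self.instrument_ids):
            return "All"
        return "&".join(str(i) for i in subset)


@dataclass
class TransferConfig:
    """Pipeline settings shared by all subsets."""

    preprocess: PreprocessSpec = field(
        default_factory=lambda: PreprocessSpec.from_shorthand("D-2,2,11"))
    cv: CVScheme = field(default_factory=CVScheme)
    max_lv: int = 20
    divergence_ratio_max: float = 1.25
    survey_per_subset: bool = False   # re-survey pretreatments per subset
    survey_candidates: list | None = None


@dataclass
class TransferReport:
    calibration: pd.DataFrame   # one row per subset
    validation: pd.DataFrame    # one row per (subset, target) cell
    models: dict                # subset label -> PLSModel


def _averaged_absorbance(spectra: SpectraSet) -> SpectraSet:
    """Average replicates per (ear, instrument) then convert to absorbance."""
    if spectra.domain == "reflectance":
        avg = average_replicates(spectra, by=("ear_id", "instrument_id"))
        return to_absorbance(avg)
    return spectra


def run_transfer(cal_spectra: SpectraSet, cal_ref: pd.Series,
                 val_spectra: SpectraSet, val_ref: pd.Series,
                 design: TransferDesign | None = None,
                 config: TransferConfig | None = None) -> TransferReport:
    """Run the full subset-calibration / per-instrument-validation matrix.

    ``cal_ref`` / ``val_ref`` are reference moisture series (%w.b.) indexed
    by ear_id.  A subset with no calibration data is recorded as a failure
    row and the run continues.
    """
    config = config or TransferConfig()
    cal = _averaged_absorbance(cal_spectra)
    val = _averaged_absorbance(val_spectra)
    if cal.grid_fingerprint() != val.grid_fingerprint():
        raise ValueError("calibration and validation spectra grids differ")
    if design is None:
        ids = tuple(sorted(pd.unique(cal.keys["instrument_id"])))
        design = TransferDesign(ids)

    cal_rows, val_rows = [], []
    models: dict[str, PLSModel] = {}
    for subset in design.calibration_subsets:
        label = design.label(subset)
        mask = cal.keys["instrument_id"].isin(subset).to_numpy()
        if not mask.any():
            cal_rows.append({"subset": label, "n": 0, "error": "no calibration data"})
            continue
        sub = cal.select(mask)
        y = cal_ref.loc[sub.keys["ear_id"]].to_numpy(dtype=float)
        spec = config.preprocess
        if config.survey_per_subset:
            ranked = optimize_preprocessing(
                sub.values, y, candidates=config.survey_candidates,
                cv=config.cv, max_lv=config.max_lv,
                divergence_ratio_max=config.divergence_ratio_max)
            spec = ranked.iloc[0]["spec"]
        model = calibrate(sub.values, y, spec=spec, cv=config.cv,
                          max_lv=config.max_lv,
                          divergence_ratio_max=config.divergence_ratio_max,
                          grid_fingerprint=cal.grid_fingerprint(),
                          metadata={"instruments": list(subset),
                                    "n_rows": int(mask.sum())})
        models[label] = model
        at = model.cv_table.iloc[model.n_lv - 1]
        cal_rows.append({
            "subset": label, "n": int(mask.sum()),
            "pretreatment": spec.shorthand(), "n_lv": model.n_lv,
            "SEC": at["sec"], "R2C": at["r2c"],
            "SECV": at["secv"], "R2CV": at["r2cv"], "error": "",
        })
        for target in design.validation_targets:
            if target == "All":
                vmask = np.ones(val.n_rows, dtype=bool)
            else:
                vmask = (val.keys["instrument_id"] == target).to_numpy()
            if not vmask.any():
                continue
            vsub = val.select(vmask)
            ref = val_ref.loc[vsub.keys["ear_id"]].to_numpy(dtype=float)
            pred = model.predict(vsub)
            rep = evaluate(pred, ref)
            val_rows.append({
                "subset": label, "target": str(target), "n": rep.n,
                "R2P": rep.r2, "RMSEP": rep.rmse, "SEP": rep.sep,
                "Bias": rep.bias, "Intercept": rep.intercept,
                "Slope": rep.slope,
            })
    return TransferReport(
        calibration=pd.DataFrame(cal_rows),
        validation=pd.DataFrame(val_rows),
        models=models,
    )


_CAL_ROWS = [("SEC", "SEC"), ("R²C", "R2C"), ("SECV", "SECV"),
             ("R²CV", "R2CV"), ("Number of terms", "n_lv")]
_VAL_ROWS = [("R²P", "R2P"), ("RMSEP", "RMSEP"), ("SEP", "SEP"),
             ("Bias", "Bias"), ("Intercept", "Intercept"), ("Slope", "Slope")]


def render_tables(report: TransferReport) -> tuple[str, str]:
    """Render (calibration, validation) tab-separated tables with the
    conventional row labels; columns are subsets / subset→target cells,
    values rounded to reported precision."""
    cal = report.calibration
    cal_ok = cal[cal.get("error", "") == ""] if len(cal) else cal
    lines = ["Parameters\t" + "\t".join(cal_ok["subset"]) if len(cal_ok)
             else "Parameters"]
    for label, col in _CAL_ROWS:
        if len(cal_ok):
            vals = [str(int(v)) if col == "n_lv" else f"{round_reported(float(v)):g}"
                    for v in cal_ok[col]]
            lines.append(label + "\t" + "\t".join(vals))
        else:
            lines.append(label)
    cal_text = "\n".join(lines) + "\n"

    valdf = report.validation
    headers = [f"{r.subset}→{r.target}" for r in valdf.itertuples()] if len(valdf) else []
    vlines = ["Instrument\t" + "\t".join(headers) if headers else "Instrument"]
    for label, col in _VAL_ROWS:
        if len(valdf):
            vals = [f"{round_reported(float(v)):g}" for v in valdf[col]]
            vlines.append(label + "\t" + "\t".join(vals))
        else:
            vlines.append(label)
    val_text = "\n".join(vlines) + "\n"
    return cal_text, val_text
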