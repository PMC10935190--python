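"""Calibration/validation statistics for NIRS moisture models.

Conventions (chemometrics standard):

* RMSE (C/CV/P) uses divisor N: sqrt(mean((P − L)²)) with P the predicted and
  L the laboratory reference value.
* Bias is mean(P − L); SEP (and SEC/SECV) is the bias-corrected residual SD
  with divisor N−1, so the exact identity N·RMSE² = N·bias² + (N−1)·SEP²
  holds for every evaluated pair set.
* R² is the squared Pearson correlation between predicted and reference —
  this is the definition under which RPD = 1/sqrt(1 − R²) reproduces the
  headline ratios (R² 0.88 → RPD 2.9).
* RPD is reported in both of its textbook forms: derived from R² (headline,
  used for classification) and as SD(reference)/SEP.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "EvaluationReport",
    "rmse",
    "bias_sep",
    "regression_line",
    "r_squared",
    "rpd_from_r2",
    "rpd_from_sd_sep",
    "classify_rpd",
    "evaluate",
    "RPD_CLASSES",
]

# Contiguous half-open RPD performance bands [low, high) → label.  The
# published criteria leave gaps (e.g. 1.9–2.0); they are closed downward so
# every non-negative RPD maps to exactly one class and 2.9 stays "screening".
RPD_CLASSES: tuple[tuple[float, float, str], ...] = (
    (0.0, 2.0, "not recommended"),
    (2.0, 2.5, "rough screening"),
    (2.5, 3.0, "screening"),
    (3.0, 3.5, "quality control"),
    (3.5, 4.0, "process control"),
    (4.0, float("inf"), "any application"),
)


def _pair(pred, ref, min_n=1):
    p = np.asarray(pred, dtype=float).ravel()
    r = np.asarray(ref, dtype=float).ravel()
    if p.size != r.size:
        raise ValueError(f"length mismatch: {p.size} predictions vs {r.size} references")
    if p.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {p.size}")
    return p, r


def rmse(pred, ref) -> float:
    """Root mean square error, divisor N."""
    p, r = _pair(pred, ref, min_n=1)
    return float(np.sqrt(np.mean((p - r) ** 2)))


def bias_sep(pred, ref) -> tuple[float, float]:
    """(bias, SEP): mean error and bias-corrected residual SD (divisor N−1)."""
    p, r = _pair(pred, ref, min_n=2)
    e = p - r
    bias = float(np.mean(e))
    sep = float(np.sqrt(np.sum((e - bias) ** 2) / (e.size - 1)))
    return bias, sep


def regression_line(pred, ref) -> tuple[float, float]:
    """OLS of predicted (response) on reference (regressor): (slope, intercept)."""
    p, r = _pair(pred, ref, min_n=2)
    vr = np.var(r)
    if vr == 0:
        raise ValueError("reference has zero variance; regression line undefined")
    slope = float(np.cov(p, r, ddof=1)[0, 1] / np.var(r, ddof=1))
    intercept = float(np.mean(p) - slope * np.mean(r))
    return slope, intercept


def r_squared(pred, ref) -> float:
    """Squared Pearson correlation (sign of the association is discarded)."""
    p, r = _pair(pred, ref, min_n=2)
    if np.var(p) == 0 or np.var(r) == 0:
        raise ValueError("zero variance in predicted or reference values")
    c = np.corrcoef(p, r)[0, 1]
    return float(c * c)


def rpd_from_r2(r2: float) -> float:
    """RPD = 1/sqrt(1 − R²); infinite at R² = 1."""
    if not 0.0 <= r2 <= 1.0:
        raise ValueError(f"R² must be in [0, 1], got {r2}")
    if r2 == 1.0:
        return float("inf")
    return float(1.0 / np.sqrt(1.0 - r2))


def rpd_from_sd_sep(sd: float, sep: float) -> float:
    """RPD = SD(reference)/SEP; infinite at SEP = 0."""
    if sep < 0 or sd < 0:
        raise ValueError("sd and sep must be non-negative")
    if sep == 0:
        return float("inf")
    return float(sd / sep)


def classify_rpd(rpd: float) -> str:
    if rpd < 0:
        raise ValueError(f"RPD must be non-negative, got {rpd}")
    if np.isinf(rpd):
        return "any application"
    for lo, hi, label in RPD_CLASSES:
        if lo <= rpd < hi:
            return label
    raise AssertionError("unreachable: RPD bands cover [0, inf)")


@dataclass
class EvaluationReport:
    n: int
    rmse: float
    bias: float
    sep: float
    slope: float
    intercept: float
    r2: float
    rpd_r2: float
    rpd_sd: float
    rpd_class: str

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def check_identity(self, rtol: float = 1e-9) -> None:
        """Assert N·RMSE² = N·bias² + (N−1)·SEP² to relative tolerance."""
        lhs = self.n * self.rmse**2
        rhs = self.n * self.bias**2 + (self.n - 1) * self.sep**2
        scale = max(abs(lhs), abs(rhs), 1e-30)
        if abs(lhs - rhs) / scale > rtol:
            raise AssertionError(
                f"RMSE/bias/SEP identity violated: {lhs} vs {rhs}"
            )


def evaluate(pred, ref) -> EvaluationReport:
    """Full validation report for paired predictions and references."""
    p, r = _pair(pred, ref, min_n=2)
    err = rmse(p, r)
    bias, sep = bias_sep(p, r)
    slope, intercept = regression_line(p, r)
    r2 = r_squared(p, r)
    rr2 = rpd_from_r2(r2)
    rsd = rpd_from_sd_sep(float(np.std(r, ddof=1)), sep)
    report = EvaluationReport(
        n=p.size, rmse=err, bias=bias, sep=sep, slope=slope,
        intercept=intercept, r2=r2, rpd_r2=rr2, rpd_sd=rsd,
        rpd_class=classify_rpd(rr2),
    )
    report.check_identity()
    return report


def sep_from_rmse_bias(rmse_val: float, bias: float, n: int) -> float:
    """Invert the identity: SEP = sqrt((N·RMSE² − N·bias²)/(N−1)).

    Reconciles a printed (RMSEP, bias) pair with its SEP; raises if the pair
    is internally inconsistent (|bias| > RMSE)."""
    num = n * rmse_val**2 - n * bias**2
    if num < 0:
        raise ValueError(f"inconsistent pair: |bias| {bias} exceeds RMSE {rmse_val}")
    return float(np.sqrt(num / (n - 1)))


def round_reported(x: float) -> float:
    """Table rounding: one decimal for |x| ≥ 1 (two significant figures ≤ 10),
    two significant figures below 1."""
    if abs(x) >= 1:
        return round(x, 1)
    if x == 0:
        return 0.0
    from math import floor, log10
    digits = 1 - floor(log10(abs(x)))
    return round(x, digits)
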