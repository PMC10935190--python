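"""Spectral pretreatments and the pretreatment survey.

Four candidate pretreatments are supported — none, autoscaling,
multiplicative scatter correction (MSC), and the Savitzky–Golay derivative
(SGD) — each train/apply separable: statistics (column means/SDs, the MSC
reference spectrum) are learned on calibration rows and applied unchanged to
new rows, so cross-validation never peeks at held-out data.

The SG derivative operates in variable-index space (window widths are counted
in variables, not nm), with edges filled by evaluating the same fitted
polynomial frame at the end points, keeping the grid length stable.  The
shorthand ``D-2,2,11`` means derivative order 2, polynomial order 2, window
11 variables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "PreprocessSpec",
    "FittedPreprocess",
    "autoscale",
    "msc",
    "sg_derivative",
    "fit_preprocess",
    "default_survey_candidates",
    "optimize_preprocessing",
]

METHODS = ("none", "autoscale", "mean_center", "msc", "sg_derivative")


@dataclass(frozen=True)
class PreprocessSpec:
    method: str = "none"
    derivative_order: int = 2
    window: int = 11
    poly_order: int = 2

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown pretreatment {self.method!r}; one of {METHODS}")
        if self.method == "sg_derivative":
            if self.window % 2 == 0 or self.window <= self.poly_order:
                raise ValueError(
                    f"SG window must be odd and > poly_order, got window="
                    f"{self.window}, poly_order={self.poly_order}"
                )
            if not 0 <= self.derivative_order <= self.poly_order:
                raise ValueError("derivative_order must be in [0, poly_order]")

    def shorthand(self) -> str:
        """Table notation: D-<deriv>,<poly>,<window> for SGD, else the name."""
        if self.method == "sg_derivative":
            return f"D-{self.derivative_order},{self.poly_order},{self.window}"
        return self.method

    @classmethod
    def from_shorthand(cls, text: str) -> "PreprocessSpec":
        t = text.strip()
        if t.lower() in ("none", "autoscale", "mean_center", "msc"):
            return cls(method=t.lower())
        if t.upper().startswith("D-"):
            parts = t[2:].split(",")
            if len(parts) != 3:
                raise ValueError(f"cannot parse SGD shorthand {text!r}")
            d, p, w = (int(x) for x in parts)
            return cls(method="sg_derivative", derivative_order=d,
                       poly_order=p, window=w)
        raise ValueError(f"cannot parse pretreatment shorthand {text!r}")


def autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise centering and scaling to unit sample SD (ddof=1).

    Returns (scaled matrix, column means, column SDs); the statistics let the
    identical transform be applied to validation rows.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("autoscaling needs at least 2 rows")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = np.nonzero(sd == 0)[0]
    if zero.size:
        raise ValueError(f"zero-SD column(s) at variable index {zero[:5].tolist()}")
    return (X - mu) / sd, mu, sd


def msc(X: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each row s is regressed (OLS, with intercept) on the reference; the
    corrected row is (s − a)/b.  Default reference: the mean spectrum of X.
    """
    X = np.asarray(X, dtype=float)
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.size != X.shape[1]:
        raise ValueError("reference length must match row length")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise ValueError("zero-variance MSC reference spectrum")
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    a = X.mean(axis=1) - b * ref.mean()
    return (X - a[:, None]) / b[:, None]


def sg_derivative(X: np.ndarray, window: int, poly_order: int,
                  derivative_order: int) -> np.ndarray:
    """Savitzky–Golay derivative per row, in variable-index units.

    Output keeps the input length; edge points come from evaluating the
    polynomial fitted to the terminal window at the edge positions.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if window > X.shape[1]:
        raise ValueError(f"SG window {window} exceeds row length {X.shape[1]}")
    # validate via the spec dataclass so both entry points share one rule set
    PreprocessSpec(method="sg_derivative", derivative_order=derivative_order,
                   window=window, poly_order=poly_order)
    return savgol_filter(X, window_length=window, polyorder=poly_order,
                         deriv=derivative_order, delta=1.0, axis=1,
                         mode="interp")


@dataclass
class FittedPreprocess:
    """A pretreatment with its training statistics frozen in."""

    spec: PreprocessSpec
    x_mean: np.ndarray | None = None
    x_sd: np.ndarray | None = None
    msc_reference: np.ndarray | None = None

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        m = self.spec.method
        if m == "none":
            return X
        if m == "mean_center":
            return X - self.x_mean
        if m == "autoscale":
            return (X - self.x_mean) / self.x_sd
        if m == "msc":
            return msc(X, reference=self.msc_reference)
        if m == "sg_derivative":
            return sg_derivative(X, self.spec.window, self.spec.poly_order,
                                 self.spec.derivative_order)
        raise AssertionError(m)


def fit_preprocess(spec: PreprocessSpec, X: np.ndarray) -> FittedPreprocess:
    """Learn the pretreatment statistics on calibration rows."""
    X = np.asarray(X, dtype=float)
    fp = FittedPreprocess(spec=spec)
    if spec.method in ("autoscale", "mean_center"):
        fp.x_mean = X.mean(axis=0)
        if spec.method == "autoscale":
            sd = X.std(axis=0, ddof=1)
            zero = np.nonzero(sd == 0)[0]
            if zero.size:
                raise ValueError(
                    f"zero-SD column(s) at variable index {zero[:5].tolist()}"
                )
            fp.x_sd = sd
    elif spec.method == "msc":
        fp.msc_reference = X.mean(axis=0)
    return fp


def default_survey_candidates() -> list[PreprocessSpec]:
    """The standard pretreatment survey: none, autoscale, MSC, and SGD over
    derivative order {1,2} × window {9,11,…,27} × polynomial order {2,3} —
    43 candidates in total."""
    cands = [PreprocessSpec("none"), PreprocessSpec("autoscale"),
             PreprocessSpec("msc")]
    for d, w, p in itertools.product((1, 2), range(9, 28, 2), (2, 3)):
        if d <= p:
            cands.append(PreprocessSpec("sg_derivative", derivative_order=d,
                                        window=w, poly_order=p))
    return cands


def optimize_preprocessing(X, y, candidates=None, cv=None, max_lv: int = 20,
                           divergence_ratio_max: float = 1.25) -> pd.DataFrame:
    """Survey pretreatments: fit PLS with automatic LV selection under each
    candidate and rank the outcomes.

    Returns a frame with one row per candidate — shorthand, selected nLV,
    RMSEC, RMSECV, R²CV and the SECV/SEC ratio — sorted by RMSECV ascending,
    ties broken by fewer LVs then smaller SECV/SEC ratio.  A candidate that
    fails to fit is recorded with its error message rather than aborting the
    survey.
    """
    from .pls import CVScheme, cross_validate, fit_pls, select_n_lv

    if candidates is None:
        candidates = default_survey_candidates()
    if not candidates:
        raise ValueError("candidate list is empty")
    if cv is None:
        cv = CVScheme()
    rows = []
    for spec in candidates:
        try:
            cv_table = cross_validate(X, y, spec, cv, max_lv=max_lv)
            n_lv = select_n_lv(cv_table["rmsec"].to_numpy(),
                               cv_table["rmsecv"].to_numpy(),
                               divergence_ratio_max)
            at = cv_table.iloc[n_lv - 1]
            ratio = at["secv"] / at["sec"] if at["sec"] > 0 else np.inf
            rows.append({
                "pretreatment": spec.shorthand(), "spec": spec, "n_lv": n_lv,
                "rmsec": at["rmsec"], "rmsecv": at["rmsecv"],
                "r2cv": at["r2cv"], "secv_sec_ratio": ratio, "error": "",
            })
        except Exception as exc:  # survey robustness: record, continue
            rows.append({
                "pretreatment": spec.shorthand(), "spec": spec, "n_lv": 0,
                "rmsec": np.nan, "rmsecv": np.nan, "r2cv": np.nan,
                "secv_sec_ratio": np.nan, "error": str(exc),
            })
    table = pd.DataFrame(rows)
    ok = table["error"] == ""
    ranked = pd.concat([
        table[ok].sort_values(["rmsecv", "n_lv", "secv_sec_ratio"],
                              kind="mergesort"),
        table[~ok],
    ]).reset_index(drop=True)
    return ranked
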