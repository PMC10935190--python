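"""Ear-moisture to whole-plant-moisture chain.

The link between ear moisture (EM) and whole-plant moisture (WP), both in
%w.b., is the previously established quadratic

    EM = 0.028·WP² − 2.24·WP + 78.3

whose vertex sits at WP = 40 (EM = 33.5).  Field-relevant whole-plant
moistures (55–81 %w.b.) lie on the increasing branch, so inversion takes the
larger root.  Three estimation strategies build on this:

* method 1 — oven-dried ear moisture → WP through the inverse quadratic;
* method 2 — NIRS-predicted ear moisture → WP through the inverse quadratic;
* method 3 — NIRS predicting WP directly from ear spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import EvaluationReport, evaluate

__all__ = [
    "EarWholeplantModel",
    "DEFAULT_EW_MODEL",
    "MethodResult",
    "ear_from_wholeplant",
    "wholeplant_from_ear",
    "run_method1",
    "run_method2",
    "run_method3",
]


class InversionDomainError(ValueError):
    """Ear moisture below the quadratic's minimum: no real whole-plant root."""


@dataclass(frozen=True)
class EarWholeplantModel:
    """Quadratic EM = a2·WP² + a1·WP + a0 with coefficients taken as printed
    constants (refitting would need the original two-year dataset)."""

    a2: float = 0.028
    a1: float = -2.24
    a0: float = 78.3

    @property
    def vertex_wp(self) -> float:
        """WP at the quadratic's minimum (40.0 for the printed coefficients)."""
        return -self.a1 / (2.0 * self.a2)

    @property
    def em_min(self) -> float:
        """EM at the vertex; the inversion domain's lower edge (33.5)."""
        return self.forward(self.vertex_wp)

    def forward(self, wp):
        return self.a2 * np.asarray(wp, dtype=float) ** 2 + self.a1 * np.asarray(wp, dtype=float) + self.a0

    def inverse(self, em):
        em = np.asarray(em, dtype=float)
        disc = self.a1**2 - 4.0 * self.a2 * (self.a0 - em)
        if np.any(disc < -1e-12):
            bad = np.atleast_1d(em)[np.atleast_1d(disc) < -1e-12]
            raise InversionDomainError(
                f"ear moisture below quadratic minimum {self.em_min:.4g} %w.b. "
                f"(no real whole-plant solution): {bad[:5]}"
            )
        disc = np.maximum(disc, 0.0)
        return (-self.a1 + np.sqrt(disc)) / (2.0 * self.a2)


DEFAULT_EW_MODEL = EarWholeplantModel()


def ear_from_wholeplant(wp, model: EarWholeplantModel = DEFAULT_EW_MODEL):
    """EM (%w.b.) from WP (%w.b.) via the quadratic; scalar in → scalar out."""
    arr = np.asarray(wp, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("whole-plant moisture must lie in [0, 100] %w.b.")
    out = model.forward(arr)
    return float(out) if np.isscalar(wp) else out


def wholeplant_from_ear(em, model: EarWholeplantModel = DEFAULT_EW_MODEL):
    """WP (%w.b.) from EM via the increasing branch (WP ≥ vertex).

    Raises :class:`InversionDomainError` for EM below the quadratic minimum
    (33.5 %w.b. for the printed coefficients) — no silent clamping, because
    the decreasing branch is physiologically wrong for standing corn.
    """
    out = model.inverse(em)
    return float(out) if np.isscalar(em) else out


@dataclass
class MethodResult:
    """Predicted whole-plant moistures plus their validation statistics."""

    method: str
    predicted_wp: pd.Series
    predicted_em: pd.Series | None
    report: EvaluationReport
    failed_ears: list = None  # ear ids whose EM fell below the inversion domain

    def __post_init__(self):
        if self.failed_ears is None:
            self.failed_ears = []


def _chain_evaluate(method, em_pred: pd.Series, reference_wp: pd.Series,
                    model: EarWholeplantModel) -> MethodResult:
    em_vals = em_pred.to_numpy(dtype=float)
    ok = em_vals >= model.em_min
    failed = list(em_pred.index[~ok])
    wp_pred = np.full(em_vals.shape, np.nan)
    wp_pred[ok] = model.inverse(em_vals[ok])
    report = evaluate(wp_pred[ok], reference_wp.to_numpy(dtype=float)[ok])
    return MethodResult(
        method=method,
        predicted_wp=pd.Series(wp_pred, index=em_pred.index, name="predicted_wp"),
        predicted_em=em_pred,
        report=report,
        failed_ears=failed,
    )


def run_method1(
    oven_em: pd.Series,
    reference_wp: pd.Series,
    model: EarWholeplantModel = DEFAULT_EW_MODEL,
) -> MethodResult:
    """Oven ear moisture → whole-plant moisture through the inverse quadratic.

    ``oven_em`` and ``reference_wp`` are aligned per-ear series (%w.b.).
    Ears whose EM falls below the inversion domain are excluded from the
    evaluation and listed in ``failed_ears``.
    """
    if len(oven_em) != len(reference_wp):
        raise ValueError("oven_em and reference_wp must be paired")
    return _chain_evaluate("method1_oven_chain", oven_em, reference_wp, model)


def run_method2(
    pls_model,
    spectra,
    reference_wp: pd.Series,
    model: EarWholeplantModel = DEFAULT_EW_MODEL,
) -> MethodResult:
    """NIRS ear-moisture prediction chained through the inverse quadratic.

    ``pls_model`` must be a calibration for *ear* moisture; ``spectra`` an
    absorbance :class:`~silagescan.spectra.SpectraSet` on the model's grid,
    one row per ear, aligned with ``reference_wp``.
    """
    em_hat = pls_model.predict(spectra)
    em_series = pd.Series(em_hat, index=reference_wp.index, name="predicted_em")
    return _chain_evaluate("method2_nirs_chain", em_series, reference_wp, model)


def run_method3(pls_model, spectra, reference_wp: pd.Series) -> MethodResult:
    """Direct NIRS prediction of whole-plant moisture from ear spectra."""
    if spectra.n_rows == 0:
        raise ValueError("empty spectra set")
    wp_hat = pls_model.predict(spectra)
    report = evaluate(wp_hat, reference_wp.to_numpy(dtype=float))
    return MethodResult(
        method="method3_direct",
        predicted_wp=pd.Series(wp_hat, index=reference_wp.index, name="predicted_wp"),
        predicted_em=None,
        report=report,
    )
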