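"""Partial least squares regression with Venetian-blinds cross-validation.

Single-response NIPALS with deflation: deterministic, no random
initialization, orthogonal scores.  Regression vectors are stored for every
latent-variable (LV) count up to ``max_lv`` so model selection can revisit
any truncation without refitting.

The LV count is chosen at the first local minimum of RMSECV, provided RMSECV
does not diverge from RMSEC (their ratio stays below a guard, default 1.25);
failing that, the global minimum under the same guard; failing that, the LV
minimizing the ratio.

Cross-validation uses Venetian blinds: row i goes to split ⌊i/thickness⌋ mod
n_splits.  Pretreatment statistics are refit inside every split — validation
rows never inform the transform applied to them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import bias_sep, r_squared, rmse
from .preprocess import FittedPreprocess, PreprocessSpec, fit_preprocess

__all__ = [
    "PLSModel",
    "CVScheme",
    "fit_pls",
    "venetian_blinds_splits",
    "cross_validate",
    "select_n_lv",
    "calibrate",
]

_EPS = 1e-12


@dataclass(frozen=True)
class CVScheme:
    """Venetian-blinds scheme: ten splits of thickness one by default."""

    method: str = "venetian_blinds"
    n_splits: int = 10
    thickness: int = 1

    def __post_init__(self) -> None:
        if self.method != "venetian_blinds":
            raise ValueError(f"unsupported CV method {self.method!r}")
        if self.n_splits < 2:
            raise ValueError("n_splits must be >= 2")
        if self.thickness < 1:
            raise ValueError("thickness must be >= 1")


@dataclass
class PLSModel:
    """A fitted PLS calibration.

    ``coefs[k-1]`` is the regression vector using k LVs, acting on
    mean-centered preprocessed spectra; predictions are
    ``(x_pre − x_mean) @ coefs[n_lv−1] + y_mean``.
    """

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray          # (max_lv, p)
    loadings: np.ndarray         # (max_lv, p)
    y_loadings: np.ndarray       # (max_lv,)
    coefs: np.ndarray            # (max_lv, p)
    n_lv: int
    preprocess: FittedPreprocess
    grid_fingerprint: tuple | None = None
    metadata: dict = field(default_factory=dict)
    cv_table: pd.DataFrame | None = None

    @property
    def max_lv(self) -> int:
        return self.coefs.shape[0]

    def regression_vector(self, n_lv: int | None = None) -> np.ndarray:
        k = self.n_lv if n_lv is None else n_lv
        if not 1 <= k <= self.max_lv:
            raise ValueError(f"n_lv must be in [1, {self.max_lv}], got {k}")
        return self.coefs[k - 1]

    def predict(self, spectra, n_lv: int | None = None) -> np.ndarray:
        """Predict the response for raw (pre-pretreatment) absorbance rows.

        Accepts a :class:`~silagescan.spectra.SpectraSet` (must be in the
        absorbance domain and on the training grid) or a plain matrix.
        """
        X = self._coerce(spectra)
        Xp = self.preprocess.apply(X)
        b = self.regression_vector(n_lv)
        return (Xp - self.x_mean) @ b + self.y_mean

    def _coerce(self, spectra) -> np.ndarray:
        values = getattr(spectra, "values", None)
        if values is not None and hasattr(spectra, "grid_fingerprint"):
            if spectra.domain != "absorbance":
                raise ValueError("model expects absorbance spectra")
            if (self.grid_fingerprint is not None
                    and spectra.grid_fingerprint() != self.grid_fingerprint):
                raise ValueError("spectra grid does not match the training grid")
            return np.asarray(values, dtype=float)
        return np.atleast_2d(np.asarray(spectra, dtype=float))

    def to_json(self) -> str:
        payload = {
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "coefs": self.coefs.tolist(),
            "n_lv": self.n_lv,
            "preprocess": {
                "shorthand": self.preprocess.spec.shorthand(),
                "x_mean": None if self.preprocess.x_mean is None
                else self.preprocess.x_mean.tolist(),
                "x_sd": None if self.preprocess.x_sd is None
                else self.preprocess.x_sd.tolist(),
                "msc_reference": None if self.preprocess.msc_reference is None
                else self.preprocess.msc_reference.tolist(),
            },
            "grid_fingerprint": list(self.grid_fingerprint)
            if self.grid_fingerprint else None,
            "metadata": self.metadata,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "PLSModel":
        d = json.loads(text)
        pp = d["preprocess"]
        fp = FittedPreprocess(
            spec=PreprocessSpec.from_shorthand(pp["shorthand"]),
            x_mean=None if pp["x_mean"] is None else np.array(pp["x_mean"]),
            x_sd=None if pp["x_sd"] is None else np.array(pp["x_sd"]),
            msc_reference=None if pp["msc_reference"] is None
            else np.array(pp["msc_reference"]),
        )
        coefs = np.array(d["coefs"])
        return cls(
            x_mean=np.array(d["x_mean"]), y_mean=d["y_mean"],
            weights=np.empty((0, coefs.shape[1])),
            loadings=np.empty((0, coefs.shape[1])),
            y_loadings=np.empty(0), coefs=coefs, n_lv=d["n_lv"],
            preprocess=fp,
            grid_fingerprint=tuple(d["grid_fingerprint"])
            if d["grid_fingerprint"] else None,
            metadata=d.get("metadata", {}),
        )


def fit_pls(X, y, max_lv: int = 20,
            preprocess: FittedPreprocess | None = None,
            grid_fingerprint: tuple | None = None,
            metadata: dict | None = None) -> PLSModel:
    """Fit single-response PLS by NIPALS on mean-centered data.

    ``X`` is the already-pretreated spectra matrix.  If the data support
    fewer than ``max_lv`` components (rank deficiency), the model is
    truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y row counts differ")
    if n < 2:
        raise ValueError("need at least 2 calibration rows")
    max_lv = min(max_lv, n - 1, p)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    x_scale0 = float(np.linalg.norm(Xc)) or 1.0

    W = np.zeros((max_lv, p))
    P = np.zeros((max_lv, p))
    q = np.zeros(max_lv)
    k_eff = 0
    for k in range(max_lv):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw < _EPS * x_scale0:
            break
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        if tt < (_EPS * x_scale0) ** 2:
            break
        pk = Xc.T @ t / tt
        qk = float(yc @ t) / tt
        Xc = Xc - np.outer(t, pk)
        yc = yc - qk * t
        W[k], P[k], q[k] = w, pk, qk
        k_eff = k + 1
    if k_eff < max_lv:
        warnings.warn(
            f"rank deficiency: truncating from {max_lv} to {k_eff} latent variables",
            RuntimeWarning, stacklevel=2,
        )
        W, P, q = W[:k_eff], P[:k_eff], q[:k_eff]
        max_lv = k_eff
    if max_lv == 0:
        raise ValueError("response or spectra have no usable variance")

    coefs = np.zeros((max_lv, p))
    for k in range(1, max_lv + 1):
        Wk, Pk, qk = W[:k].T, P[:k].T, q[:k]
        coefs[k - 1] = Wk @ np.linalg.solve(Pk.T @ Wk, qk)

    return PLSModel(
        x_mean=x_mean, y_mean=y_mean, weights=W, loadings=P, y_loadings=q,
        coefs=coefs, n_lv=max_lv,
        preprocess=preprocess or FittedPreprocess(PreprocessSpec("none")),
        grid_fingerprint=grid_fingerprint, metadata=metadata or {},
    )


def venetian_blinds_splits(n_rows: int, n_splits: int, thickness: int = 1
                           ) -> list[np.ndarray]:
    """Disjoint index sets: row i belongs to split ⌊i/thickness⌋ mod n_splits."""
    if n_rows < n_splits:
        raise ValueError(f"n_rows ({n_rows}) < n_splits ({n_splits})")
    assign = (np.arange(n_rows) // thickness) % n_splits
    return [np.nonzero(assign == s)[0] for s in range(n_splits)]


def _sec(residuals: np.ndarray) -> float:
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        return float("nan")
    b = e.mean()
    return float(np.sqrt(np.sum((e - b) ** 2) / (e.size - 1)))


def cross_validate(X, y, spec: PreprocessSpec | None = None,
                   cv: CVScheme | None = None, max_lv: int = 20) -> pd.DataFrame:
    """Venetian-blinds CV over LV counts.

    For each split the pretreatment statistics and PLS are refit on the
    retained rows only; held-out predictions are pooled across splits per LV.
    Returns a frame with columns ``lv, rmsec, sec, r2c, rmsecv, secv, r2cv``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    spec = spec or PreprocessSpec("none")
    cv = cv or CVScheme()
    n = X.shape[0]
    splits = venetian_blinds_splits(n, cv.n_splits, cv.thickness)
    min_train = min(n - s.size for s in splits)
    max_lv = min(max_lv, min_train - 1, X.shape[1])
    if max_lv < 1:
        raise ValueError("too few rows for cross-validation")

    # calibration branch: statistics from all rows
    fp_all = fit_preprocess(spec, X)
    model_all = fit_pls(fp_all.apply(X), y, max_lv=max_lv, preprocess=fp_all)
    max_lv = model_all.max_lv

    pooled = np.full((n, max_lv), np.nan)
    for held in splits:
        keep = np.setdiff1d(np.arange(n), held)
        y_tr = y[keep]
        if np.std(y_tr) == 0:
            raise ValueError("a CV split's training responses have zero variance")
        fp = fit_preprocess(spec, X[keep])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = fit_pls(fp.apply(X[keep]), y_tr, max_lv=max_lv, preprocess=fp)
        Xh = fp.apply(X[held])
        for k in range(1, m.max_lv + 1):
            pooled[held, k - 1] = (Xh - m.x_mean) @ m.coefs[k - 1] + m.y_mean
        for k in range(m.max_lv + 1, max_lv + 1):  # rank-truncated split
            pooled[held, k - 1] = pooled[held, m.max_lv - 1]

    Xp_all = fp_all.apply(X)
    rows = []
    for k in range(1, max_lv + 1):
        yc_hat = (Xp_all - model_all.x_mean) @ model_all.coefs[k - 1] + model_all.y_mean
        cv_hat = pooled[:, k - 1]
        rows.append({
            "lv": k,
            "rmsec": rmse(yc_hat, y),
            "sec": _sec(yc_hat - y),
            "r2c": r_squared(yc_hat, y),
            "rmsecv": rmse(cv_hat, y),
            "secv": _sec(cv_hat - y),
            "r2cv": r_squared(cv_hat, y),
        })
    return pd.DataFrame(rows)


def select_n_lv(rmsec, rmsecv, divergence_ratio_max: float = 1.25) -> int:
    """LV count at the first local minimum of RMSECV whose RMSECV/RMSEC ratio
    stays within the divergence guard.

    Position 1 qualifies as a local minimum when rmsecv[1] ≤ rmsecv[2]; the
    last position never does.  Fallbacks: the global minimum satisfying the
    guard, then the ratio-minimizing LV (with a warning).  Returns a 1-based
    LV count.
    """
    c = np.asarray(rmsec, dtype=float)
    v = np.asarray(rmsecv, dtype=float)
    if c.size == 0 or c.size != v.size:
        raise ValueError("rmsec and rmsecv must be equal-length, non-empty")
    L = v.size
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(c > 0, v / c, np.inf)
    if L == 1:
        return 1

    def is_local_min(i: int) -> bool:  # 0-based index
        if i == L - 1:
            return False
        left_ok = True if i == 0 else v[i] <= v[i - 1]
        return left_ok and v[i] <= v[i + 1]

    for i in range(L):
        if is_local_min(i) and ratio[i] <= divergence_ratio_max:
            return i + 1
    order = np.argsort(v, kind="stable")
    for i in order:
        if ratio[i] <= divergence_ratio_max:
            return int(i) + 1
    warnings.warn(
        "no LV satisfies the RMSECV/RMSEC divergence guard; "
        "falling back to the ratio-minimizing LV",
        RuntimeWarning, stacklevel=2,
    )
    return int(np.argmin(ratio)) + 1


def calibrate(X, y, spec: PreprocessSpec | None = None,
              cv: CVScheme | None = None, max_lv: int = 20,
              divergence_ratio_max: float = 1.25,
              grid_fingerprint: tuple | None = None,
              metadata: dict | None = None) -> PLSModel:
    """Full calibration: pretreat, cross-validate, select the LV count, and
    return the fitted model with its CV table attached."""
    spec = spec or PreprocessSpec("none")
    table = cross_validate(X, y, spec, cv, max_lv=max_lv)
    n_lv = select_n_lv(table["rmsec"].to_numpy(), table["rmsecv"].to_numpy(),
                       divergence_ratio_max)
    fp = fit_preprocess(spec, np.asarray(X, dtype=float))
    model = fit_pls(fp.apply(X), y, max_lv=int(table["lv"].max()),
                    preprocess=fp, grid_fingerprint=grid_fingerprint,
                    metadata=metadata)
    model.n_lv = min(n_lv, model.max_lv)
    model.cv_table = table
    return model
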