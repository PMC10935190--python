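"""Spectra containers and I/O.

A :class:`SpectraSet` bundles a shared wavelength grid (nm), a scan matrix
(rows = scans or per-ear averages), a key table (ear_id, instrument_id,
replicate) and a signal-domain flag (reflectance or absorbance).

Pipeline order is fixed: replicate scans are averaged in the reflectance
domain first, then converted to absorbance (A = log10(1/R)); the two
operations do not commute exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "SpectraFormatError",
    "read_spectra",
    "write_spectra",
    "read_reference",
    "write_reference",
    "to_absorbance",
    "average_replicates",
]

KEY_COLUMNS = ["ear_id", "instrument_id", "replicate"]
AVERAGED = "averaged"


class SpectraFormatError(ValueError):
    """Malformed spectra table."""


@dataclass
class SpectraSet:
    grid: np.ndarray            # wavelengths, nm, strictly increasing
    values: np.ndarray          # (n_rows, n_wavelengths)
    keys: pd.DataFrame          # ear_id, instrument_id, replicate
    domain: str = "reflectance"  # or "absorbance"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.grid.size:
            raise SpectraFormatError(
                f"value matrix shape {self.values.shape} does not match grid "
                f"of {self.grid.size} wavelengths"
            )
        if len(self.keys) != self.values.shape[0]:
            raise SpectraFormatError("key table row count != matrix row count")
        if np.any(np.diff(self.grid) <= 0):
            raise SpectraFormatError("wavelength grid must be strictly increasing")
        if self.domain not in ("reflectance", "absorbance"):
            raise SpectraFormatError(f"unknown signal domain {self.domain!r}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def grid_fingerprint(self) -> tuple:
        """Hashable grid identity used to guard model/spectra compatibility."""
        return (self.grid.size, round(float(self.grid[0]), 6),
                round(float(self.grid[-1]), 6),
                round(float(self.grid.sum()), 4))

    def select(self, mask) -> "SpectraSet":
        mask = np.asarray(mask)
        return SpectraSet(
            grid=self.grid,
            values=self.values[mask],
            keys=self.keys.iloc[mask].reset_index(drop=True)
            if mask.dtype == bool else self.keys.iloc[mask].reset_index(drop=True),
            domain=self.domain,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"{w:.1f}" for w in self.grid])
        for col in reversed(KEY_COLUMNS):
            df.insert(0, col, self.keys[col].to_numpy())
        return df


def from_frame(df: pd.DataFrame, domain: str = "reflectance") -> SpectraSet:
    """Build a SpectraSet from the wide table written by the simulator."""
    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraFormatError(f"missing key columns: {missing}")
    wl_cols = [c for c in df.columns if c not in KEY_COLUMNS]
    try:
        grid = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavelength header: {exc}") from exc
    vals = df[wl_cols].to_numpy(dtype=float)
    return SpectraSet(grid=grid, values=vals,
                      keys=df[KEY_COLUMNS].reset_index(drop=True), domain=domain)


def read_spectra(path, domain: str = "reflectance") -> SpectraSet:
    """Read a spectra CSV (ear_id, instrument_id, replicate, then one column
    per wavelength, header in nm).  Errors name the offending column/row."""
    df = pd.read_csv(path, float_precision="round_trip")
    wl_cols = [c for c in df.columns if c not in KEY_COLUMNS]
    for c in wl_cols:
        bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
        if df[c].isna().any() or bad.any():
            row = int(np.argmax(df[c].isna().to_numpy() | bad.to_numpy()))
            raise SpectraFormatError(
                f"non-numeric or missing value at row {row}, column {c!r} in {path}"
            )
    s = from_frame(df, domain=domain)
    return s


def write_spectra(s: SpectraSet, path) -> None:
    # %.17g guarantees float64 round-trips bit-identically through the CSV
    s.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_reference(path) -> pd.DataFrame:
    """Read the reference table (ear_id, ear_moisture_wb,
    wholeplant_moisture_wb, season), indexed by ear_id."""
    df = pd.read_csv(path)
    required = {"ear_id", "ear_moisture_wb", "wholeplant_moisture_wb"}
    missing = required - set(df.columns)
    if missing:
        raise SpectraFormatError(f"reference table missing columns {sorted(missing)}")
    return df.set_index("ear_id")


def write_reference(ref: pd.DataFrame, path) -> None:
    out = ref.reset_index() if ref.index.name == "ear_id" else ref
    out.to_csv(path, index=False)


def to_absorbance(s: SpectraSet) -> SpectraSet:
    """Convert reflectance to absorbance, A = log10(1/R)."""
    if s.domain != "reflectance":
        raise ValueError(f"expected reflectance input, got {s.domain}")
    if np.any(s.values <= 0):
        i, j = np.argwhere(s.values <= 0)[0]
        raise ValueError(
            f"non-positive reflectance at row {i}, wavelength {s.grid[j]:.1f} nm"
        )
    return SpectraSet(grid=s.grid, values=-np.log10(s.values),
                      keys=s.keys.copy(), domain="absorbance")


def average_replicates(s: SpectraSet, by: tuple = ("ear_id", "instrument_id")) -> SpectraSet:
    """Average replicate scans per group (arithmetic mean per wavelength).

    ``by`` is ``("ear_id",)`` to pool across instruments or
    ``("ear_id", "instrument_id")`` to keep instruments separate.  The
    replicate key of averaged rows is set to ``'averaged'``; group order
    follows first appearance in the input.
    """
    if s.n_rows == 0:
        raise ValueError("cannot average an empty SpectraSet")
    by = list(by)
    df = s.keys.copy()
    df["_row"] = np.arange(s.n_rows)
    rows = []
    keys = []
    for group_key, sub in df.groupby(by, sort=False):
        idx = sub["_row"].to_numpy()
        rows.append(s.values[idx].mean(axis=0))
        if not isinstance(group_key, tuple):
            group_key = (group_key,)
        entry = dict(zip(by, group_key))
        entry.setdefault("instrument_id", sub["instrument_id"].iloc[0]
                         if sub["instrument_id"].nunique() == 1 else "pooled")
        entry["replicate"] = AVERAGED
        keys.append(entry)
    key_df = pd.DataFrame(keys)[["ear_id", "instrument_id", "replicate"]]
    return SpectraSet(grid=s.grid, values=np.vstack(rows), keys=key_df,
                      domain=s.domain)
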