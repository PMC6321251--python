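"""Domain types and tabular I/O for NIR reflectance spectra.

Spectra are stored as apparent absorbance, log(1/R), on a shared strictly
increasing uniform wavelength grid (default 400-2500 nm in 2 nm steps, 1050
points).  Reference chemistry values (e.g. total phenolic content in
mg GAE g^-1 dry weight, total carotenoid content in ug g^-1 dry weight) are
kept in a separate aligned table.  The on-disk dialect is plain delimited
text: a header row of wavelengths with one row per sample for spectra, and
an (id, analyte, value) table for reference values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_WL_MIN = 400.0
DEFAULT_WL_MAX = 2500.0
DEFAULT_WL_STEP = 2.0

#: Uniformity tolerance for the wavelength grid, in nm.
GRID_TOL = 1e-9


class SpectraError(ValueError):
    """Raised on malformed spectra tables or violated invariants."""


def default_grid(wl_min: float = DEFAULT_WL_MIN,
                 wl_max: float = DEFAULT_WL_MAX,
                 step: float = DEFAULT_WL_STEP) -> np.ndarray:
    """The instrument wavelength grid: point i at wl_min + step*i, covering
    [wl_min, wl_max) -- 1050 points for the default 400-2500 nm at 2 nm."""
    n = int(round((wl_max - wl_min) / step))
    return wl_min + step * np.arange(n)


def index_to_nm(i: int | np.ndarray, wl_min: float = DEFAULT_WL_MIN,
                step: float = DEFAULT_WL_STEP) -> float | np.ndarray:
    """Centralized index <-> nm conversion (point i sits at wl_min + step*i)."""
    return wl_min + step * np.asarray(i)


def nm_to_index(nm: float | np.ndarray, wl_min: float = DEFAULT_WL_MIN,
                step: float = DEFAULT_WL_STEP) -> int | np.ndarray:
    return np.asarray(np.round((np.asarray(nm) - wl_min) / step)).astype(int)


@dataclass(frozen=True)
class SpectraSet:
    """A matrix of log(1/R) spectra on a shared wavelength grid.

    Attributes
    ----------
    wavelengths : (m,) array, nm, strictly increasing uniform grid
    absorbance : (n, m) array of log(1/R), no missing values
    sample_ids : n unique strings
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        ids = tuple(str(s) for s in self.sample_ids)
        if ab.shape[1] != wl.size:
            raise SpectraError(
                f"wavelength count ({wl.size}) != matrix columns ({ab.shape[1]})")
        if ab.shape[0] != len(ids):
            raise SpectraError(
                f"sample id count ({len(ids)}) != matrix rows ({ab.shape[0]})")
        if len(set(ids)) != len(ids):
            dup = sorted({s for s in ids if ids.count(s) > 1})
            raise SpectraError(f"duplicate sample ids: {dup}")
        if wl.size >= 2:
            d = np.diff(wl)
            if np.any(d <= 0):
                raise SpectraError("wavelength grid must be strictly increasing")
            if np.ptp(d) > GRID_TOL:
                raise SpectraError("wavelength grid must be uniform")
        if not np.all(np.isfinite(ab)):
            raise SpectraError("absorbance matrix contains missing/non-finite values")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)
        object.__setattr__(self, "sample_ids", ids)

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    def take(self, indices: Sequence[int]) -> "SpectraSet":
        """Row-subset preserving order of `indices`."""
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(self.wavelengths, self.absorbance[idx],
                          tuple(self.sample_ids[i] for i in idx))


ANALYTE_UNITS = {"TPC": "mg GAE g-1 dw", "TCC": "ug g-1 dw"}


@dataclass(frozen=True)
class ReferenceValues:
    """Reference chemistry values aligned to a SpectraSet by sample id."""

    sample_ids: tuple[str, ...]
    analyte: str
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float).ravel()
        ids = tuple(str(s) for s in self.sample_ids)
        if vals.size != len(ids):
            raise SpectraError("one value per sample id required")
        if len(set(ids)) != len(ids):
            raise SpectraError("duplicate sample ids in reference table")
        if np.any(~np.isfinite(vals)) or np.any(vals < 0):
            raise SpectraError("reference values must be finite and non-negative")
        units = self.units or ANALYTE_UNITS.get(self.analyte, "")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "units", units)

    @property
    def n(self) -> int:
        return self.values.size

    def take(self, indices: Sequence[int]) -> "ReferenceValues":
        idx = np.asarray(indices, dtype=int)
        return ReferenceValues(tuple(self.sample_ids[i] for i in idx),
                               self.analyte, self.values[idx], self.units)


@dataclass(frozen=True)
class MathTreatment:
    """WinISI-style 4-integer math treatment plus scatter-correction switch.

    The notation "d,g,s1,s2" reads: derivative order, derivative gap,
    first smooth, second smooth -- all in data points (1 point = 2 nm on the
    default grid).  ``scatter`` selects SNV + de-trend applied to log(1/R)
    before derivation.
    """

    derivative_order: int = 0
    gap: int = 0
    smooth1: int = 1
    smooth2: int = 1
    scatter: str = "none"  # {"none", "snv_dt"}

    def __post_init__(self):
        if self.derivative_order not in (0, 1, 2):
            raise ValueError("derivative_order must be 0, 1 or 2")
        if self.derivative_order > 0 and self.gap <= 0:
            raise ValueError("gap must be > 0 when derivative_order > 0")
        if self.gap < 0 or self.smooth1 < 1 or self.smooth2 < 1:
            raise ValueError("gap >= 0 and smooth widths >= 1 required")
        if self.scatter not in ("none", "snv_dt"):
            raise ValueError(f"unknown scatter correction {self.scatter!r}")

    @classmethod
    def parse(cls, text: str, scatter: str = "none") -> "MathTreatment":
        """Parse the paper-style string, e.g. ``"2,5,5,2"``."""
        parts = [int(p) for p in str(text).replace(";", ",").split(",")]
        if len(parts) != 4:
            raise ValueError(f"treatment must have 4 integers, got {text!r}")
        d, g, s1, s2 = parts
        return cls(d, g, max(s1, 1), max(s2, 1), scatter)

    def __str__(self) -> str:
        s = f"{self.derivative_order},{self.gap},{self.smooth1},{self.smooth2}"
        return s + (" SNV-DT" if self.scatter == "snv_dt" else "")

    @property
    def label(self) -> str:
        return f"{self.derivative_order},{self.gap},{self.smooth1},{self.smooth2}"


# ---------------------------------------------------------------------------
# Tabular I/O


def _sep_for(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_spectra(path: str | Path, sep: str | None = None) -> SpectraSet:
    """Read a delimited spectra table (header = wavelengths, col 0 = id)."""
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    try:
        wl = df.columns.to_numpy(dtype=float)
    except (TypeError, ValueError) as e:
        raise SpectraError(f"non-numeric wavelength header in {path}: {e}") from e
    ids = [str(s) for s in df.index]
    dup = sorted({s for s in ids if ids.count(s) > 1})
    if dup:
        raise SpectraError(f"duplicate sample id(s) {dup} in {path}")
    mat = df.to_numpy(dtype=float)
    bad = np.where(~np.isfinite(mat).all(axis=1))[0]
    if bad.size:
        raise SpectraError(
            f"non-numeric/missing cells in row(s) {[ids[i] for i in bad]} of {path}")
    return SpectraSet(wl, mat, tuple(ids))


def write_spectra(spectra: SpectraSet, path: str | Path,
                  sep: str | None = None) -> None:
    df = pd.DataFrame(spectra.absorbance, index=list(spectra.sample_ids),
                      columns=[repr(float(w)) for w in spectra.wavelengths])
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path, sep), float_format="%.17g")


def read_reference(path: str | Path, analyte: str | None = None,
                   sep: str | None = None) -> ReferenceValues:
    """Read an (id, analyte, value) table; filter to one analyte if asked."""
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype={0: str})
    cols = {c.lower(): c for c in df.columns}
    for need in ("sample_id", "analyte", "value"):
        if need not in cols:
            raise SpectraError(f"reference table {path} lacks column {need!r}")
    if analyte is not None:
        df = df[df[cols["analyte"]] == analyte]
        if df.empty:
            raise SpectraError(f"no rows for analyte {analyte!r} in {path}")
    labels = df[cols["analyte"]].unique()
    if len(labels) != 1:
        raise SpectraError(
            f"reference table holds several analytes {sorted(labels)}; pass analyte=")
    return ReferenceValues(tuple(df[cols["sample_id"]].astype(str)), labels[0],
                           df[cols["value"]].to_numpy(dtype=float))


def write_reference(refs: ReferenceValues, path: str | Path,
                    sep: str | None = None) -> None:
    pd.DataFrame({"sample_id": list(refs.sample_ids),
                  "analyte": refs.analyte,
                  "value": refs.values}).to_csv(
        path, sep=_sep_for(path, sep), index=False, float_format="%.17g")


def align(spectra: SpectraSet, refs: ReferenceValues
          ) -> tuple[SpectraSet, ReferenceValues]:
    """Restrict both tables to common ids, in spectra order."""
    pos = {s: i for i, s in enumerate(refs.sample_ids)}
    keep = [i for i, s in enumerate(spectra.sample_ids) if s in pos]
    if not keep:
        raise SpectraError("spectra and reference tables share no sample ids")
    return (spectra.take(keep),
            refs.take([pos[spectra.sample_ids[i]] for i in keep]))


def split_validation(spectra: SpectraSet, refs: ReferenceValues,
                     step: int = 5
                     ) -> tuple[tuple[SpectraSet, ReferenceValues],
                                tuple[SpectraSet, ReferenceValues]]:
    """Deterministic calibration/validation split: every step-th sample
    (1-based positions step, 2*step, ...) goes to validation, the remainder
    to calibration.  The partitions are disjoint and exhaustive.

    Returns ``((cal_spectra, cal_refs), (val_spectra, val_refs))``.
    """
    if step < 2:
        raise ValueError("step must be >= 2")
    if tuple(spectra.sample_ids) != tuple(refs.sample_ids):
        spectra, refs = align(spectra, refs)
    n = spectra.n_samples
    if n < step:
        raise SpectraError(f"need at least step={step} samples, got {n}")
    val_idx = np.arange(step - 1, n, step)
    cal_idx = np.setdiff1d(np.arange(n), val_idx)
    return ((spectra.take(cal_idx), refs.take(cal_idx)),
            (spectra.take(val_idx), refs.take(val_idx)))
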