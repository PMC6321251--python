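"""Spectral pretreatment: SNV + de-trending and gap-segment derivatives.

The transform order mirrors common practice for reflectance chemometrics:
scatter correction (standard normal variate, then polynomial de-trend) is
applied to log(1/R) per spectrum, and the derivative pipeline -- first
boxcar smooth, symmetric gap difference, second boxcar smooth -- runs on the
corrected spectra.  All window/gap parameters are in data points (1 point =
2 nm on the default grid); edges where any stencil would leave the grid are
trimmed, never padded, and the surviving grid is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_core import MathTreatment, SpectraSet


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessedSpectra:
    """Transformed spectra on a (possibly edge-trimmed) wavelength grid."""

    wavelengths: np.ndarray
    matrix: np.ndarray
    treatment: MathTreatment
    sample_ids: tuple[str, ...]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def take(self, indices) -> "PreprocessedSpectra":
        idx = np.asarray(indices, dtype=int)
        return PreprocessedSpectra(self.wavelengths, self.matrix[idx],
                                   self.treatment,
                                   tuple(self.sample_ids[i] for i in idx))


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale one spectrum to mean 0,
    sample standard deviation 1 (ddof=1).  Removes multiplicative scatter
    and additive baseline offsets."""
    x = np.asarray(spectrum, dtype=float)
    if x.size < 2:
        raise PreprocessError("SNV needs at least 2 points")
    sd = x.std(ddof=1)
    if sd == 0:
        raise PreprocessError("zero-variance spectrum: SNV undefined")
    return (x - x.mean()) / sd


def detrend(spectrum: np.ndarray, wavelengths: np.ndarray,
            degree: int = 2) -> np.ndarray:
    """Residual of a least-squares polynomial fit of absorbance on
    wavelength; removes curvilinear baseline trend.  The residual is
    orthogonal to the polynomial basis."""
    x = np.asarray(spectrum, dtype=float)
    wl = np.asarray(wavelengths, dtype=float)
    if degree >= x.size:
        raise PreprocessError(f"degree {degree} >= spectrum length {x.size}")
    # centred/scaled wavelength axis keeps the Vandermonde well conditioned
    coef = np.polynomial.polynomial.polyfit(wl, x, degree)
    return x - np.polynomial.polynomial.polyval(wl, coef)


def snv_detrend(spectrum: np.ndarray, wavelengths: np.ndarray,
                degree: int = 2) -> np.ndarray:
    """SNV followed by de-trending (the SNV-DT scatter correction)."""
    return detrend(snv(spectrum), wavelengths, degree)


def _odd(width: int) -> int:
    """Boxcar widths are centered and odd; even requests round up."""
    w = int(width)
    if w < 1:
        raise PreprocessError("smooth width must be >= 1")
    return w if w % 2 == 1 else w + 1


def _boxcar(mat: np.ndarray, width: int) -> np.ndarray:
    """Centered running mean of odd `width`, valid region only
    (trims (width-1)/2 points per edge)."""
    w = _odd(width)
    if w == 1:
        return mat
    if mat.shape[1] < w:
        raise PreprocessError("spectrum shorter than smoothing window")
    kernel = np.full(w, 1.0 / w)
    out = np.empty((mat.shape[0], mat.shape[1] - w + 1))
    for i, row in enumerate(mat):
        out[i] = np.convolve(row, kernel, mode="valid")
    return out


def _gap_difference(mat: np.ndarray, order: int, gap: int) -> np.ndarray:
    """Symmetric gap difference, trimming `gap` points per edge.

    order 1: y[i] = x[i+g] - x[i-g]
    order 2: y[i] = x[i+g] - 2 x[i] + x[i-g]
    """
    if order == 0:
        return mat
    g = int(gap)
    if mat.shape[1] <= 2 * g:
        raise PreprocessError("spectrum shorter than derivative stencil")
    lo, hi, mid = mat[:, : -2 * g], mat[:, 2 * g:], mat[:, g:-g]
    if order == 1:
        return hi - lo
    if order == 2:
        return hi - 2.0 * mid + lo
    raise PreprocessError(f"derivative order {order} not supported")


def gap_derivative(matrix: np.ndarray, wavelengths: np.ndarray,
                   treatment: MathTreatment
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Apply the 4-number derivative pipeline to a spectra matrix.

    Pipeline: boxcar(smooth1) -> symmetric gap difference(order, gap) ->
    boxcar(smooth2).  Returns (transformed matrix, trimmed grid).
    """
    mat = np.atleast_2d(np.asarray(matrix, dtype=float))
    wl = np.asarray(wavelengths, dtype=float)
    if mat.shape[1] != wl.size:
        raise PreprocessError("matrix columns != wavelength count")

    trim = 0
    out = _boxcar(mat, treatment.smooth1)
    trim += (_odd(treatment.smooth1) - 1) // 2
    if treatment.derivative_order > 0:
        out = _gap_difference(out, treatment.derivative_order, treatment.gap)
        trim += treatment.gap
    out = _boxcar(out, treatment.smooth2)
    trim += (_odd(treatment.smooth2) - 1) // 2

    new_wl = wl[trim: wl.size - trim] if trim else wl
    if out.shape[1] < 2:
        raise PreprocessError("treatment leaves fewer than 2 points")
    assert new_wl.size == out.shape[1]
    return out, new_wl


def apply_treatment(spectra: SpectraSet, treatment: MathTreatment,
                    detrend_degree: int = 2) -> PreprocessedSpectra:
    """Full pretreatment of a SpectraSet: optional SNV-DT per spectrum on
    log(1/R), then the gap-segment derivative pipeline."""
    mat = spectra.absorbance
    if treatment.scatter == "snv_dt":
        mat = np.vstack([
            snv_detrend(row, spectra.wavelengths, detrend_degree)
            for row in mat])
    out, wl = gap_derivative(mat, spectra.wavelengths, treatment)
    return PreprocessedSpectra(wl, out, treatment, spectra.sample_ids)
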