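"""NIPALS partial least squares and modified PLS (Shenk-Westerhaus).

PLS1 extracts latent factors that maximise covariance between the spectral
matrix and a single reference variable.  The "modified" variant (MPLS)
additionally standardises the spectral residual matrix after each factor:
every wavelength column is divided by its residual standard deviation before
the next factor is extracted, so late factors are not dominated by a few
high-variance wavelengths -- the noise is "encapsulated in the less
important factors".  The per-factor scale history is stored on the model and
replayed at prediction time, which makes MPLS prediction exactly reproducible
and reduces to plain PLS when every scale is forced to 1.

Only PLS1 is provided: each analyte is calibrated independently.  X is
always mean-centred; y is centred but never scaled, so predictions carry the
reference units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .spectra_core import MathTreatment


class RegressionError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted PLS/MPLS calibration.

    weights (W), x_loadings (P) are (n_factors, m); y_loadings (q) is
    (n_factors,).  scales is (n_factors, m): the per-wavelength residual
    standard deviations applied *before* extracting each factor (all ones
    for plain PLS).  Prediction replays, per factor a:

        e <- e / scales[a];  t = e @ W[a];  yhat += t * q[a];
        e <- e - outer(t, P[a])
    """

    x_center: np.ndarray
    y_center: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scales: np.ndarray
    n_factors: int
    method: str  # "pls" | "mpls"
    wavelengths: np.ndarray | None = None
    treatment: MathTreatment | None = None
    analyte: str = ""

    @property
    def coefficients(self) -> np.ndarray:
        """Regression vector b on the (centred, preprocessed) grid:
        yhat = y_center + (x - x_center) @ b.  Obtained by pushing the
        identity basis through the factor replay, so it is exact for MPLS
        scale histories as well."""
        m = self.x_center.size
        e = np.eye(m)
        b = np.zeros(m)
        for a in range(self.n_factors):
            e = e / self.scales[a]
            t = e @ self.weights[a]
            b += t * self.y_loadings[a]
            e -= np.outer(t, self.x_loadings[a])
        return b

    @property
    def fitted_values(self) -> np.ndarray | None:
        return getattr(self, "_fitted", None)


def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_factors: int,
                 rescale_residuals: bool) -> dict:
    n, m = X.shape
    x_center = X.mean(axis=0)
    y_center = float(y.mean())
    E = X - x_center
    f = y - y_center

    rank = np.linalg.matrix_rank(E) if min(n, m) <= 200 else min(n - 1, m)
    if n_factors > rank:
        raise RegressionError(
            f"n_factors={n_factors} exceeds rank {rank} of centred X")

    W = np.zeros((n_factors, m))
    P = np.zeros((n_factors, m))
    q = np.zeros(n_factors)
    S = np.ones((n_factors, m))
    T = np.zeros((n_factors, n))

    for a in range(n_factors):
        if rescale_residuals:
            sd = E.std(axis=0, ddof=1)
            sd[sd <= 0] = 1.0  # degenerate rule: dead columns keep scale 1
            S[a] = sd
            E = E / sd
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw == 0:
            raise RegressionError(
                f"residual covariance vanished at factor {a + 1}")
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt == 0:
            raise RegressionError(f"degenerate score at factor {a + 1}")
        p = E.T @ t / tt
        qa = float(f @ t) / tt
        E = E - np.outer(t, p)
        f = f - qa * t
        W[a], P[a], q[a], T[a] = w, p, qa, t

    return dict(x_center=x_center, y_center=y_center, weights=W,
                x_loadings=P, y_loadings=q, scales=S, scores=T)


def _fit(X, y, n_factors, method, wavelengths, treatment, analyte,
         rescale) -> CalibrationModel:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if y.size != n:
        raise RegressionError("X rows and y length differ")
    if n_factors < 1:
        raise RegressionError("n_factors must be >= 1")
    if n < n_factors + 2:
        raise RegressionError(
            f"need at least n_factors+2={n_factors + 2} samples, got {n}")
    parts = _nipals_pls1(X, y, n_factors, rescale)
    model = CalibrationModel(
        x_center=parts["x_center"], y_center=parts["y_center"],
        weights=parts["weights"], x_loadings=parts["x_loadings"],
        y_loadings=parts["y_loadings"], scales=parts["scales"],
        n_factors=n_factors, method=method,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, float),
        treatment=treatment, analyte=analyte)
    object.__setattr__(model, "_fitted", predict(model, X))
    return model


def fit_pls(X, y, n_factors: int, wavelengths=None,
            treatment: MathTreatment | None = None,
            analyte: str = "") -> CalibrationModel:
    """Standard NIPALS PLS1 on mean-centred data; deterministic."""
    return _fit(X, y, n_factors, "pls", wavelengths, treatment, analyte,
                rescale=False)


def fit_mpls(X, y, n_factors: int, wavelengths=None,
             treatment: MathTreatment | None = None,
             analyte: str = "", rescale_residuals: bool = True
             ) -> CalibrationModel:
    """Modified PLS: per-wavelength residual standardisation between
    factors.  ``rescale_residuals=False`` forces unit scales, reducing the
    fit to plain PLS (used as a correctness anchor in tests)."""
    return _fit(X, y, n_factors,
                "mpls" if rescale_residuals else "pls",
                wavelengths, treatment, analyte, rescale=rescale_residuals)


def predict(model: CalibrationModel, X_new, n_factors: int | None = None
            ) -> np.ndarray:
    """Predict reference values for new preprocessed spectra.

    ``n_factors`` truncates the factor replay (used by cross-validation to
    score every factor count from one fit)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_center.size:
        wl = model.wavelengths
        where = (f" (expected grid {wl[0]:g}-{wl[-1]:g} nm, {wl.size} points)"
                 if wl is not None else "")
        raise RegressionError(
            f"grid mismatch: model has {model.x_center.size} wavelengths, "
            f"input has {X_new.shape[1]}{where}")
    k = model.n_factors if n_factors is None else int(n_factors)
    if not 1 <= k <= model.n_factors:
        raise RegressionError(f"n_factors must be in [1, {model.n_factors}]")
    e = X_new - model.x_center
    yhat = np.full(X_new.shape[0], model.y_center)
    for a in range(k):
        e = e / model.scales[a]
        t = e @ model.weights[a]
        yhat += t * model.y_loadings[a]
        e = e - np.outer(t, model.x_loadings[a])
    return yhat


def loading_spectrum(model: CalibrationModel, factor_index: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Unit-norm X-loading of one factor (1-based index) with its grid."""
    if not 1 <= factor_index <= model.n_factors:
        raise RegressionError(
            f"factor_index {factor_index} out of range 1..{model.n_factors}")
    p = model.x_loadings[factor_index - 1]
    wl = (model.wavelengths if model.wavelengths is not None
          else np.arange(p.size, dtype=float))
    return wl, p / np.linalg.norm(p)


# Band assignment table (nm -> constituent / vibration), visible + NIR.
BAND_ASSIGNMENTS: dict[float, str] = {
    558: "electronic transition (green)",
    614: "electronic transition (orange)",
    632: "electronic transition (visible)",
    640: "electronic transition (visible)",
    672: "chlorophyll (electronic)",
    674: "chlorophyll (electronic)",
    678: "electronic transition (red)",
    1175: "carotenoid C-H 3rd overtone",
    1325: "carotenoid C-H combination",
    1364: "O-H 1st overtone",
    1404: "O-H stretch 1st overtone (water)",
    1412: "C-H/O-H (phenolics region)",
    1420: "phenolic O-H (1415-1512 nm region)",
    1436: "sugars: O-H stretch / HOH deformation",
    1444: "phenolic O-H (1415-1512 nm region)",
    1514: "O-H hydroxyl group",
    1516: "O-H hydroxyl group",
    1668: "carotenoid C-H 1st overtone",
    1692: "C-H 1st overtone",
    1724: "lipid C-H 1st overtone",
    1762: "C-H stretch 1st overtone",
    1900: "C=O stretch 2nd overtone",
    1908: "O-H stretch (water)",
    1924: "O-H stretch 1st overtone (water)",
    1980: "aromatic C-H 2nd overtone / O-H combination (phenolics)",
    2056: "C-O stretch of phenols",
    2068: "N-H/O-H combination",
    2142: "C-H stretch 1st overtone",
    2170: "C-H stretch 1st overtone",
    2236: "N-H bend",
    2268: "cellulose C-H stretch",
    2278: "cellulose C-H stretch",
    2300: "C-H combination (lipids)",
    2350: "lipid C-H stretch 1st overtone",
    2388: "hemicellulose/cellulose C-H",
}

ANNOTATION_WINDOW_NM = 12.0


def annotate_loadings(loading: np.ndarray, wavelengths: np.ndarray,
                      top_k: int = 5) -> list[tuple[float, float, str]]:
    """Annotate the `top_k` absolute-loading local extrema with the nearest
    tabulated band assignment within a 12 nm window ('unassigned' outside).

    Returns a list of (wavelength nm, loading value, assignment).
    """
    p = np.asarray(loading, dtype=float)
    wl = np.asarray(wavelengths, dtype=float)
    if p.size != wl.size:
        raise RegressionError("loading and wavelength lengths differ")
    if p.size < 3 or top_k <= 0:
        return []
    interior = np.arange(1, p.size - 1)
    is_ext = ((p[interior] - p[interior - 1]) * (p[interior + 1] - p[interior])
              <= 0)
    idx = interior[is_ext]
    if idx.size == 0:
        idx = np.array([int(np.argmax(np.abs(p)))])
    order = idx[np.argsort(-np.abs(p[idx]), kind="stable")][:top_k]
    centers = np.array(sorted(BAND_ASSIGNMENTS))
    out = []
    for i in order:
        d = np.abs(centers - wl[i])
        j = int(np.argmin(d))
        label = (BAND_ASSIGNMENTS[centers[j]] if d[j] <= ANNOTATION_WINDOW_NM
                 else "unassigned")
        out.append((float(wl[i]), float(p[i]), label))
    return out


# ---------------------------------------------------------------------------
# Serialization: versioned plain-JSON model documents

MODEL_FORMAT_VERSION = 1


def model_to_json(model: CalibrationModel, path: str | Path | None = None
                  ) -> str:
    doc = {
        "format": "nirscal-model", "version": MODEL_FORMAT_VERSION,
        "method": model.method, "analyte": model.analyte,
        "n_factors": model.n_factors,
        "y_center": model.y_center,
        "x_center": model.x_center.tolist(),
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "scales": model.scales.tolist(),
        "wavelengths": (None if model.wavelengths is None
                        else model.wavelengths.tolist()),
        "treatment": (None if model.treatment is None else {
            "derivative_order": model.treatment.derivative_order,
            "gap": model.treatment.gap,
            "smooth1": model.treatment.smooth1,
            "smooth2": model.treatment.smooth2,
            "scatter": model.treatment.scatter}),
    }
    text = json.dumps(doc)
    if path is not None:
        Path(path).write_text(text)
    return text


def model_from_json(source: str | Path) -> CalibrationModel:
    text = (Path(source).read_text() if isinstance(source, Path)
            or (isinstance(source, str) and not source.lstrip().startswith("{"))
            else source)
    doc = json.loads(text)
    if doc.get("format") != "nirscal-model":
        raise RegressionError("not a nirscal model document")
    tr = doc.get("treatment")
    return CalibrationModel(
        x_center=np.array(doc["x_center"], float),
        y_center=float(doc["y_center"]),
        weights=np.array(doc["weights"], float),
        x_loadings=np.array(doc["x_loadings"], float),
        y_loadings=np.array(doc["y_loadings"], float),
        scales=np.array(doc["scales"], float),
        n_factors=int(doc["n_factors"]), method=doc["method"],
        wavelengths=(None if doc["wavelengths"] is None
                     else np.array(doc["wavelengths"], float)),
        treatment=None if tr is None else MathTreatment(**tr),
        analyte=doc.get("analyte", ""))
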