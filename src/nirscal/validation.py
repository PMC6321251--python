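"""Cross-validation, outlier screening and calibration/validation statistics.

Implements the error statistics used to judge NIR calibrations:

* SEC  -- standard error of calibration, sqrt(SSE / (n - k - 1)) with k the
          number of model factors;
* SECV -- standard error of cross-validation, the RMS of cross-validated
          residuals over seeded folds, with the factor count chosen at the
          SECV minimum (ties broken toward fewer factors);
* SEP  -- standard error of prediction corrected for bias,
          sqrt(sum((e - bias)^2) / (n - 1)), bias = mean(yhat - y);
* RPD  -- reference SD / standard error; RER -- reference range / SEP;
* Q^2 / R^2 -- coefficient of determination about the reference mean;

plus the CENTER-style spectral outlier screen: global H (GH), the squared
Mahalanobis distance of each sample in principal-component score space
divided by the number of retained components, flagging GH > 3 as anomalous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import PreprocessedSpectra
from .regression import CalibrationModel, fit_mpls, fit_pls, predict
from .spectra_core import MathTreatment


class ValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Elementary statistics


def sec(y, yhat, n_factors: int) -> float:
    """Standard error of calibration: sqrt(SSE / (n - k - 1))."""
    y = np.asarray(y, float).ravel()
    yhat = np.asarray(yhat, float).ravel()
    if y.size != yhat.size:
        raise ValidationError("y and yhat lengths differ")
    n, k = y.size, int(n_factors)
    if n <= k + 1:
        raise ValidationError(f"need n > n_factors+1 (n={n}, k={k})")
    return float(np.sqrt(np.sum((y - yhat) ** 2) / (n - k - 1)))


def sep_bias_corrected(y, yhat) -> tuple[float, float]:
    """Bias-corrected standard error of prediction; returns (sep, bias)."""
    y = np.asarray(y, float).ravel()
    yhat = np.asarray(yhat, float).ravel()
    if y.size != yhat.size:
        raise ValidationError("y and yhat lengths differ")
    if y.size < 3:
        raise ValidationError("need n >= 3 for SEP")
    e = yhat - y
    bias = float(e.mean())
    return float(np.sqrt(np.sum((e - bias) ** 2) / (y.size - 1))), bias


def r_squared(y, yhat) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot about mean(y)."""
    y = np.asarray(y, float).ravel()
    yhat = np.asarray(yhat, float).ravel()
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValidationError("reference values have zero variance")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


def rpd(sd: float, se: float) -> float:
    """Ratio of reference standard deviation to a standard error
    (SECV for RPDcv, SEP for RPDp)."""
    if se <= 0:
        raise ValidationError("standard error must be > 0 for RPD")
    return float(sd) / float(se)


def rer(value_range: float, sep: float) -> float:
    """Ratio of the reference-value range (max - min) to SEP."""
    if sep <= 0:
        raise ValidationError("SEP must be > 0 for RER")
    if value_range <= 0:
        raise ValidationError("degenerate reference range")
    return float(value_range) / float(sep)


# Quality bands for external validation.
Q2_BANDS = (
    (0.90, "excellent"),
    (0.82, "good prediction"),
    (0.65, "discriminate low/high"),
    (0.50, "rough prediction"),
    (0.26, "low correlation"),
)
RPD_BANDS = (
    (3.0, "excellent"),
    (2.5, "good"),
    (1.5, "screening"),
)


def classify_model(q2: float, rpd_p: float, rer_value: float
                   ) -> tuple[str, str, str]:
    """Map external-validation statistics to the standard quality labels.

    Returns (q2 label, rpd label, rer label).  RPD < 1.5 marks an unusable
    equation; RPD 1.5-2.5 suffices for screening; RER >= 10 marks a model
    fit for quantitative use.
    """
    for s in (q2, rpd_p, rer_value):
        if not np.isfinite(s):
            raise ValidationError("statistics must be finite")
    q2_label = "no correlation"
    for lo, label in Q2_BANDS:
        if q2 > lo or (lo == 0.26 and q2 >= lo):
            q2_label = label
            break
    rpd_label = "unusable"
    for lo, label in RPD_BANDS:
        if rpd_p > lo or (lo != 3.0 and rpd_p >= lo):
            rpd_label = label
            break
    rer_label = "quantitative" if rer_value >= 10 else "below-10"
    return q2_label, rpd_label, rer_label


# ---------------------------------------------------------------------------
# Cross-validation with factor selection at minimum SECV

#: factor counts within this of the minimum SECV tie toward fewer factors
SECV_TIE_TOL = 1e-9


@dataclass(frozen=True)
class SECVCurve:
    factors: np.ndarray     # 1..max_factors
    secv: np.ndarray        # SECV per factor count
    chosen_factors: int
    n_groups: int
    seed: int

    def __post_init__(self):
        lo = float(np.min(self.secv))
        k = int(self.factors[np.argmax(self.secv <= lo + SECV_TIE_TOL)])
        if k != self.chosen_factors:
            raise ValidationError("chosen_factors must attain the SECV minimum")


def cross_validate(X, y, max_factors: int, n_groups: int = 5,
                   seed: int = 0, method: str = "mpls") -> SECVCurve:
    """Grouped cross-validation of a PLS/MPLS calibration.

    Samples are partitioned into ``n_groups`` folds by a seeded shuffle;
    each fold is predicted by a model fitted on the remainder, scored at
    every factor count 1..max_factors from a single fit per fold.  SECV(k)
    is the RMS cross-validated residual; the chosen factor count is the
    smallest within tolerance of the SECV minimum ("a medium sized model
    is preferred").
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n = y.size
    if n_groups < 2:
        raise ValidationError("n_groups must be >= 2")
    if n < 2 * n_groups:
        raise ValidationError(
            f"fold with < 2 samples: n={n} over {n_groups} groups")
    fit = {"mpls": fit_mpls, "pls": fit_pls}[method]

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_groups)

    # cap the factor search at the rank available in every training fold
    # (low-rank data would otherwise make NIPALS degenerate)
    k_max = int(max_factors)
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        Xt = X[train_idx]
        k_max = min(k_max, int(np.linalg.matrix_rank(Xt - Xt.mean(axis=0))),
                    train_idx.size - 2)
    if k_max < 1:
        raise ValidationError("no usable factors: rank-deficient folds")

    press = np.zeros(k_max)
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        model = fit(X[train_idx], y[train_idx], k_max)
        for a in range(1, k_max + 1):
            resid = y[test_idx] - predict(model, X[test_idx], n_factors=a)
            press[a - 1] += float(resid @ resid)

    secv = np.sqrt(press / n)
    factors = np.arange(1, k_max + 1)
    chosen = int(factors[np.argmax(secv <= secv.min() + SECV_TIE_TOL)])
    return SECVCurve(factors, secv, chosen, n_groups, int(seed))


# ---------------------------------------------------------------------------
# CENTER-style outlier screen (global H)


@dataclass(frozen=True)
class OutlierReport:
    sample_ids: tuple[str, ...]
    gh: np.ndarray
    flagged: np.ndarray  # boolean
    threshold: float
    n_components: int

    @property
    def flagged_ids(self) -> tuple[str, ...]:
        return tuple(s for s, f in zip(self.sample_ids, self.flagged) if f)


def global_h(matrix: np.ndarray, explained_variance: float = 0.99
             ) -> tuple[np.ndarray, int]:
    """Global H (GH) of each spectrum: squared Mahalanobis distance in
    principal-component score space divided by the number of retained
    components.  Components are retained up to the requested explained
    variance fraction; the mean GH over samples is ~1 by construction.

    Returns (gh values, number of retained components).
    """
    X = np.atleast_2d(np.asarray(matrix, float))
    n = X.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 spectra for GH")
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    ev = s ** 2
    pos = ev > ev[0] * 1e-12 if ev.size and ev[0] > 0 else ev > 0
    rank_deficient = int(pos.sum()) < min(n - 1, Xc.shape[1])
    ev, U, s = ev[pos], U[:, pos], s[pos]
    if ev.size == 0:
        raise ValidationError("zero-variance spectra matrix")
    frac = np.cumsum(ev) / ev.sum()
    k = int(np.searchsorted(frac, explained_variance - 1e-12) + 1)
    k = min(k, ev.size, n - 2)
    if k < 1:
        k = 1
    if rank_deficient and k == ev.size:
        warnings.warn("rank-deficient spectra matrix: retained all "
                      f"{k} non-null components", RuntimeWarning)
    # scores T = U*s; per-component variance ev/(n-1); Mahalanobis^2 in
    # score space is then (n-1) * sum_j U_ij^2
    d2 = (n - 1) * np.sum(U[:, :k] ** 2, axis=1)
    return d2 / k, k


def center_outliers(spectra: PreprocessedSpectra | np.ndarray,
                    threshold: float = 3.0,
                    explained_variance: float = 0.99,
                    sample_ids: tuple[str, ...] | None = None
                    ) -> OutlierReport:
    """Screen spectra for anomalous samples: GH > threshold flags an
    outlier (threshold 3 is the conventional cut)."""
    if isinstance(spectra, PreprocessedSpectra):
        matrix = spectra.matrix
        ids = spectra.sample_ids
    else:
        matrix = np.atleast_2d(np.asarray(spectra, float))
        ids = sample_ids or tuple(f"S{i + 1}" for i in range(matrix.shape[0]))
    gh, k = global_h(matrix, explained_variance)
    return OutlierReport(tuple(ids), gh, gh > threshold, float(threshold), k)


# ---------------------------------------------------------------------------
# The full per-model report (one row of the calibration/validation tables)


@dataclass(frozen=True)
class ValidationReport:
    """Calibration, cross-validation and external-validation statistics for
    one analyte x treatment model."""

    analyte: str
    treatment: MathTreatment
    n_factors: int
    # calibration set
    n_cal: int
    cal_range: tuple[float, float]
    cal_sd: float
    sec: float
    r2: float
    secv: float
    r2cv: float
    rpd_cv: float
    # validation set
    n_val: int
    val_range: tuple[float, float]
    val_mean: float
    val_sd: float
    sep: float
    bias: float
    q2: float
    rpd_p: float
    rer: float
    quality: tuple[str, str, str]
    cv_seed: int = 0

    def __post_init__(self):
        for name in ("sec", "secv", "sep", "rpd_cv", "rpd_p", "rer"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def as_dict(self, decimals: int | None = 2) -> dict:
        r = (lambda v: round(float(v), decimals)) if decimals else float
        return {
            "analyte": self.analyte, "treatment": self.treatment.label,
            "scatter": self.treatment.scatter, "factors": self.n_factors,
            "n_cal": self.n_cal,
            "cal_min": r(self.cal_range[0]), "cal_max": r(self.cal_range[1]),
            "SD": r(self.cal_sd), "R2": r(self.r2), "SEC": r(self.sec),
            "R2cv": r(self.r2cv), "SECV": r(self.secv),
            "RPDcv": r(self.rpd_cv),
            "n_val": self.n_val,
            "val_min": r(self.val_range[0]), "val_max": r(self.val_range[1]),
            "val_mean": r(self.val_mean), "val_SD": r(self.val_sd),
            "Q2": r(self.q2), "SEP": r(self.sep), "bias": r(self.bias),
            "RPDp": r(self.rpd_p), "RER": r(self.rer),
            "q2_quality": self.quality[0], "rpd_quality": self.quality[1],
            "rer_quality": self.quality[2], "cv_seed": self.cv_seed,
        }


def evaluate_model(model: CalibrationModel, curve: SECVCurve,
                   y_cal, yhat_cal, y_val, yhat_val) -> ValidationReport:
    """Assemble the report row from a fitted model, its SECV curve and the
    calibration/validation predictions."""
    y_cal = np.asarray(y_cal, float).ravel()
    y_val = np.asarray(y_val, float).ravel()
    sd_cal = float(y_cal.std(ddof=1))
    sd_val = float(y_val.std(ddof=1))
    secv_val = float(curve.secv[curve.chosen_factors - 1])
    sep_val, bias = sep_bias_corrected(y_val, yhat_val)
    q2 = r_squared(y_val, yhat_val)
    rpd_p = rpd(sd_val, sep_val)
    rer_val = rer(float(y_val.max() - y_val.min()), sep_val)
    return ValidationReport(
        analyte=model.analyte, treatment=model.treatment or MathTreatment(),
        n_factors=model.n_factors,
        n_cal=y_cal.size, cal_range=(float(y_cal.min()), float(y_cal.max())),
        cal_sd=sd_cal, sec=sec(y_cal, yhat_cal, model.n_factors),
        r2=r_squared(y_cal, yhat_cal), secv=secv_val,
        # R2cv = 1 - PRESS/SST with PRESS = n * SECV^2
        r2cv=1.0 - (secv_val ** 2 * y_cal.size)
             / float(np.sum((y_cal - y_cal.mean()) ** 2)),
        rpd_cv=rpd(sd_cal, secv_val),
        n_val=y_val.size, val_range=(float(y_val.min()), float(y_val.max())),
        val_mean=float(y_val.mean()), val_sd=sd_val,
        sep=sep_val, bias=bias, q2=q2, rpd_p=rpd_p, rer=rer_val,
        quality=classify_model(q2, rpd_p, rer_val), cv_seed=curve.seed)
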