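"""End-to-end study orchestration.

Runs the full calibration workflow for each analyte x math-treatment pair:
preprocess -> CENTER outlier screen -> deterministic calibration/validation
split -> cross-validated factor selection at minimum SECV -> MPLS fit ->
external validation -> report row, and emits plain-text report bundles
(calibration/validation table, SECV-vs-factors curves, predicted-vs-
reference pairs, annotated loadings, a JSON run manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .preprocess import apply_treatment
from .regression import (CalibrationModel, annotate_loadings, fit_mpls,
                         loading_spectrum, predict)
from .spectra_core import (MathTreatment, ReferenceValues, SpectraSet, align,
                           read_reference, read_spectra, split_validation)
from .synthetic_data import GeneratorConfig, generate_study
from .validation import (OutlierReport, SECVCurve, ValidationReport,
                         center_outliers, cross_validate, evaluate_model)

log = logging.getLogger("nirscal")

#: The four math treatments the study compares, all with SNV-DT.
DEFAULT_TREATMENTS = (
    MathTreatment(1, 4, 4, 1, "snv_dt"),
    MathTreatment(1, 10, 10, 1, "snv_dt"),
    MathTreatment(2, 5, 5, 2, "snv_dt"),
    MathTreatment(2, 20, 20, 2, "snv_dt"),
)


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one full study run."""

    spectra_path: str | None = None
    reference_path: str | None = None
    generator: GeneratorConfig | None = None
    analytes: tuple[str, ...] = ("TPC", "TCC")
    treatments: tuple[MathTreatment, ...] = DEFAULT_TREATMENTS
    max_factors: int = 16
    folds: int = 5
    seed: int = 42
    split_step: int = 5
    outlier_threshold: float = 3.0
    explained_variance: float = 0.99
    method: str = "mpls"

    def __post_init__(self):
        if not self.treatments:
            raise ValueError("at least one treatment required")
        if self.generator is None and not (self.spectra_path
                                           and self.reference_path):
            raise ValueError("provide file paths or a generator config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        for key in ("spectra_path", "reference_path", "max_factors", "folds",
                    "seed", "split_step", "outlier_threshold",
                    "explained_variance", "method"):
            if key in doc:
                kw[key] = doc[key]
        if "analytes" in doc:
            kw["analytes"] = tuple(doc["analytes"])
        if "treatments" in doc:
            scatter = doc.get("scatter", "snv_dt")
            kw["treatments"] = tuple(
                MathTreatment.parse(t, scatter) for t in doc["treatments"])
        gen = doc.get("generator")
        if gen is not None:
            kw["generator"] = GeneratorConfig(**gen) if isinstance(gen, dict) \
                else GeneratorConfig(seed=doc.get("seed", 0))
        elif doc.get("simulate"):
            kw["generator"] = GeneratorConfig(seed=doc.get("seed", 0))
        return cls(**kw)

    def digest(self) -> str:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if hasattr(o, "__dict__") or hasattr(o, "__dataclass_fields__"):
                return {k: getattr(o, k) for k in o.__dataclass_fields__}
            return str(o)
        blob = json.dumps(self, default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ModelResult:
    analyte: str
    treatment: MathTreatment
    model: CalibrationModel
    curve: SECVCurve
    report: ValidationReport
    outliers: OutlierReport
    y_val: np.ndarray
    yhat_val: np.ndarray
    val_ids: tuple[str, ...]
    loadings: dict[int, list[tuple[float, float, str]]]


@dataclass(frozen=True)
class StudyBundle:
    config: StudyConfig
    results: tuple[ModelResult, ...]

    @property
    def report_table(self) -> pd.DataFrame:
        return pd.DataFrame([r.report.as_dict() for r in self.results])

    def best(self, analyte: str) -> ModelResult:
        """Lowest-SECV model for one analyte."""
        cand = [r for r in self.results if r.analyte == analyte]
        if not cand:
            raise KeyError(f"no results for analyte {analyte!r}")
        return min(cand, key=lambda r: r.report.secv)


def _load_inputs(config: StudyConfig
                 ) -> tuple[SpectraSet, dict[str, ReferenceValues]]:
    if config.generator is not None:
        study = generate_study(config.generator)
        log.info("generated synthetic study: n=%d seed=%d",
                 study.spectra.n_samples, study.config.seed)
        return study.spectra, study.truths
    spectra = read_spectra(config.spectra_path)
    refs = {a: read_reference(config.reference_path, analyte=a)
            for a in config.analytes}
    log.info("loaded %d spectra from %s", spectra.n_samples,
             config.spectra_path)
    return spectra, refs


def run_study(config: StudyConfig) -> StudyBundle:
    """Execute the complete workflow; deterministic for a fixed config."""
    spectra, refs = _load_inputs(config)
    results = []
    for treatment in config.treatments:
        prep = apply_treatment(spectra, treatment)
        screen = center_outliers(prep, config.outlier_threshold,
                                 config.explained_variance)
        keep = np.where(~screen.flagged)[0]
        log.info("treatment %s: %d/%d spectra kept after CENTER screen "
                 "(GH > %.1f flags %s)", treatment, keep.size,
                 prep.n_samples, config.outlier_threshold,
                 list(screen.flagged_ids) or "none")
        clean = spectra.take(keep)
        for analyte in config.analytes:
            ref = refs[analyte].take(
                [list(refs[analyte].sample_ids).index(s)
                 for s in clean.sample_ids])
            (cal_s, cal_r), (val_s, val_r) = split_validation(
                clean, ref, config.split_step)
            prep_cal = apply_treatment(cal_s, treatment)
            prep_val = apply_treatment(val_s, treatment)
            curve = cross_validate(prep_cal.matrix, cal_r.values,
                                   config.max_factors, config.folds,
                                   config.seed, config.method)
            model = fit_mpls(prep_cal.matrix, cal_r.values,
                             curve.chosen_factors,
                             wavelengths=prep_cal.wavelengths,
                             treatment=treatment, analyte=analyte,
                             rescale_residuals=config.method == "mpls")
            yhat_cal = predict(model, prep_cal.matrix)
            yhat_val = predict(model, prep_val.matrix)
            report = evaluate_model(model, curve, cal_r.values, yhat_cal,
                                    val_r.values, yhat_val)
            loadings = {}
            for a in range(1, min(3, model.n_factors) + 1):
                wl_a, p_a = loading_spectrum(model, a)
                loadings[a] = annotate_loadings(p_a, wl_a, top_k=5)
            log.info("%s %s: k=%d SECV=%.3f SEP=%.3f RPDp=%.2f (%s)",
                     analyte, treatment, curve.chosen_factors, report.secv,
                     report.sep, report.rpd_p, report.quality[1])
            results.append(ModelResult(
                analyte, treatment, model, curve, report, screen,
                val_r.values, yhat_val, val_r.sample_ids, loadings))
    return StudyBundle(config, tuple(results))


def write_outputs(bundle: StudyBundle, out_dir: str | Path) -> dict[str, Path]:
    """Emit report.tsv, secv_curves.tsv, predictions.tsv, loadings.tsv and
    manifest.json; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["report"] = out / "report.tsv"
    bundle.report_table.to_csv(paths["report"], sep="\t", index=False)

    curves = []
    for r in bundle.results:
        for k, s in zip(r.curve.factors, r.curve.secv):
            curves.append({"analyte": r.analyte,
                           "treatment": r.treatment.label,
                           "factors": int(k), "secv": float(s),
                           "chosen": int(k) == r.curve.chosen_factors})
    paths["secv_curves"] = out / "secv_curves.tsv"
    pd.DataFrame(curves).to_csv(paths["secv_curves"], sep="\t", index=False)

    preds = []
    for r in bundle.results:
        for sid, yv, yh in zip(r.val_ids, r.y_val, r.yhat_val):
            preds.append({"analyte": r.analyte,
                          "treatment": r.treatment.label, "sample_id": sid,
                          "reference": yv, "predicted": yh})
    paths["predictions"] = out / "predictions.tsv"
    pd.DataFrame(preds).to_csv(paths["predictions"], sep="\t", index=False)

    loads = []
    for r in bundle.results:
        for factor, rows in r.loadings.items():
            for wl, value, label in rows:
                loads.append({"analyte": r.analyte,
                              "treatment": r.treatment.label,
                              "factor": factor, "wavelength_nm": wl,
                              "loading": value, "assignment": label})
    paths["loadings"] = out / "loadings.tsv"
    pd.DataFrame(loads).to_csv(paths["loadings"], sep="\t", index=False)

    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps({
        "nirscal_version": __version__,
        "seed": bundle.config.seed,
        "config_digest": bundle.config.digest(),
        "n_results": len(bundle.results),
        "analytes": list(bundle.config.analytes),
        "treatments": [t.label for t in bundle.config.treatments],
    }, indent=2))
    log.info("wrote %d report files to %s", len(paths), out)
    return paths


def render_report(bundle: StudyBundle) -> str:
    """Human-readable rendering of the calibration/validation table."""
    df = bundle.report_table
    cols = ["analyte", "treatment", "factors", "SD", "R2", "SEC", "R2cv",
            "SECV", "RPDcv", "Q2", "SEP", "RPDp", "RER", "rpd_quality"]
    return df[cols].to_string(index=False)
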