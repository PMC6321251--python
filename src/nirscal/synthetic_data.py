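"""Synthetic blackberry-like NIR spectra with paired reference chemistry.

No public spectral dataset accompanies the blackberry study this package
operationalises, so every stage is exercised on simulated data built from
the structure the analysis assumes:

* reference values (TPC in mg GAE g^-1 dw, TCC in ug g^-1 dw) drawn from
  truncated normal distributions matching the reported summary statistics
  (TPC: mean 24.27, sd 3.06, range 17.36-35.67; TCC: mean 8.30, sd 1.82,
  range 2.84-13.73);
* log(1/R) spectra as additive Beer-Lambert mixtures of Gaussian absorption
  bands at the wavelengths assigned to fruit constituents (chlorophyll
  ~674 nm, sugars ~1436 nm, water 1404/1924 nm, lipids 1724/2350 nm,
  cellulose 2278/2388 nm, phenolics 1415-1512 and 1955-2035 nm, carotenoid
  C-H 1100-1250 / 1300-1350 / 1650-1700 nm);
* per-sample multiplicative scatter, additive offset and spectral tilt
  (the artefacts SNV-DT is designed to remove) plus iid instrument noise.

The generator is fully deterministic for a fixed seed and records its own
configuration so parameter-recovery tests can compare against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectra_core import ReferenceValues, SpectraSet, default_grid


class GeneratorError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Component library: Gaussian-band absorption profiles per constituent

#: (center nm, relative amplitude, fwhm-ish width nm) per constituent band.
#: Widths default to ~30 nm in the visible and ~60 nm in the NIR.
COMPONENT_BANDS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "phenolics": ((1420, 0.7, 45), (1464, 1.0, 50), (1500, 0.6, 40),
                  (1975, 0.8, 45), (2015, 0.7, 40)),
    "carotenoids": ((450, 0.8, 40), (1175, 0.9, 60), (1325, 0.6, 35),
                    (1675, 1.0, 35)),
    "chlorophyll": ((674, 1.0, 30), (620, 0.35, 30)),
    "sugars": ((1436, 1.0, 60), (2080, 0.5, 60)),
    "water": ((1404, 0.7, 55), (1924, 1.0, 80)),
    "lipids": ((1724, 1.0, 40), (2300, 0.5, 45), (2350, 0.9, 40)),
    "cellulose": ((2278, 1.0, 40), (2388, 0.8, 40)),
}


def default_component_library(wavelengths: np.ndarray | None = None
                              ) -> dict[str, np.ndarray]:
    """Pure-component absorption spectra on the instrument grid.

    Each component is a non-negative Gaussian-band mixture, max-normalised
    to 1 so configured amplitudes are in absorbance units."""
    wl = default_grid() if wavelengths is None else np.asarray(wavelengths, float)
    lib = {}
    for name, bands in COMPONENT_BANDS.items():
        spec = np.zeros_like(wl)
        for center, amp, width in bands:
            sigma = width / 2.355  # width given as FWHM
            spec += amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
        lib[name] = spec / spec.max()
    return lib


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class AnalyteSpec:
    """Distribution and spectral signature of one measured analyte.

    ``amplitude`` is the peak absorbance contributed by this analyte's
    component at the mean concentration; the contribution scales linearly
    with concentration (Beer-Lambert)."""

    name: str
    mean: float
    sd: float
    vmin: float
    vmax: float
    component: str
    amplitude: float = 0.2

    def __post_init__(self):
        if not (self.vmin < self.mean < self.vmax):
            raise GeneratorError(
                f"{self.name}: need min < mean < max "
                f"({self.vmin}, {self.mean}, {self.vmax})")
        if self.sd < 0 or self.amplitude < 0:
            raise GeneratorError(f"{self.name}: sd and amplitude must be >= 0")
        if self.vmax < self.mean - 6 * self.sd or self.vmin > self.mean + 6 * self.sd:
            raise GeneratorError(
                f"{self.name}: truncation window [{self.vmin}, {self.vmax}] "
                "is infeasibly far from the mean")


#: Reference-distribution defaults mirror the study population.
DEFAULT_ANALYTES = (
    AnalyteSpec("TPC", mean=24.27, sd=3.06, vmin=17.36, vmax=35.67,
                component="phenolics", amplitude=0.30),
    AnalyteSpec("TCC", mean=8.30, sd=1.82, vmin=2.84, vmax=13.73,
                component="carotenoids", amplitude=0.15),
)

#: Interfering matrix constituents: name -> (mean amplitude AU, relative sd).
DEFAULT_BACKGROUND: dict[str, tuple[float, float]] = {
    "water": (0.80, 0.10),
    "sugars": (0.40, 0.20),
    "lipids": (0.20, 0.20),
    "cellulose": (0.30, 0.15),
    "chlorophyll": (0.25, 0.30),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything that defines one synthetic study."""

    n_samples: int = 120
    seed: int = 0
    analytes: tuple[AnalyteSpec, ...] = DEFAULT_ANALYTES
    background: dict = field(default_factory=lambda: dict(DEFAULT_BACKGROUND))
    baseline_level: float = 0.5
    multiplicative_sd: float = 0.10
    additive_sd: float = 0.05
    tilt_sd: float = 0.02
    noise_sd: float = 0.001
    dry_matter_fraction: float = 0.1162
    wavelengths: np.ndarray = field(default_factory=default_grid)

    def __post_init__(self):
        if self.n_samples < 1:
            raise GeneratorError("n_samples must be >= 1")
        for v in (self.multiplicative_sd, self.additive_sd, self.tilt_sd,
                  self.noise_sd):
            if v < 0:
                raise GeneratorError("all noise/scatter sds must be >= 0")
        object.__setattr__(self, "wavelengths",
                           np.asarray(self.wavelengths, float))

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class SyntheticStudy:
    spectra: SpectraSet
    truths: dict[str, ReferenceValues]
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# Sampling


def truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                     vmin: float, vmax: float, size: int) -> np.ndarray:
    """Exact truncated-normal draws by rejection."""
    if sd == 0:
        if not vmin <= mean <= vmax:
            raise GeneratorError("degenerate distribution outside bounds")
        return np.full(size, mean)
    out = np.empty(size)
    have = 0
    while have < size:
        draw = rng.normal(mean, sd, size=max(size - have, 16))
        ok = draw[(draw >= vmin) & (draw <= vmax)]
        take = min(ok.size, size - have)
        out[have:have + take] = ok[:take]
        have += take
    return out


def generate_study(config: GeneratorConfig | None = None) -> SyntheticStudy:
    """Draw one synthetic study: truths, mixture spectra, scatter, noise.

    Deterministic for a fixed ``config.seed``."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    wl = cfg.wavelengths
    lib = default_component_library(wl)
    n = cfg.n_samples

    truths: dict[str, ReferenceValues] = {}
    ids = tuple(f"S{i + 1:03d}" for i in range(n))
    clean = np.full((n, wl.size), cfg.baseline_level)

    for spec in cfg.analytes:
        if spec.component not in lib:
            raise GeneratorError(f"unknown component {spec.component!r}")
        vals = truncated_normal(rng, spec.mean, spec.sd, spec.vmin,
                                spec.vmax, n)
        truths[spec.name] = ReferenceValues(ids, spec.name, vals)
        # Beer-Lambert: contribution linear in concentration
        clean += np.outer(vals * (spec.amplitude / spec.mean),
                          lib[spec.component])

    for name, (amp, rel_sd) in cfg.background.items():
        conc = amp * np.clip(1.0 + rel_sd * rng.standard_normal(n), 0.05, None)
        clean += np.outer(conc, lib[name])

    mult = 1.0 + cfg.multiplicative_sd * rng.standard_normal(n)
    add = cfg.additive_sd * rng.standard_normal(n)
    tilt = cfg.tilt_sd * rng.standard_normal(n)
    axis = (wl - wl[0]) / (wl[-1] - wl[0])  # 0..1 across the grid
    mat = (clean * mult[:, None] + add[:, None] + np.outer(tilt, axis)
           + cfg.noise_sd * rng.standard_normal((n, wl.size)))

    return SyntheticStudy(SpectraSet(wl, mat, ids), truths, cfg)


def fw_to_dw(value: float, dry_matter_fraction: float) -> float:
    """Convert a per-g-fresh-weight concentration to dry-weight basis."""
    if not 0 < dry_matter_fraction <= 1:
        raise GeneratorError("dry_matter_fraction must be in (0, 1]")
    return value / dry_matter_fraction
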