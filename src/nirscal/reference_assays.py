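"""Formula-level helpers for the wet-chemistry reference quantities.

These encode the unit arithmetic behind the two reference assays --
Folin-Ciocalteu total phenolics read at 765 nm against a gallic-acid
standard curve, and total carotenoids read at 450 nm in petroleum ether --
not the lab protocols themselves.  Curve parameters and the specific
absorptivity are user-supplied; the default A1%1cm of 2592 is the widely
used beta-carotene-in-petroleum-ether value and is an assumption, not a
measured constant of any particular study.
"""

from __future__ import annotations

from dataclasses import dataclass


class AssayError(ValueError):
    pass


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration of absorbance on concentration (mg mL^-1)."""

    slope: float       # absorbance per (mg mL^-1)
    intercept: float   # absorbance at zero concentration
    r2: float = 1.0

    def __post_init__(self):
        if self.slope <= 0:
            raise AssayError("standard-curve slope must be > 0")

    def concentration(self, absorbance: float) -> float:
        """Invert the curve: concentration in mg mL^-1."""
        c = (absorbance - self.intercept) / self.slope
        if c < 0:
            raise AssayError(
                f"absorbance {absorbance} below curve intercept "
                f"{self.intercept}: negative concentration")
        return c


def tpc_from_absorbance(a765: float, curve: StandardCurve,
                        extract_volume_ml: float, sample_mass_g: float,
                        dry_matter_fraction: float = 1.0) -> float:
    """Total phenolic content in mg GAE per g dry weight.

    concentration (mg GAE mL^-1) from the gallic-acid curve, times extract
    volume (mL), per g of sample corrected to dry-weight basis.
    """
    if extract_volume_ml <= 0 or sample_mass_g <= 0:
        raise AssayError("volume and mass must be > 0")
    if not 0 < dry_matter_fraction <= 1:
        raise AssayError("dry_matter_fraction must be in (0, 1]")
    conc = curve.concentration(a765)
    return conc * extract_volume_ml / (sample_mass_g * dry_matter_fraction)


#: Specific absorptivity A1%1cm of beta-carotene in petroleum ether.
BETA_CAROTENE_A1PCT = 2592.0


def tcc_from_absorbance(a450: float, sample_mass_g: float,
                        final_volume_ml: float = 50.0,
                        absorptivity: float = BETA_CAROTENE_A1PCT) -> float:
    """Total carotenoid content in ug per g of sample.

    TCC = A450 * V * 10^4 / (A1%1cm * m) -- the standard spectrophotometric
    total-carotenoid formula with the specific absorptivity as an explicit
    parameter.
    """
    if a450 < 0:
        raise AssayError("absorbance must be >= 0")
    if sample_mass_g <= 0 or final_volume_ml <= 0:
        raise AssayError("mass and volume must be > 0")
    if absorptivity <= 0:
        raise AssayError("absorptivity must be > 0")
    return a450 * final_volume_ml * 1e4 / (absorptivity * sample_mass_g)
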