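import numpy as np
import pytest

from nirscal import (GeneratorConfig, MathTreatment, SpectraSet,
                     generate_study)


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study (n=120, seed 0) reused across tests."""
    return generate_study(GeneratorConfig(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_spectra(rng):
    """A small random SpectraSet on a 50-point grid."""
    wl = 400.0 + 2.0 * np.arange(50)
    mat = rng.normal(0.5, 0.1, size=(12, 50))
    return SpectraSet(wl, mat, tuple(f"S{i}" for i in range(12)))


@pytest.fixture
def snvdt_2552():
    return MathTreatment(2, 5, 5, 2, "snv_dt")
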