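import numpy as np
import pytest

from lipannot.library import SpectralLibrary, default_class_defs
from lipannot.nomenclature import parse_lipid_name
from lipannot.synthetic import NoiseSpec, PlantedAnalyte, simulate_run


@pytest.fixture(scope="session")
def class_defs():
    return default_class_defs()


@pytest.fixture(scope="session")
def small_chain_pool():
    return [(14, 0), (16, 0), (18, 0), (18, 1), (18, 2), (20, 1), (20, 4), (22, 5)]


@pytest.fixture(scope="session")
def positive_library(class_defs, small_chain_pool):
    """Positive-mode library over a compact chain pool (fast to build)."""
    return SpectralLibrary.build(
        class_defs,
        chains=small_chain_pool,
        polarity="positive",
        classes=["PC", "PE", "PS", "TG", "LPC", "SM", "DG"],
    )


@pytest.fixture()
def pc_analyte():
    return PlantedAnalyte(
        parse_lipid_name("PC(16:0_18:1)"), "[M+H]+", rt_apex=3.0, height=1e6
    )


@pytest.fixture()
def clean_run(pc_analyte, class_defs):
    """Zero-noise single-analyte DDA run plus its truth table."""
    return simulate_run(
        [pc_analyte], NoiseSpec(), gradient_length=6.0, class_defs=class_defs, seed=7
    )


def assert_spectra_equal(scan_a, scan_b, atol=0.0):
    np.testing.assert_allclose(scan_a.mz, scan_b.mz, atol=atol)
    np.testing.assert_allclose(scan_a.intensity, scan_b.intensity, atol=atol)
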