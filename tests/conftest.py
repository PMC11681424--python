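import numpy as np
import pytest

from papunmix import (
    DEFAULT_WAVELENGTHS_NM,
    Cell,
    PhantomScene,
    WhiteReference,
    default_spectra,
)


@pytest.fixture(scope="session")
def wavelengths():
    return DEFAULT_WAVELENGTHS_NM.copy()


@pytest.fixture(scope="session")
def stains():
    """Phantom stain matrix on the default 14-band grid."""
    return default_spectra()


@pytest.fixture(scope="session")
def white(wavelengths):
    return WhiteReference(np.full(wavelengths.size, 4095.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def two_cell_scene(seed, photon_count=1e4, bit_depth=12):
    """One OG-rich (LEGH-like) and one EY-rich (EC-like) cell on glass."""
    cells = [
        Cell(
            center=(40.0, 40.0),
            cytoplasm_axes=(26.0, 30.0),
            nucleus_axes=(8.0, 7.0),
            cytoplasm_amounts={"EY": 0.15, "LG": 0.08, "OG": 0.40},
            nucleus_amounts={"H": 0.9, "EY": 0.05},
        ),
        Cell(
            center=(100.0, 90.0),
            cytoplasm_axes=(24.0, 28.0),
            nucleus_axes=(7.0, 8.0),
            cytoplasm_amounts={"EY": 0.45, "LG": 0.12, "OG": 0.01},
            nucleus_amounts={"H": 0.9, "EY": 0.05},
        ),
    ]
    return PhantomScene(
        shape=(144, 144),
        cells=cells,
        seed=seed,
        photon_count=photon_count,
        bit_depth=bit_depth,
    )
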