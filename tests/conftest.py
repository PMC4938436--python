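import numpy as np
import pytest

from specmix.spectra import (
    AcquisitionLayout,
    FluorophoreSpectrum,
    build_reference_matrix,
)
from specmix import simulation as sim


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_layout():
    """Two excitations, 3 channels each: the smallest interesting layout."""
    return AcquisitionLayout.regular([405.0, 488.0], [3, 3], channel_width=20.0)


@pytest.fixture
def toy_reference(small_layout):
    """Four hand-written 6-channel spectra with distinct shapes."""
    raw = np.array(
        [
            [1.0, 0.5, 0.1, 0.4, 0.2, 0.0],
            [0.2, 1.0, 0.5, 0.1, 0.5, 0.2],
            [0.0, 0.3, 1.0, 0.0, 0.2, 0.6],
            [0.1, 0.0, 0.2, 0.3, 0.8, 1.0],
        ]
    )
    spectra = [
        FluorophoreSpectrum(f"dye{k}", raw[k], normalized=True) for k in range(4)
    ]
    return build_reference_matrix(spectra, small_layout)


@pytest.fixture
def fig5_reference():
    """Four overlapping green dyes under single 488 nm excitation, 16x10nm."""
    layout = sim.single_excitation_layout()
    return sim.reference_matrix_from_models(sim.fig5_style_models(), layout)


@pytest.fixture
def full_reference():
    """The 16-dye palette on the six-laser default layout."""
    layout = sim.default_layout()
    return sim.reference_matrix_from_models(sim.DEFAULT_FLUOROPHORES, layout)
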