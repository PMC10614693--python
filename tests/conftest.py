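import numpy as np
import pytest

from sonopet import pam, protocol, synthetic


def toy_linear_array(n_elem: int = 8, pitch_mm: float = 1.0) -> protocol.TransducerArray:
    """Small linear receive array for fast PAM/spectrum tests."""
    x = (np.arange(n_elem) - (n_elem - 1) / 2.0) * pitch_mm
    pos = np.column_stack([x, np.zeros(n_elem), np.zeros(n_elem)])
    return protocol.TransducerArray(
        element_positions=pos,
        center_frequency_mhz=7.8,
        geometric_focus_mm=np.array([0.0, 0.0, 20.0]),
        aperture_extent_mm=np.array([n_elem * pitch_mm, 0.0, 0.0]),
        role="imaging",
    )


@pytest.fixture(scope="session")
def imaging():
    return protocol.imaging_array()


@pytest.fixture(scope="session")
def stable_rf(imaging):
    """One burst from a single stable source at (1.5, 0, 56) mm, light noise."""
    src = synthetic.CavitationSource(position_mm=(1.5, 0.0, 56.0), kind="stable")
    return synthetic.make_cavitation_rf([src], imaging, n_bursts=1, noise_sd=0.05, seed=3)


@pytest.fixture(scope="session")
def harmonic_map(stable_rf):
    return pam.asm_pam(stable_rf, pam.harmonic_bands(), depth_range_mm=(48.0, 64.0))
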