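import numpy as np
import pytest

from flowunwrap.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def ubend_clean():
    """Noise-free U-bend phantom: (field, vessel, waveform)."""
    spec = PhantomSpec(
        grid_shape=(48, 32, 14),
        voxel_spacing=(2.4, 2.4, 2.6),
        n_frames=14,
        snr=np.inf,
        seed=5,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def straight_clean():
    """Noise-free straight-tube phantom along z: (field, vessel, waveform)."""
    spec = PhantomSpec(
        grid_shape=(40, 40, 12),
        voxel_spacing=(2.0, 2.0, 2.0),
        n_frames=8,
        vessel="straight",
        vessel_radius=14.0,
        snr=np.inf,
        seed=11,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default noisy U-bend phantom: (field, vessel, waveform)."""
    spec = PhantomSpec(
        grid_shape=(48, 32, 14),
        voxel_spacing=(2.4, 2.4, 2.6),
        n_frames=14,
        snr=15.0,
        seed=21,
    )
    return generate_phantom(spec)
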