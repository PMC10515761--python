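import numpy as np
import pytest

from mrsproc import MRSVolume, PhantomSpec, SequenceMeta, build_csi_phantom, fid_to_spectrum


@pytest.fixture
def meta() -> SequenceMeta:
    """Default 3 T 1H acquisition: f0 = 127.74 MHz, SW = 2000 Hz."""
    return SequenceMeta(transmitter_frequency=127.74, spectral_width=2000.0)


@pytest.fixture
def svs_volume(meta) -> MRSVolume:
    """A small noiseless single-voxel FID volume."""
    from mrsproc.phantom import Peak, simulate_fid

    fid = simulate_fid(meta, [Peak("NAA", 2.01, 1.0, 0.1)], 512)
    return MRSVolume(fid.reshape(1, 1, 1, -1), np.diag([20.0, 20.0, 20.0, 1.0]), meta)


@pytest.fixture
def small_phantom():
    """4x4x1 noiseless CSI phantom with one lipid-contaminated voxel."""
    spec = PhantomSpec(grid_shape=(4, 4, 1), n_points=512, artifact_voxels=[(0, 1, 0)], seed=11)
    suppressed, unsuppressed, truth = build_csi_phantom(spec)
    return spec, suppressed, unsuppressed, truth


@pytest.fixture
def small_spectrum(small_phantom):
    spec, suppressed, _, truth = small_phantom
    freq, axis = fid_to_spectrum(suppressed)
    return spec, freq, axis, truth
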