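"""Shared independent oracles for the test suite."""

import numpy as np

from mrsproc import LabelImage, MRSVolume


def brute_force_assignment(labels: LabelImage, csi: MRSVolume) -> np.ndarray:
    """Triple-loop voxel-centre assignment: the reference for regrid_to_csi."""
    inv = np.linalg.inv(csi.affine)
    out = np.full(labels.data.shape, -1, dtype=int)
    nx, ny, nz = csi.grid_shape
    for i in range(labels.data.shape[0]):
        for j in range(labels.data.shape[1]):
            for k in range(labels.data.shape[2]):
                world = labels.affine @ np.array([i, j, k, 1.0])
                idx = np.rint((inv @ world)[:3]).astype(int)
                if 0 <= idx[0] < nx and 0 <= idx[1] < ny and 0 <= idx[2] < nz:
                    out[i, j, k] = np.ravel_multi_index(tuple(idx), (nx, ny, nz))
    return out
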