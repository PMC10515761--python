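"""FID <-> spectrum transforms and the ppm axis.

The free induction decay (FID) sampled at dwell time ``1/SW`` and its
spectrum are related by the discrete Fourier transform along the spectral
dimension.  Conventions, fixed once and used everywhere:

* unitary FFT (``norm="ortho"``) so the round trip and Parseval's identity
  hold symmetrically;
* the zero-frequency (on-resonance) bin is shifted to the centre of the
  axis, then the axis is reversed so ppm decreases with bin index — the
  standard MRS display order;
* ``ppm_k = reference_ppm + f_k / transmitter_frequency`` with ``f_k`` the
  centred FFT bin frequencies in Hz and the transmitter frequency in MHz.

No apodisation, zero-filling or phase correction is applied here; baseline
and lineshape modelling are delegated to downstream fitting (LCModel).
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sp_fft

from .model import (
    DOMAIN_FREQUENCY,
    DOMAIN_TIME,
    InvariantViolation,
    MRSVolume,
    SequenceMeta,
    SpectralAxis,
)

__all__ = [
    "make_ppm_axis",
    "fid_to_spectrum",
    "spectrum_to_fid",
    "crop_ppm",
    "heatmap_collapse",
]


def make_ppm_axis(meta: SequenceMeta, n: int) -> SpectralAxis:
    """Chemical-shift axis for an ``n``-bin spectrum under ``meta``.

    The centred FFT frequencies span ``[-SW/2, +SW/2)`` Hz, so the axis
    span (``n`` times the bin width) equals ``SW / f0`` ppm exactly;
    doubling ``n`` halves the bin width and leaves the span unchanged.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 spectral bins, got {n}")
    f_hz = np.fft.fftshift(np.fft.fftfreq(n, d=meta.dwell_time))
    ppm = meta.reference_ppm + f_hz / meta.transmitter_frequency
    return SpectralAxis(
        ppm=ppm[::-1].copy(),  # display order: decreasing ppm
        spectral_width=meta.spectral_width,
        transmitter_frequency=meta.transmitter_frequency,
        reference_ppm=meta.reference_ppm,
    )


def fid_to_spectrum(vol: MRSVolume) -> tuple[MRSVolume, SpectralAxis]:
    """FFT each voxel's FID into a spectrum on the matching ppm axis."""
    vol.require_domain(DOMAIN_TIME)
    spec = np.fft.fftshift(sp_fft.fft(vol.data, axis=-1, norm="ortho"), axes=-1)
    spec = spec[..., ::-1]  # match the decreasing-ppm display order
    out = vol.with_data(spec, domain_tag=DOMAIN_FREQUENCY)
    return out, make_ppm_axis(vol.meta, vol.n_points)


def spectrum_to_fid(vol: MRSVolume) -> MRSVolume:
    """Exact inverse of :func:`fid_to_spectrum`."""
    vol.require_domain(DOMAIN_FREQUENCY)
    spec = vol.data[..., ::-1]
    fid = sp_fft.ifft(np.fft.ifftshift(spec, axes=-1), axis=-1, norm="ortho")
    return vol.with_data(fid, domain_tag=DOMAIN_TIME)


def crop_ppm(
    vol: MRSVolume, axis: SpectralAxis, lo: float, hi: float
) -> tuple[MRSVolume, SpectralAxis]:
    """Retain exactly the bins with ``lo <= ppm <= hi`` (closed interval)."""
    vol.require_domain(DOMAIN_FREQUENCY)
    if axis.n != vol.n_points:
        raise InvariantViolation(
            f"axis length {axis.n} does not match spectral dimension {vol.n_points}"
        )
    mask = axis.window_mask(lo, hi)
    if not mask.any():
        raise ValueError(
            f"ppm window [{lo}, {hi}] does not intersect axis range "
            f"[{axis.ppm.min():.4g}, {axis.ppm.max():.4g}]"
        )
    ppm = axis.ppm[mask]
    if ppm.size < 2:
        raise ValueError(f"ppm window [{lo}, {hi}] retains fewer than 2 bins")
    cropped_axis = SpectralAxis(
        ppm=ppm,
        spectral_width=vol.meta.spectral_width,
        transmitter_frequency=axis.transmitter_frequency,
        reference_ppm=axis.reference_ppm,
    )
    return vol.with_data(vol.data[..., mask]), cropped_axis


def heatmap_collapse(vol: MRSVolume, eps: float | None = None) -> np.ndarray:
    """Collapse the spectral dimension to one scalar per voxel.

    The value is the log of the mean absolute real spectral amplitude,
    ``log(mean_k |Re s_k| + eps)`` — the display used for coarse
    orientation-phantom heat maps.  ``eps`` defaults to ``1e-12`` times the
    volume's maximum ``|Re|`` (or 1 if the volume is all zero) so the log
    stays finite on empty voxels.
    """
    vol.require_domain(DOMAIN_FREQUENCY)
    re = np.abs(vol.data.real)
    if eps is None:
        peak = float(re.max()) if re.size else 0.0
        eps = 1e-12 * (peak if peak > 0 else 1.0)
    return np.log(re.mean(axis=-1) + eps)
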