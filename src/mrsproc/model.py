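"""Core spatiospectral MRS data model.

MRS data live on a coarse spatial grid (1x1x1 for single-voxel spectroscopy,
2-D/3-D for chemical shift imaging) with one complex spectral dimension per
voxel.  The model mirrors the 4-D NIFTI convention used for fMRI/dMRI: the
image array carries the signal, a 4x4 affine carries spatial location and
orientation (RAS+ world millimetres, voxel-centre sampling, 0-based indices),
and a small set of sequence parameters travels alongside in a JSON sidecar.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DOMAIN_TIME",
    "DOMAIN_FREQUENCY",
    "SUPPRESSED",
    "UNSUPPRESSED",
    "SequenceMeta",
    "MRSVolume",
    "SpectralAxis",
    "validate_volume",
    "InvariantViolation",
]

DOMAIN_TIME = "time"
DOMAIN_FREQUENCY = "frequency"
SUPPRESSED = "suppressed"
UNSUPPRESSED = "unsuppressed"

_VENDORS = ("philips", "siemens", "synthetic")


class InvariantViolation(ValueError):
    """A data-model invariant does not hold."""


@dataclass
class SequenceMeta:
    """Acquisition parameters needed for Hz<->ppm conversion and export.

    Parameters
    ----------
    transmitter_frequency : float
        Spectrometer (transmitter) frequency in MHz; e.g. ~127.74 for 1H at 3 T.
    spectral_width : float
        Sampling bandwidth in Hz.
    echo_time : float
        Echo time in ms.
    dwell_time : float, optional
        Sampling interval in s; defaults to ``1 / spectral_width``.
    nucleus : str
        Resonant nucleus, default ``"1H"``.
    reference_ppm : float
        Chemical shift assigned to the zero-frequency (on-resonance) bin;
        default 4.65 ppm, water at body temperature.
    vendor : str
        One of ``philips``, ``siemens``, ``synthetic``.
    extra : dict
        Unknown sidecar keys, preserved verbatim across read/write.
    """

    transmitter_frequency: float
    spectral_width: float
    echo_time: float = 30.0
    dwell_time: float | None = None
    nucleus: str = "1H"
    reference_ppm: float = 4.65
    vendor: str = "synthetic"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dwell_time is None and self.spectral_width > 0:
            self.dwell_time = 1.0 / self.spectral_width


@dataclass
class MRSVolume:
    """A complex spatiospectral image: ``data[x, y, z, k]``.

    ``k`` indexes time points (``domain_tag == "time"``) or spectral bins
    (``domain_tag == "frequency"``).  ``affine`` maps 0-based voxel indices to
    RAS+ world mm at voxel centres.  ``suppression_tag`` records whether the
    water resonance was suppressed during acquisition.
    """

    data: np.ndarray
    affine: np.ndarray
    meta: SequenceMeta
    domain_tag: str = DOMAIN_TIME
    suppression_tag: str = SUPPRESSED

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def n_points(self) -> int:
        return self.data.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    def require_domain(self, domain: str) -> None:
        if self.domain_tag != domain:
            raise InvariantViolation(
                f"operation requires a {domain}-domain volume, got {self.domain_tag!r}"
            )

    def with_data(self, data: np.ndarray, *, domain_tag: str | None = None) -> "MRSVolume":
        return replace(
            self,
            data=np.asarray(data, dtype=np.complex128),
            domain_tag=self.domain_tag if domain_tag is None else domain_tag,
        )

    def voxel_center_world(self, index) -> np.ndarray:
        """World-mm coordinate of a voxel centre (RAS+)."""
        ijk = np.asarray(index, dtype=float)
        return (self.affine @ np.append(ijk, 1.0))[:3]


@dataclass
class SpectralAxis:
    """Per-bin chemical-shift values plus the parameters that generate them.

    ``ppm`` is strictly monotonic; the conventional MRS display order is
    decreasing ppm with increasing bin index.  ``span`` is the total axis
    width ``n * |bin spacing| == spectral_width / transmitter_frequency``.
    """

    ppm: np.ndarray
    spectral_width: float
    transmitter_frequency: float
    reference_ppm: float

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=np.float64)
        d = np.diff(self.ppm)
        if self.ppm.ndim != 1 or self.ppm.size < 2:
            raise InvariantViolation("spectral axis needs >= 2 ppm values")
        if not (np.all(d > 0) or np.all(d < 0)):
            raise InvariantViolation("ppm axis must be strictly monotonic")

    @property
    def n(self) -> int:
        return self.ppm.size

    @property
    def bin_width(self) -> float:
        """|Δppm| between adjacent bins."""
        return abs(float(self.ppm[1] - self.ppm[0]))

    @property
    def span(self) -> float:
        return self.n * self.bin_width

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of bins in the closed ppm interval [lo, hi]."""
        if not lo < hi:
            raise ValueError(f"require lo < hi, got [{lo}, {hi}]")
        return (self.ppm >= lo) & (self.ppm <= hi)


def validate_volume(vol: MRSVolume, axis: SpectralAxis | None = None) -> list[str]:
    """Check every data-model invariant; return a description per violation.

    Validation never raises: a malformed volume yields messages, each naming
    the offending field.
    """
    violations: list[str] = []
    data = np.asarray(vol.data)
    if data.ndim != 4:
        violations.append(f"data: expected 4 dimensions, got {data.ndim}")
    elif data.shape[-1] < 2:
        violations.append(f"data: spectral dimension must have >= 2 points, got {data.shape[-1]}")
    aff = np.asarray(vol.affine, dtype=float)
    if aff.shape != (4, 4):
        violations.append(f"affine: expected shape (4, 4), got {aff.shape}")
    else:
        det = float(np.linalg.det(aff[:3, :3]))
        if det == 0.0 or not np.isfinite(det):
            violations.append("affine: upper-left 3x3 block is singular")
    if vol.domain_tag not in (DOMAIN_TIME, DOMAIN_FREQUENCY):
        violations.append(f"domain_tag: {vol.domain_tag!r} not in {{time, frequency}}")
    if vol.suppression_tag not in (SUPPRESSED, UNSUPPRESSED):
        violations.append(
            f"suppression_tag: {vol.suppression_tag!r} not in {{suppressed, unsuppressed}}"
        )
    m = vol.meta
    if not m.transmitter_frequency > 0:
        violations.append("meta.transmitter_frequency: must be > 0")
    if not m.spectral_width > 0:
        violations.append("meta.spectral_width: must be > 0")
    elif m.dwell_time is None or abs(m.dwell_time * m.spectral_width - 1.0) > 1e-9:
        violations.append("meta.dwell_time: inconsistent with 1 / spectral_width")
    if m.vendor not in _VENDORS:
        violations.append(f"meta.vendor: {m.vendor!r} not in {_VENDORS}")
    if axis is not None and data.ndim == 4 and axis.n != data.shape[-1]:
        violations.append(
            f"axis.ppm: length {axis.n} does not match spectral dimension {data.shape[-1]}"
        )
    return violations
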