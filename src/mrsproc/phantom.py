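"""Synthetic MRS phantom simulator.

Every test input the package needs is generated here: Lorentzian-lineshape
FIDs with named metabolite peaks, CSI grids with white-matter / deep-gray
layouts and matching high-resolution segmentations, lipid-contaminated
voxels, water-unsuppressed companions, asymmetric orientation phantoms, and
vendor-dialect DICOM fixtures.

Signal model — a sum of exponentially damped complex sinusoids:

    s(t_k) = sum_m A_m * exp(i 2 pi f_m t_k) * exp(-t_k / T2*_m) + noise,

with ``f_m = (ppm_m - reference_ppm) * f0`` in Hz (``f0`` in MHz), sampled
at ``t_k = k * dwell`` and complex Gaussian noise of a stated per-point SD.
The Fourier transform of each term is a Lorentzian of half-width
``1 / (pi T2*)`` Hz centred at ``f_m``, which gives every downstream oracle
a closed form.  ``analytic_spectrum`` evaluates the sampled transform
directly in the frequency domain (a geometric series per peak), entirely
independent of the FFT code path.

Defaults model a 3 T 1H acquisition: f0 = 127.74 MHz, spectral width
2000 Hz, 1024 points, TE 30 ms, 10 mm CSI voxels (20 mm for single-voxel
use).  Metabolite positions are the standard singlet shifts (NAA 2.01,
Cr 3.03, Cho 3.20, Lac 1.31 ppm); lipid contamination is a broad resonance
at 1.30 ppm with a five-fold shorter T2*.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import dicom as vdicom
from .model import (
    DOMAIN_TIME,
    SUPPRESSED,
    UNSUPPRESSED,
    MRSVolume,
    SequenceMeta,
)
from .spatial import LabelImage
from .spectral import fid_to_spectrum, heatmap_collapse, make_ppm_axis

__all__ = [
    "Peak",
    "PhantomSpec",
    "PhantomTruth",
    "default_metabolites",
    "simulate_fid",
    "analytic_spectrum",
    "build_csi_phantom",
    "orientation_phantom",
    "detect_marker",
    "orientation_mismatch",
    "write_vendor_fixture",
]

WM, DGM = 1, 2  # label values used by the built-in tissue layout


@dataclass(frozen=True)
class Peak:
    """One Lorentzian resonance: position (ppm), amplitude (a.u.), T2* (s)."""

    name: str
    ppm: float
    amplitude: float
    t2star: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"{self.name}: amplitude must be >= 0")
        if not self.t2star > 0:
            raise ValueError(f"{self.name}: T2* must be > 0")


def default_metabolites() -> list[Peak]:
    return [
        Peak("NAA", 2.01, 1.0, 0.1),
        Peak("Cr", 3.03, 1.0, 0.1),
        Peak("Cho", 3.20, 0.8, 0.1),
        Peak("Lac", 1.31, 0.5, 0.1),
    ]


@dataclass
class PhantomSpec:
    """Declarative description of one synthetic acquisition.

    The same seed always reproduces the same phantom bit for bit.
    ``tissue_scales`` multiply the metabolite amplitudes inside the built-in
    left-half-WM / right-half-dGM layout; ``artifact_voxels`` receive an
    added broad lipid resonance of amplitude ``lipid_amplitude``.
    """

    peaks: list[Peak] = field(default_factory=default_metabolites)
    grid_shape: tuple[int, int, int] = (8, 8, 1)
    voxel_size_mm: float = 10.0
    n_points: int = 1024
    transmitter_frequency: float = 127.74  # MHz (1H at 3 T)
    spectral_width: float = 2000.0  # Hz
    echo_time: float = 30.0  # ms
    reference_ppm: float = 4.65
    noise_sd: float = 0.0  # per-point complex Gaussian SD (a.u.)
    artifact_voxels: list[tuple[int, int, int]] = field(default_factory=list)
    lipid_ppm: float = 1.30
    lipid_amplitude: float = 10.0
    lipid_t2star: float = 0.02  # 5x shorter than the metabolites
    water_amplitude: float = 100.0
    tissue_scales: dict = field(default_factory=lambda: {"WM": 2.0, "dGM": 1.0})
    highres_factor: int = 4
    gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.artifact_voxels = [tuple(int(i) for i in v) for v in self.artifact_voxels]
        for v in self.artifact_voxels:
            if any(i < 0 or i >= s for i, s in zip(v, self.grid_shape)):
                raise ValueError(f"artifact voxel {v} outside grid {self.grid_shape}")

    @property
    def meta(self) -> SequenceMeta:
        return SequenceMeta(
            transmitter_frequency=self.transmitter_frequency,
            spectral_width=self.spectral_width,
            echo_time=self.echo_time,
            reference_ppm=self.reference_ppm,
            vendor="synthetic",
        )

    def affine(self) -> np.ndarray:
        """RAS+ affine centring the grid on the world origin."""
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        for ax, n in enumerate(self.grid_shape):
            aff[ax, 3] = -self.voxel_size_mm * (n - 1) / 2.0
        return aff

    @property
    def lipid_peak(self) -> Peak:
        return Peak("lipid", self.lipid_ppm, self.lipid_amplitude, self.lipid_t2star)

    @property
    def water_peak(self) -> Peak:
        return Peak("water", self.reference_ppm, self.water_amplitude, 0.1)

    def to_json(self, path) -> Path:
        payload = asdict(self)
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_json(cls, path) -> "PhantomSpec":
        payload = json.loads(Path(path).read_text())
        payload["peaks"] = [Peak(**p) for p in payload.get("peaks", [])]
        return cls(**payload)


@dataclass
class PhantomTruth:
    """Ground truth for downstream oracles.

    ``labels`` is the high-resolution segmentation (WM=1, dGM=2),
    ``brain_mask`` its binarisation, ``tissue_amplitudes`` the per-tissue
    metabolite amplitude scale actually simulated, ``csi_tissue`` the
    CSI-grid tissue label each voxel was simulated with.
    """

    labels: LabelImage
    brain_mask: LabelImage
    artifact_voxels: list[tuple[int, int, int]]
    tissue_amplitudes: dict
    csi_tissue: np.ndarray

    def to_json(self, path) -> Path:
        payload = {
            "artifact_voxels": [list(v) for v in self.artifact_voxels],
            "tissue_amplitudes": self.tissue_amplitudes,
            "csi_tissue": self.csi_tissue.tolist(),
            "label_names": {str(k): v for k, v in self.labels.labels.items()},
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path


def simulate_fid(
    meta: SequenceMeta,
    peaks,
    n: int,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample the damped-sinusoid signal model for one voxel."""
    t = np.arange(n) * meta.dwell_time
    fid = np.zeros(n, dtype=np.complex128)
    for p in peaks:
        f_hz = (p.ppm - meta.reference_ppm) * meta.transmitter_frequency
        fid += p.amplitude * np.exp((2j * np.pi * f_hz - 1.0 / p.t2star) * t)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        fid += noise_sd * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
    return fid


def analytic_spectrum(meta: SequenceMeta, peaks, n: int) -> np.ndarray:
    """Closed-form noiseless spectrum on the display-ordered ppm axis.

    For each peak the unitary DFT of the sampled damped sinusoid is a
    geometric series, ``(1/sqrt(n)) * (1 - r^n) / (1 - r)`` with
    ``r = exp((i 2 pi (f_m - f_bin) - 1/T2*) * dwell)`` — evaluated here
    term by term with no FFT, as an independent oracle for the FFT path.
    """
    axis = make_ppm_axis(meta, n)
    f_bin = (axis.ppm - meta.reference_ppm) * meta.transmitter_frequency  # Hz
    out = np.zeros(n, dtype=np.complex128)
    for p in peaks:
        f_hz = (p.ppm - meta.reference_ppm) * meta.transmitter_frequency
        r = np.exp((2j * np.pi * (f_hz - f_bin) - 1.0 / p.t2star) * meta.dwell_time)
        out += p.amplitude * (1.0 - r**n) / (1.0 - r)
    return out / np.sqrt(n)


def _tissue_layout(spec: PhantomSpec) -> np.ndarray:
    """CSI-grid tissue labels: left half WM (1), right half dGM (2)."""
    nx, ny, nz = spec.grid_shape
    tissue = np.full(spec.grid_shape, DGM, dtype=np.int16)
    tissue[: max(nx // 2, 1)] = WM
    return tissue


def _highres_labels(spec: PhantomSpec, csi_tissue: np.ndarray) -> LabelImage:
    """Upsample the CSI tissue layout onto an aligned finer grid.

    The high-resolution grid covers exactly the CSI field of view with
    ``highres_factor`` voxels per CSI voxel per axis; its affine is derived
    from the CSI affine so the two grids are geometrically consistent.
    """
    f = spec.highres_factor
    hi = np.repeat(np.repeat(np.repeat(csi_tissue, f, axis=0), f, axis=1), f, axis=2)
    csi_aff = spec.affine()
    aff = csi_aff.copy()
    aff[:3, :3] = csi_aff[:3, :3] / f
    # voxel (0,0,0) of the fine grid sits at continuous CSI index (0.5/f - 0.5)
    offset = np.full(3, 0.5 / f - 0.5)
    aff[:3, 3] = (csi_aff @ np.append(offset, 1.0))[:3]
    return LabelImage(hi.astype(np.int16), aff, labels={WM: "WM", DGM: "dGM"})


def build_csi_phantom(
    spec: PhantomSpec,
) -> tuple[MRSVolume, MRSVolume, PhantomTruth]:
    """Simulate a full CSI acquisition plus its ground truth.

    Returns the water-suppressed volume (metabolites, tissue-scaled, lipid
    artifacts in the designated voxels), the unsuppressed companion (water
    at ``water_amplitude`` on top of the same metabolites) and the truth
    needed by every downstream oracle.
    """
    rng = np.random.default_rng(spec.seed)
    meta = spec.meta
    csi_tissue = _tissue_layout(spec)
    scale_of = {WM: spec.tissue_scales.get("WM", 1.0), DGM: spec.tissue_scales.get("dGM", 1.0)}
    shape = spec.grid_shape + (spec.n_points,)
    sup = np.zeros(shape, dtype=np.complex128)
    unsup = np.zeros(shape, dtype=np.complex128)
    artifact_set = set(spec.artifact_voxels)
    for idx in np.ndindex(spec.grid_shape):
        scale = scale_of[int(csi_tissue[idx])]
        peaks = [replace(p, amplitude=p.amplitude * scale) for p in spec.peaks]
        if idx in artifact_set:
            peaks = peaks + [spec.lipid_peak]
        sup[idx] = simulate_fid(meta, peaks, spec.n_points, spec.noise_sd, rng)
        unsup[idx] = simulate_fid(
            meta,
            [replace(p, amplitude=p.amplitude * scale) for p in spec.peaks]
            + [spec.water_peak],
            spec.n_points,
            spec.noise_sd,
            rng,
        )
    affine = spec.affine()
    suppressed = MRSVolume(sup * spec.gain, affine, meta, DOMAIN_TIME, SUPPRESSED)
    unsuppressed = MRSVolume(unsup * spec.gain, affine.copy(), meta, DOMAIN_TIME, UNSUPPRESSED)
    labels = _highres_labels(spec, csi_tissue)
    truth = PhantomTruth(
        labels=labels,
        brain_mask=labels.binarize(),
        artifact_voxels=list(spec.artifact_voxels),
        tissue_amplitudes={
            "WM": scale_of[WM],
            "dGM": scale_of[DGM],
            "peaks": {p.name: p.amplitude for p in spec.peaks},
        },
        csi_tissue=csi_tissue,
    )
    return suppressed, unsuppressed, truth


def orientation_phantom(
    spec: PhantomSpec, marker_index: tuple[int, int, int] | None = None
) -> tuple[MRSVolume, dict]:
    """Asymmetric phantom: one bright off-axis corner voxel.

    Low CSI resolution makes a flipped or transposed image hard to spot on
    anatomy, so a deliberately asymmetric layout is simulated: every voxel
    carries a weak on-resonance peak, the marker voxel a 10x brighter one.
    The truth records the marker's index and world coordinate; after any
    conversion path the heat-map argmax must land back on that coordinate.
    """
    if any(s < 2 for s in spec.grid_shape[:2]):
        raise ValueError("orientation phantom needs a grid >= 2 along x and y")
    if marker_index is None:
        marker_index = (spec.grid_shape[0] - 1, 0, 0)
    marker_index = tuple(int(i) for i in marker_index)
    meta = spec.meta
    shape = spec.grid_shape + (spec.n_points,)
    data = np.zeros(shape, dtype=np.complex128)
    rng = np.random.default_rng(spec.seed)
    background = Peak("background", spec.reference_ppm, 1.0, 0.1)
    marker = Peak("marker", spec.reference_ppm, 10.0, 0.1)
    for idx in np.ndindex(spec.grid_shape):
        peak = marker if idx == marker_index else background
        data[idx] = simulate_fid(meta, [peak], spec.n_points, spec.noise_sd, rng)
    vol = MRSVolume(data, spec.affine(), meta, DOMAIN_TIME, SUPPRESSED)
    truth = {
        "marker_index": marker_index,
        "marker_world": vol.voxel_center_world(marker_index).tolist(),
    }
    return vol, truth


def detect_marker(vol: MRSVolume) -> tuple[tuple[int, int, int], np.ndarray]:
    """Locate the brightest voxel of a phantom via the heat-map collapse."""
    if vol.domain_tag == DOMAIN_TIME:
        vol, _ = fid_to_spectrum(vol)
    heat = heatmap_collapse(vol)
    idx = tuple(int(i) for i in np.unravel_index(int(np.argmax(heat)), heat.shape))
    return idx, vol.voxel_center_world(idx)


def orientation_mismatch(
    vol: MRSVolume, truth: dict, tol_mm: float = 1e-6
) -> float:
    """Distance (mm) between the detected marker and its true world position.

    A value above ``tol_mm`` means the conversion path scrambled the
    orientation (e.g. an undetected left-right flip).  Note the check is
    blind to flips that map the marker onto an equally bright twin — a
    symmetric phantom cannot reveal them, which is exactly why the phantom
    is built asymmetric.
    """
    _, world = detect_marker(vol)
    return float(np.linalg.norm(world - np.asarray(truth["marker_world"])))


def write_vendor_fixture(spec: PhantomSpec, vendor: str, path) -> Path:
    """Write the phantom as a vendor-dialect DICOM fixture file.

    Philips files carry both the suppressed and unsuppressed payloads,
    Siemens only the suppressed one; ``spec.gain`` scales the stored signal
    to emulate vendor-dependent amplitude conventions.
    """
    suppressed, unsuppressed, _ = build_csi_phantom(spec)
    affine = spec.affine()
    # invert the LPS->RAS negation to recover the DICOM-side geometry
    lps = np.diag([-1.0, -1.0, 1.0, 1.0]) @ affine
    spacing = np.linalg.norm(lps[:3, :3], axis=0)
    geometry = vdicom.MrsGeometry(
        position=lps[:3, 3],
        row_cosines=lps[:3, 0] / spacing[0],
        col_cosines=lps[:3, 1] / spacing[1],
        spacing=spacing,
        shape=spec.grid_shape,
    )
    return vdicom.write_fixture_dicom(
        path,
        vendor,
        geometry,
        spec.meta,
        suppressed=suppressed.data,
        unsuppressed=unsuppressed.data if vendor == "philips" else None,
        uid_seed=spec.seed,
    )
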