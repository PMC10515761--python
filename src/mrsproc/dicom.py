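"""Vendor-style MRS DICOM ingestion.

Philips MRS DICOMs carry two interleaved datasets per acquisition — a
water-suppressed and a water-unsuppressed spectrum — while Siemens exports
only the suppressed one.  Both vendors encode the complex time-domain FID in
non-standard fields, so a reader must (a) know which payload it is handed
and (b) rebuild the spatial affine from the DICOM geometry tags.

Real scanner dialects are numerous and undocumented; this module reads a
declared fixture dialect (below) through the same ``parse_philips`` /
``parse_siemens`` interface a real-dialect reader would use.  Production
dialects are an extension point behind these functions.

Fixture dialect (DICOM Part-10, explicit VR little endian):

* ``Manufacturer`` selects the vendor branch.
* Grid: ``Columns`` = x, ``Rows`` = y, ``NumberOfFrames`` = z.
* Geometry: ``ImagePositionPatient`` (LPS mm of the (0,0,0) voxel centre),
  ``ImageOrientationPatient`` (x- then y-axis direction cosines, LPS),
  ``PixelSpacing`` = [y, x] mm, ``SpacingBetweenSlices`` = z mm.
* Sequence: ``ImagingFrequency`` (MHz), ``SpectralWidth`` (Hz),
  ``EchoTime`` (ms), ``ChemicalShiftReference`` (ppm).
* Payloads: private block ``(7FE1,0010) = "MRSPROC"``; element 0x01 holds
  the suppressed FID, 0x02 (Philips only) the unsuppressed one, each as
  little-endian float32 (real, imag) pairs in C order over (x, y, z, t).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

from .model import (
    DOMAIN_TIME,
    SUPPRESSED,
    UNSUPPRESSED,
    MRSVolume,
    SequenceMeta,
)

__all__ = [
    "MrsGeometry",
    "DicomMrsSeries",
    "build_affine",
    "parse_philips",
    "parse_siemens",
    "load_series",
    "write_fixture_dicom",
]

PRIVATE_CREATOR = "MRSPROC"
PRIVATE_GROUP = 0x7FE1
_ELEM_SUPPRESSED = 0x01
_ELEM_UNSUPPRESSED = 0x02
MRS_STORAGE_UID = "1.2.840.10008.5.1.4.1.1.4.2"
_UID_ROOT = "1.2.826.0.1.3680043.10.1241"

_LPS_TO_RAS = np.diag([-1.0, -1.0, 1.0, 1.0])


@dataclass
class MrsGeometry:
    """DICOM spatial descriptors for a CSI/SVS grid (LPS convention)."""

    position: np.ndarray      # LPS mm of the first voxel centre
    row_cosines: np.ndarray   # direction of increasing x index
    col_cosines: np.ndarray   # direction of increasing y index
    spacing: np.ndarray       # (x, y, z) mm
    shape: tuple[int, int, int]


@dataclass
class DicomMrsSeries:
    """One parsed vendor MRS series: raw payload(s) + geometry + sequence."""

    paths: list[Path]
    vendor: str
    payloads: dict[str, np.ndarray]  # tag -> complex (x, y, z, t) array
    geometry: MrsGeometry
    meta: SequenceMeta = field(repr=False, default=None)  # type: ignore[assignment]


def build_affine(geometry: MrsGeometry) -> np.ndarray:
    """RAS+ voxel-to-world affine from DICOM LPS geometry.

    Voxel index steps follow the row/column cosines at the stated spacing;
    the slice axis is the right-handed cross product of the two.  DICOM
    world coordinates are LPS, so the first two world axes are negated to
    reach the NIFTI RAS convention.
    """
    row = np.asarray(geometry.row_cosines, dtype=float)
    col = np.asarray(geometry.col_cosines, dtype=float)
    spacing = np.asarray(geometry.spacing, dtype=float)
    for name, vec in (("row", row), ("column", col)):
        if abs(np.linalg.norm(vec) - 1.0) > 1e-6:
            raise ValueError(f"{name} direction cosines are not unit length")
    if abs(float(row @ col)) > 1e-6:
        raise ValueError("row/column direction cosines are not orthogonal")
    if np.any(spacing <= 0):
        raise ValueError(f"voxel spacing must be positive, got {spacing}")
    normal = np.cross(row, col)
    lps = np.eye(4)
    lps[:3, 0] = row * spacing[0]
    lps[:3, 1] = col * spacing[1]
    lps[:3, 2] = normal * spacing[2]
    lps[:3, 3] = np.asarray(geometry.position, dtype=float)
    return _LPS_TO_RAS @ lps


def _decode_payload(blob: bytes, shape: tuple[int, int, int]) -> np.ndarray:
    flat = np.frombuffer(blob, dtype="<f4")
    n_vox = int(np.prod(shape))
    if flat.size % (2 * n_vox):
        raise ValueError(
            f"payload of {flat.size} floats does not tile a {shape} grid "
            "of (real, imag) pairs"
        )
    n = flat.size // (2 * n_vox)
    pairs = flat.reshape(*shape, n, 2).astype(np.float64)
    return (pairs[..., 0] + 1j * pairs[..., 1]).astype(np.complex128)


def _encode_payload(data: np.ndarray) -> bytes:
    arr = np.ascontiguousarray(data, dtype=np.complex128)
    pairs = np.empty(arr.shape + (2,), dtype="<f4")
    pairs[..., 0] = arr.real
    pairs[..., 1] = arr.imag
    return pairs.tobytes()


def load_series(paths) -> DicomMrsSeries:
    """Read fixture-dialect DICOM file(s) into a :class:`DicomMrsSeries`."""
    paths = [Path(p) for p in (paths if isinstance(paths, (list, tuple)) else [paths])]
    if len(paths) != 1:
        raise ValueError("the fixture dialect stores one series per file")
    path = paths[0]
    if not path.exists():
        raise FileNotFoundError(f"missing DICOM file: {path}")
    ds = pydicom.dcmread(str(path))
    manufacturer = str(getattr(ds, "Manufacturer", "")).strip().lower()
    if "philips" in manufacturer:
        vendor = "philips"
    elif "siemens" in manufacturer:
        vendor = "siemens"
    else:
        raise ValueError(f"{path}: unrecognised Manufacturer {manufacturer!r}")

    shape = (int(ds.Columns), int(ds.Rows), int(getattr(ds, "NumberOfFrames", 1)))
    spacing = np.array(
        [float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0]), float(ds.SpacingBetweenSlices)]
    )
    iop = [float(v) for v in ds.ImageOrientationPatient]
    geometry = MrsGeometry(
        position=np.array([float(v) for v in ds.ImagePositionPatient]),
        row_cosines=np.array(iop[:3]),
        col_cosines=np.array(iop[3:]),
        spacing=spacing,
        shape=shape,
    )
    meta = SequenceMeta(
        transmitter_frequency=float(ds.ImagingFrequency),
        spectral_width=float(ds.SpectralWidth),
        echo_time=float(ds.EchoTime),
        reference_ppm=float(ds.ChemicalShiftReference),
        vendor=vendor,
    )

    block = ds.private_block(PRIVATE_GROUP, PRIVATE_CREATOR)
    payloads: dict[str, np.ndarray] = {}
    for elem, tag in ((_ELEM_SUPPRESSED, SUPPRESSED), (_ELEM_UNSUPPRESSED, UNSUPPRESSED)):
        try:
            blob = block[elem].value
        except KeyError:
            continue
        payloads[tag] = _decode_payload(bytes(blob), shape)
    if not payloads:
        raise ValueError(f"{path}: no MRS payload found in private block")
    return DicomMrsSeries(paths=paths, vendor=vendor, payloads=payloads,
                          geometry=geometry, meta=meta)


def _to_volume(series: DicomMrsSeries, tag: str) -> MRSVolume:
    return MRSVolume(
        data=series.payloads[tag],
        affine=build_affine(series.geometry),
        meta=series.meta,
        domain_tag=DOMAIN_TIME,
        suppression_tag=tag,
    )


def parse_philips(series: DicomMrsSeries) -> tuple[MRSVolume, MRSVolume]:
    """Split a Philips series into its (suppressed, unsuppressed) volumes.

    Both payloads are mandatory: handing back a lone spectrum would invite
    silently quantifying the wrong one, so a single-payload Philips series
    is an explicit error.
    """
    if series.vendor != "philips":
        raise ValueError(f"expected a philips series, got {series.vendor!r}")
    if UNSUPPRESSED not in series.payloads:
        raise ValueError(
            "missing unsuppressed data: Philips MRS series must carry both the "
            "water-suppressed and water-unsuppressed payloads"
        )
    if SUPPRESSED not in series.payloads:
        raise ValueError("missing suppressed data in Philips series")
    return _to_volume(series, SUPPRESSED), _to_volume(series, UNSUPPRESSED)


def parse_siemens(series: DicomMrsSeries) -> MRSVolume:
    """Extract the single water-suppressed volume of a Siemens series."""
    if series.vendor != "siemens":
        raise ValueError(f"expected a siemens series, got {series.vendor!r}")
    if SUPPRESSED not in series.payloads:
        raise ValueError("missing suppressed payload in Siemens series")
    return _to_volume(series, SUPPRESSED)


def write_fixture_dicom(
    path,
    vendor: str,
    geometry: MrsGeometry,
    meta: SequenceMeta,
    suppressed: np.ndarray,
    unsuppressed: np.ndarray | None = None,
    uid_seed: int = 0,
) -> Path:
    """Write one fixture-dialect DICOM file (see module docstring).

    ``uid_seed`` makes the instance UIDs — the only otherwise-random bytes —
    deterministic, so identical inputs produce byte-identical files.
    """
    if vendor not in ("philips", "siemens"):
        raise ValueError(f"vendor must be philips or siemens, got {vendor!r}")
    if vendor == "philips" and unsuppressed is None:
        raise ValueError("philips fixtures require an unsuppressed payload")

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = MRS_STORAGE_UID
    file_meta.MediaStorageSOPInstanceUID = f"{_UID_ROOT}.1.{uid_seed % 2**31}"
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    file_meta.ImplementationClassUID = f"{_UID_ROOT}.0.1"

    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = MRS_STORAGE_UID
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "MR"
    ds.Manufacturer = "Philips" if vendor == "philips" else "SIEMENS"
    ds.Columns = geometry.shape[0]
    ds.Rows = geometry.shape[1]
    ds.NumberOfFrames = geometry.shape[2]
    ds.ImagePositionPatient = [float(v) for v in geometry.position]
    ds.ImageOrientationPatient = [
        float(v) for v in np.concatenate([geometry.row_cosines, geometry.col_cosines])
    ]
    ds.PixelSpacing = [float(geometry.spacing[1]), float(geometry.spacing[0])]
    ds.SpacingBetweenSlices = float(geometry.spacing[2])
    ds.ImagingFrequency = float(meta.transmitter_frequency)
    ds.SpectralWidth = float(meta.spectral_width)
    ds.EchoTime = float(meta.echo_time)
    ds.ChemicalShiftReference = float(meta.reference_ppm)

    block = ds.private_block(PRIVATE_GROUP, PRIVATE_CREATOR, create=True)
    block.add_new(_ELEM_SUPPRESSED, "OB", _encode_payload(suppressed))
    if vendor == "philips":
        block.add_new(_ELEM_UNSUPPRESSED, "OB", _encode_payload(unsuppressed))

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)
    return path
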