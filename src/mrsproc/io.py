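"""NIFTI + JSON sidecar + ``.ppm`` readers and writers.

One MRS acquisition is stored as three files sharing a path stem:

``<stem>.nii``
    NIFTI-1 image holding the complex 4-D array (native complex128
    datatype, viewable in standard NIFTI tools that support it) with the
    volume's affine in the sform/qform.
``<stem>.json``
    Sidecar serialising the sequence parameters plus the domain and
    water-suppression tags.  Key names follow the NIFTI-MRS convention
    (SpectrometerFrequency, SpectralWidth, EchoTime ...).  Unknown keys
    are preserved on read and re-emitted on write.
``<stem>.ppm``
    Optional plain-text chemical-shift axis, one decimal ppm value per
    line, no header — the spectral analogue of dMRI ``.bval`` files.
    Present only for frequency-domain volumes.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .model import (
    DOMAIN_FREQUENCY,
    DOMAIN_TIME,
    SUPPRESSED,
    UNSUPPRESSED,
    InvariantViolation,
    MRSVolume,
    SequenceMeta,
    SpectralAxis,
    validate_volume,
)

__all__ = ["write_mrs_nifti", "read_mrs_nifti", "SIDECAR_KEYS"]

# Fixed sidecar schema; anything else round-trips through SequenceMeta.extra.
SIDECAR_KEYS = (
    "SpectrometerFrequency",  # MHz
    "SpectralWidth",          # Hz
    "EchoTime",               # ms
    "DwellTime",              # s
    "ResonantNucleus",
    "ReferencePpm",
    "Manufacturer",
    "Domain",
    "WaterSuppressed",
    "SpectralPoints",
)


def _stem(path_stem) -> Path:
    p = Path(path_stem)
    if p.suffix == ".nii":
        p = p.with_suffix("")
    return p


def write_mrs_nifti(vol: MRSVolume, axis: SpectralAxis | None, path_stem) -> list[Path]:
    """Write a volume (and optionally its ppm axis) under ``path_stem``.

    Returns the written paths.  A ppm axis may only accompany a
    frequency-domain volume and must match its spectral dimension.
    """
    violations = validate_volume(vol)
    if violations:
        raise InvariantViolation("; ".join(violations))
    if axis is not None:
        if vol.domain_tag != DOMAIN_FREQUENCY:
            raise InvariantViolation(
                "a ppm axis may only be written with a frequency-domain volume"
            )
        if axis.n != vol.n_points:
            raise InvariantViolation(
                f"axis length {axis.n} does not match spectral dimension {vol.n_points}"
            )
    stem = _stem(path_stem)
    stem.parent.mkdir(parents=True, exist_ok=True)

    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.complex128), vol.affine)
    img.header.set_data_dtype(np.complex128)
    img.header.set_xyzt_units(xyz="mm")
    nii_path = stem.with_suffix(".nii")
    nib.save(img, str(nii_path))

    sidecar = {
        "SpectrometerFrequency": vol.meta.transmitter_frequency,
        "SpectralWidth": vol.meta.spectral_width,
        "EchoTime": vol.meta.echo_time,
        "DwellTime": vol.meta.dwell_time,
        "ResonantNucleus": vol.meta.nucleus,
        "ReferencePpm": vol.meta.reference_ppm,
        "Manufacturer": vol.meta.vendor,
        "Domain": vol.domain_tag,
        "WaterSuppressed": vol.suppression_tag == SUPPRESSED,
        "SpectralPoints": int(vol.n_points),
    }
    for key, value in vol.meta.extra.items():
        sidecar.setdefault(key, value)
    json_path = stem.with_suffix(".json")
    json_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")

    paths = [nii_path, json_path]
    if axis is not None:
        ppm_path = stem.with_suffix(".ppm")
        ppm_path.write_text("".join(f"{v:.17g}\n" for v in axis.ppm))
        paths.append(ppm_path)
    return paths


def read_mrs_nifti(path_stem) -> tuple[MRSVolume, SpectralAxis | None]:
    """Inverse of :func:`write_mrs_nifti` up to storage precision.

    A missing ``.ppm`` file yields an absent axis; a missing sidecar is an
    error (the sidecar is the only carrier of the sequence parameters).
    """
    stem = _stem(path_stem)
    nii_path = stem.with_suffix(".nii")
    json_path = stem.with_suffix(".json")
    if not nii_path.exists():
        raise FileNotFoundError(f"missing NIFTI file: {nii_path}")
    if not json_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar: {json_path}")

    img = nib.load(str(nii_path))
    data = np.asanyarray(img.dataobj).astype(np.complex128)
    sidecar = json.loads(json_path.read_text())
    for key in ("SpectrometerFrequency", "SpectralWidth", "Domain", "WaterSuppressed"):
        if key not in sidecar:
            raise ValueError(f"sidecar {json_path} missing required key {key!r}")
    if data.ndim != 4:
        raise ValueError(f"{nii_path}: expected a 4-D array, got {data.ndim}-D")
    n_sidecar = sidecar.get("SpectralPoints")
    if n_sidecar is not None and int(n_sidecar) != data.shape[-1]:
        raise ValueError(
            f"sidecar SpectralPoints={n_sidecar} disagrees with array "
            f"spectral dimension {data.shape[-1]}"
        )

    extra = {k: v for k, v in sidecar.items() if k not in SIDECAR_KEYS}
    meta = SequenceMeta(
        transmitter_frequency=float(sidecar["SpectrometerFrequency"]),
        spectral_width=float(sidecar["SpectralWidth"]),
        echo_time=float(sidecar.get("EchoTime", 0.0)),
        dwell_time=float(sidecar["DwellTime"]) if sidecar.get("DwellTime") else None,
        nucleus=str(sidecar.get("ResonantNucleus", "1H")),
        reference_ppm=float(sidecar.get("ReferencePpm", 4.65)),
        vendor=str(sidecar.get("Manufacturer", "synthetic")),
        extra=extra,
    )
    vol = MRSVolume(
        data=data,
        affine=np.asarray(img.affine, dtype=np.float64),
        meta=meta,
        domain_tag=str(sidecar["Domain"]),
        suppression_tag=SUPPRESSED if sidecar["WaterSuppressed"] else UNSUPPRESSED,
    )

    ppm_path = stem.with_suffix(".ppm")
    axis: SpectralAxis | None = None
    if ppm_path.exists():
        ppm = np.loadtxt(str(ppm_path), dtype=np.float64, ndmin=1)
        if ppm.size != data.shape[-1]:
            raise ValueError(
                f"{ppm_path}: {ppm.size} values for spectral dimension {data.shape[-1]}"
            )
        axis = SpectralAxis(
            ppm=ppm,
            spectral_width=meta.spectral_width,
            transmitter_frequency=meta.transmitter_frequency,
            reference_ppm=meta.reference_ppm,
        )
    return vol, axis
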