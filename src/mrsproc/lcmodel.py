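"""LCModel interchange and a desk-scale peak-area integrator.

LCModel fits spectra as linear combinations of metabolite basis sets and
reports concentrations with Cramer-Rao lower-bound uncertainties (%SD).
This module only speaks LCModel's boundary formats — it writes the RAW
time-domain input and a minimal control (namelist) file, and parses an
output concentration table — plus a deliberately simple chord-baselined
trapezoidal peak integrator so the surrounding pipeline can be exercised
end to end without the external program.  The integrator is a test
surrogate: it shares none of LCModel's basis fitting, baseline splines or
uncertainty machinery and is never a substitute for them.

Output-table dialect: CSV with a header row and columns ``metabolite``,
``concentration``, ``percent_sd`` (any order); malformed rows are reported
with their line numbers and skipped, never silently dropped mid-value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import DOMAIN_TIME, MRSVolume, SequenceMeta, SpectralAxis

__all__ = [
    "MetaboliteEstimate",
    "PeakWindow",
    "DEFAULT_WINDOWS",
    "default_window",
    "write_lcmodel_raw",
    "read_lcmodel_raw",
    "write_lcmodel_control",
    "parse_lcmodel_table",
    "sd_filter",
    "peak_area",
    "metabolite_ratio",
]

logger = logging.getLogger(__name__)

SD_THRESHOLD = 20.0  # LCModel-recommended %SD cutoff
ANALYSIS_WINDOW = (0.2, 4.0)  # ppm range handed to LCModel


@dataclass(frozen=True)
class MetaboliteEstimate:
    """One metabolite quantity: LCModel concentration or integrator area."""

    name: str
    concentration: float
    percent_sd: float | None = None
    source: str = "lcmodel"  # "lcmodel" | "integrator"

    def __post_init__(self) -> None:
        if self.percent_sd is not None and self.percent_sd < 0:
            raise ValueError(f"{self.name}: percent_sd must be >= 0")
        if self.source == "integrator" and self.percent_sd is not None:
            raise ValueError("integrator estimates carry no Cramer-Rao %SD")


@dataclass(frozen=True)
class PeakWindow:
    """Closed ppm window used by the trapezoidal integrator."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"{self.name}: window requires lo < hi")


# Approximate singlet positions; adequate only for the integrator surrogate.
DEFAULT_WINDOWS = {
    "NAA": PeakWindow("NAA", 1.9, 2.1),
    "Cr": PeakWindow("Cr", 2.9, 3.1),
    "Lac": PeakWindow("Lac", 1.2, 1.4),
}


def default_window(name: str) -> PeakWindow:
    """Standard integrator window for a metabolite, if one is defensible.

    GSH deliberately has no window: its multiplets overlap Cr near 3.0 ppm
    and a naive area there would quantify the wrong molecule.  GSH is only
    meaningful from basis-set fitting, so asking for its window is an error
    directing the caller to LCModel output.
    """
    if name.upper() == "GSH":
        raise ValueError(
            "GSH overlaps the Cr resonance and cannot be integrated by a ppm "
            "window; use basis-set fitting (parse_lcmodel_table) instead"
        )
    try:
        return DEFAULT_WINDOWS[name]
    except KeyError:
        raise KeyError(
            f"no default integrator window for {name!r}; known: "
            f"{sorted(DEFAULT_WINDOWS)}"
        ) from None


def write_lcmodel_raw(vol: MRSVolume, path) -> Path:
    """Write a single-voxel time-domain FID as an LCModel RAW text file.

    The file is a ``$NMID`` namelist header followed by one
    ``real imaginary`` pair per line (8 significant digits) for all n
    points.  Multi-voxel input is rejected: average (e.g. via
    ``weighted_average_spectrum``) or iterate voxels first.
    """
    vol.require_domain(DOMAIN_TIME)
    if vol.grid_shape != (1, 1, 1):
        raise ValueError(
            f"LCModel RAW holds one voxel; got grid {vol.grid_shape}. "
            "Average the CSI grid (weighted_average_spectrum) or write one "
            "RAW file per voxel."
        )
    fid = vol.data[0, 0, 0]
    lines = [
        " $NMID",
        " ID='mrsproc'",
        " FMT='(2E16.8)'",
        f" HZPPPM={vol.meta.transmitter_frequency:.6f}",
        f" ECHOT={vol.meta.echo_time:.3f}",
        f" SW={vol.meta.spectral_width:.6f}",
        f" NPTS={fid.size}",
        " $END",
    ]
    lines += [f" {v.real:15.8E} {v.imag:15.8E}" for v in fid]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_lcmodel_raw(path) -> tuple[np.ndarray, dict]:
    """Parse a RAW file back to its complex FID and header fields."""
    path = Path(path)
    header: dict = {}
    data: list[complex] = []
    in_header = False
    for line in path.read_text().splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("$NMID"):
            in_header = True
            continue
        if stripped.startswith("$END"):
            in_header = False
            continue
        if in_header:
            if "=" in stripped:
                key, _, value = stripped.partition("=")
                header[key.strip()] = value.strip().strip("'")
            continue
        parts = stripped.split()
        if len(parts) != 2:
            raise ValueError(f"{path}: malformed data line {stripped!r}")
        data.append(complex(float(parts[0]), float(parts[1])))
    return np.asarray(data, dtype=np.complex128), header


def write_lcmodel_control(
    raw_path,
    out_path,
    meta: SequenceMeta,
    n_points: int,
    ppm_range: tuple[float, float] = ANALYSIS_WINDOW,
) -> Path:
    """Write a minimal LCModel control (namelist) file for one RAW input."""
    lo, hi = ppm_range
    lines = [
        " $LCMODL",
        f" FILRAW='{Path(raw_path)}'",
        f" HZPPPM={meta.transmitter_frequency:.6f}",
        f" ECHOT={meta.echo_time:.3f}",
        f" DELTAT={meta.dwell_time:.9e}",
        f" NUNFIL={n_points}",
        f" PPMST={hi:.3f}",
        f" PPMEND={lo:.3f}",
        " $END",
    ]
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text("\n".join(lines) + "\n")
    return out_path


def parse_lcmodel_table(path) -> list[MetaboliteEstimate]:
    """Parse an LCModel output table (documented CSV dialect).

    Every well-formed row yields one estimate with the metabolite name kept
    verbatim — including implausible %SD values like 999, whose filtering is
    a separate, explicit step.  Malformed rows are logged with their line
    number and skipped.
    """
    path = Path(path)
    estimates: list[MetaboliteEstimate] = []
    lines = path.read_text().splitlines()
    if not lines:
        return estimates
    header = [h.strip().lower() for h in lines[0].split(",")]
    required = {"metabolite", "concentration", "percent_sd"}
    if not required.issubset(header):
        raise ValueError(
            f"{path}: header {header} must contain columns {sorted(required)}"
        )
    cols = {name: header.index(name) for name in required}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split(",")]
        try:
            name = parts[cols["metabolite"]]
            conc = float(parts[cols["concentration"]])
            sd_text = parts[cols["percent_sd"]]
            sd = float(sd_text) if sd_text else None
            estimates.append(MetaboliteEstimate(name, conc, sd, source="lcmodel"))
        except (IndexError, ValueError) as exc:
            logger.warning("%s:%d: skipping malformed row (%s)", path, lineno, exc)
    return estimates


def sd_filter(
    estimates, threshold: float = SD_THRESHOLD
) -> list[MetaboliteEstimate]:
    """Drop estimates whose Cramer-Rao %SD is strictly above ``threshold``.

    A %SD exactly at the threshold survives ("above 20" excludes).  The
    filter is idempotent and order-preserving.  Integrator estimates carry
    no %SD and pass through with a warning — they have no uncertainty to
    judge them by.
    """
    kept: list[MetaboliteEstimate] = []
    estimates = list(estimates)
    for est in estimates:
        if est.percent_sd is None:
            warnings.warn(
                f"{est.name}: no %SD available ({est.source} estimate); "
                "passing through unfiltered",
                stacklevel=2,
            )
            kept.append(est)
        elif est.percent_sd <= threshold:
            kept.append(est)
    if estimates and not kept:
        logger.warning(
            "all %d estimates exceeded the %%SD threshold %.3g; nothing survives",
            len(estimates), threshold,
        )
    return kept


def peak_area(spectrum: np.ndarray, axis: SpectralAxis, window: PeakWindow) -> float:
    """Chord-baselined trapezoidal area of Re(s) over a closed ppm window.

    The straight line joining the window's endpoint values is subtracted as
    a local baseline before integration, so any constant or linear offset
    contributes zero area.  Units: a.u. * ppm.
    """
    spectrum = np.asarray(spectrum).reshape(-1)
    if spectrum.size != axis.n:
        raise ValueError(f"spectrum length {spectrum.size} != axis length {axis.n}")
    mask = axis.window_mask(window.lo, window.hi)
    if mask.sum() < 3:
        raise ValueError(
            f"{window.name}: window [{window.lo}, {window.hi}] ppm holds "
            f"{int(mask.sum())} bins; need >= 3"
        )
    x = axis.ppm[mask]
    y = spectrum.real[mask]
    order = np.argsort(x)
    x, y = x[order], y[order]
    chord = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    return float(np.trapezoid(y - chord, x))


def metabolite_ratio(numerator, denominator) -> float:
    """Ratio of two metabolite quantities (e.g. NAA/Cr, GSH/Cr).

    Accepts two :class:`MetaboliteEstimate` of the same source, or two
    plain areas.  Mixing an LCModel concentration with an integrator area
    would compare incommensurable scales and is rejected.
    """
    if isinstance(numerator, MetaboliteEstimate) != isinstance(denominator, MetaboliteEstimate):
        raise ValueError("numerator and denominator must both be estimates or both areas")
    if isinstance(numerator, MetaboliteEstimate):
        if numerator.source != denominator.source:
            raise ValueError(
                f"mixed sources: {numerator.source} vs {denominator.source}"
            )
        num, den = numerator.concentration, denominator.concentration
    else:
        num, den = float(numerator), float(denominator)
    if den <= 0:
        raise ValueError(f"denominator must be > 0, got {den}")
    return num / den
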