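"""Lipid-interference quality assurance for CSI spectra.

Dural lipids produce large spectral distortions below 2.0 ppm.  A clean
water-suppressed spectrum is close to flat over the 0.2–1.8 ppm region
(lactate excepted), so the residual of a per-voxel straight-line fit there
is a cheap artifact statistic: each spectrum's real part is fit with an
ordinary least-squares line against ppm over the window and summarised by
the root-mean-squared error (RMSE).  Voxels whose RMSE lies above the upper
Tukey fence ``Q3 + 1.5 * (Q3 - Q1)`` of the per-slab RMSE distribution are
flagged and excluded from further analysis.

Only the upper fence is applied: a suspiciously *smooth* spectrum is not an
artifact signature, and discarding low-RMSE voxels would throw away clean
data.  Quartiles use linear interpolation between order statistics (the
common "type 7" rule), stated here so independent recomputation matches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import DOMAIN_FREQUENCY, MRSVolume, SpectralAxis

__all__ = ["QAReport", "baseline_rmse", "iqr_outliers", "qa_exclude", "plot_qa"]

QA_WINDOW = (0.2, 1.8)  # ppm, closed at both ends
FENCE_FACTOR = 1.5


@dataclass
class QAReport:
    """Per-voxel baseline RMSE, interquartile fences and exclusion flags."""

    rmse: dict          # voxel index -> RMSE (a.u.)
    window: tuple[float, float]
    q1: float
    q3: float
    fence: float
    flags: dict         # voxel index -> "pass" | "outlier"

    @property
    def excluded(self) -> frozenset:
        return frozenset(v for v, f in self.flags.items() if f == "outlier")

    def to_json(self, path) -> Path:
        payload = {
            "window_ppm": list(self.window),
            "quantile_rule": "linear interpolation (type 7)",
            "q1": self.q1,
            "q3": self.q3,
            "upper_fence": self.fence,
            "voxels": [
                {
                    "index": list(v),
                    "rmse": self.rmse[v],
                    "flag": self.flags[v],
                }
                for v in sorted(self.rmse)
            ],
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"x": v[0], "y": v[1], "z": v[2], "rmse": self.rmse[v], "flag": self.flags[v]}
            for v in sorted(self.rmse)
        ]
        return pd.DataFrame(rows, columns=["x", "y", "z", "rmse", "flag"])


def baseline_rmse(
    spectrum: np.ndarray,
    axis: SpectralAxis,
    lo: float = QA_WINDOW[0],
    hi: float = QA_WINDOW[1],
) -> float:
    """RMSE of the least-squares line through Re(s) vs ppm over [lo, hi]."""
    spectrum = np.asarray(spectrum).reshape(-1)
    if spectrum.size != axis.n:
        raise ValueError(f"spectrum length {spectrum.size} != axis length {axis.n}")
    mask = axis.window_mask(lo, hi)
    if mask.sum() < 3:
        raise ValueError(
            f"baseline window [{lo}, {hi}] ppm holds {int(mask.sum())} bins; need >= 3"
        )
    x = axis.ppm[mask]
    y = spectrum.real[mask]
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(np.sqrt(np.mean(resid**2)))


def iqr_outliers(values: dict) -> tuple[float, float, float, frozenset]:
    """Upper-Tukey-fence outliers of a per-voxel statistic.

    Returns ``(Q1, Q3, fence, outlier set)`` with
    ``fence = Q3 + 1.5 * (Q3 - Q1)`` and outliers the keys whose value
    strictly exceeds the fence.  With a degenerate (zero) IQR the fence
    collapses to Q3, so any exceedance — however tiny — is flagged.
    """
    if len(values) < 4:
        raise ValueError(f"need >= 4 values for quartiles, got {len(values)}")
    arr = np.asarray(list(values.values()), dtype=float)
    q1, q3 = np.quantile(arr, [0.25, 0.75])  # linear interpolation, type 7
    fence = q3 + FENCE_FACTOR * (q3 - q1)
    outliers = frozenset(v for v, x in values.items() if x > fence)
    return float(q1), float(q3), float(fence), outliers


def qa_exclude(
    csi: MRSVolume,
    axis: SpectralAxis,
    included,
    lo: float = QA_WINDOW[0],
    hi: float = QA_WINDOW[1],
) -> tuple[QAReport, frozenset]:
    """Run the full QA chain on the included voxels.

    Computes the baseline RMSE per included voxel, flags upper-fence
    outliers, and returns the report together with the surviving set
    (included minus outliers).
    """
    csi.require_domain(DOMAIN_FREQUENCY)
    included = sorted(tuple(int(i) for i in v) for v in included)
    if not included:
        raise ValueError("included voxel set is empty")
    rmse = {v: baseline_rmse(csi.data[v], axis, lo, hi) for v in included}
    q1, q3, fence, outliers = iqr_outliers(rmse)
    flags = {v: ("outlier" if v in outliers else "pass") for v in included}
    report = QAReport(rmse=rmse, window=(lo, hi), q1=q1, q3=q3, fence=fence, flags=flags)
    return report, frozenset(included) - outliers


def plot_qa(csi: MRSVolume, axis: SpectralAxis, report: QAReport, path) -> Path:
    """Overlay plot: passing spectra in grey, flagged outliers in red."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for v, flag in report.flags.items():
        color, z, lw = ("0.6", 1, 0.7) if flag == "pass" else ("crimson", 2, 1.2)
        ax.plot(axis.ppm, csi.data[v].real, color=color, zorder=z, linewidth=lw)
    ax.set_xlim(axis.ppm.max(), axis.ppm.min())  # ppm decreases rightward
    ax.set_xlabel("chemical shift (ppm)")
    ax.set_ylabel("Re(s) (a.u.)")
    ax.set_title("baseline-RMSE QA: pass (grey) vs outlier (red)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
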