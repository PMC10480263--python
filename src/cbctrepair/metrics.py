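"""Image-quality evaluation: SSIM, MAE, difference maps and volume summaries.

SSIM uses the standard windowed formulation (11x11 Gaussian window,
sigma 1.5, K1=0.01, K2=0.03) with the data range fixed at the full HU span
(4095) so values are comparable across slices and volumes. MAE is reported
in HU. Volume reports carry per-slice values plus mean and sample standard
deviation, the shape in which patient-specific model performance is tabled
against the regular partial CBCT.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .phantom import CTVolume

HU_DATA_RANGE = 4095.0


def ssim_slice(
    a: np.ndarray,
    b: np.ndarray,
    data_range: float = HU_DATA_RANGE,
    sigma: float = 1.5,
    win_size: int = 11,
) -> float:
    """Structural similarity between two slices (symmetric in a, b)."""
    if a.shape != b.shape:
        raise ValueError("slice dimensions differ")
    return float(
        structural_similarity(
            a.astype(np.float64),
            b.astype(np.float64),
            data_range=data_range,
            gaussian_weights=True,
            sigma=sigma,
            win_size=win_size,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def mae_slice(a: np.ndarray, b: np.ndarray) -> float:
    """Mean absolute error over all pixels, in HU."""
    if a.shape != b.shape:
        raise ValueError("slice dimensions differ")
    return float(np.mean(np.abs(a.astype(np.float64) - b.astype(np.float64))))


def difference_map(output: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Signed HU difference, ground truth minus model output."""
    if output.shape != truth.shape:
        raise ValueError("slice dimensions differ")
    return truth.astype(np.float32) - output.astype(np.float32)


def save_difference_panel(diff: np.ndarray, path: str, vmax: float | None = None) -> None:
    """Render a difference map with a symmetric diverging scale about 0 HU."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = vmax or float(np.abs(diff).max() or 1.0)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(diff, cmap="seismic", vmin=-vmax, vmax=vmax)
    fig.colorbar(im, ax=ax, label="HU")
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


@dataclass
class MetricsReport:
    """Per-slice SSIM/MAE for one volume with mean and sample SD."""

    label: str
    per_slice: list[tuple[int, float, float]] = field(default_factory=list)

    @property
    def mean_ssim(self) -> float:
        return float(np.mean([s for _, s, _ in self.per_slice]))

    @property
    def sd_ssim(self) -> float:
        vals = [s for _, s, _ in self.per_slice]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    @property
    def mean_mae(self) -> float:
        return float(np.mean([m for _, _, m in self.per_slice]))

    @property
    def sd_mae(self) -> float:
        vals = [m for _, _, m in self.per_slice]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0


def evaluate_volume(
    pred: CTVolume | np.ndarray, truth: CTVolume | np.ndarray, label: str = ""
) -> MetricsReport:
    """Slice-wise SSIM/MAE of a predicted volume against ground truth."""
    p = pred.data if isinstance(pred, CTVolume) else np.asarray(pred)
    t = truth.data if isinstance(truth, CTVolume) else np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError("volumes must share slice count and dimensions")
    report = MetricsReport(label=label)
    for i in range(p.shape[0]):
        report.per_slice.append((i, ssim_slice(p[i], t[i]), mae_slice(p[i], t[i])))
    return report


COLUMNS = ["Image volume", "SSIM", "Standard deviation", "MAE", "Standard deviation "]


def compare_reports(reports: list[MetricsReport], csv_path: str | None = None) -> str:
    """Render volume summaries as a table, one row per report, and optionally
    write the same rows as CSV. Column order: label, SSIM, SD, MAE, SD."""
    rows = [
        [r.label, f"{r.mean_ssim:.6g}", f"{r.sd_ssim:.6g}", f"{r.mean_mae:.6g}", f"{r.sd_mae:.6g}"]
        for r in reports
    ]
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(COLUMNS)
    writer.writerows(rows)
    text = buf.getvalue()
    if csv_path:
        with open(csv_path, "w", newline="") as fh:
            fh.write(text)
    widths = [max(len(str(x)) for x in col) for col in zip(COLUMNS, *rows)]
    lines = ["  ".join(str(x).ljust(w) for x, w in zip(row, widths)) for row in [COLUMNS, *rows]]
    return "\n".join(lines)
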