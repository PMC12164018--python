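"""PSNR/SSIM metrics, intensity-profile extraction and report generation.

PSNR uses a fixed data range of 1.0 on normalized images so runs are
comparable; identical images are reported with a 999 dB sentinel to keep
CSV files numeric.  SSIM uses the standard windowed form with a 7x7 uniform
window and C1 = (0.01 * range)^2, C2 = (0.03 * range)^2 (a Gaussian window
is available behind a flag).  Both delegate to scikit-image.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.metrics import peak_signal_noise_ratio, structural_similarity

__all__ = [
    "PSNR_IDENTICAL_SENTINEL",
    "MetricsReport",
    "ProfileLine",
    "psnr",
    "ssim",
    "intensity_profile",
    "evaluate",
]

PSNR_IDENTICAL_SENTINEL = 999.0


def psnr(x: np.ndarray, y: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio, 10*log10(range^2 / MSE), in dB."""
    x, y = np.asarray(x, dtype=np.float64), np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    if np.array_equal(x, y):
        return PSNR_IDENTICAL_SENTINEL
    return float(peak_signal_noise_ratio(y, x, data_range=data_range))


def ssim(x: np.ndarray, y: np.ndarray, data_range: float = 1.0,
         gaussian_window: bool = False) -> float:
    """Mean structural similarity in [-1, 1]; symmetric in its arguments."""
    x, y = np.asarray(x, dtype=np.float64), np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if min(x.shape) < 7:
        raise ValueError("image smaller than the 7x7 SSIM window")
    return float(structural_similarity(
        x, y, data_range=data_range, gaussian_weights=gaussian_window,
        win_size=None if gaussian_window else 7,
    ))


@dataclass(frozen=True)
class ProfileLine:
    """A sampling segment between two (row, col) pixel coordinates."""

    start: tuple[float, float]
    end: tuple[float, float]
    n_samples: int = 100

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


def intensity_profile(img: np.ndarray, line: ProfileLine) -> np.ndarray:
    """Bilinear samples at n equally spaced points from start to end inclusive."""
    img = np.asarray(img, dtype=np.float64)
    for pt in (line.start, line.end):
        r, c = pt
        if not (0 <= r <= img.shape[0] - 1 and 0 <= c <= img.shape[1] - 1):
            raise ValueError(f"endpoint {pt} outside image bounds {img.shape}")
    t = np.linspace(0.0, 1.0, line.n_samples)
    rows = line.start[0] + t * (line.end[0] - line.start[0])
    cols = line.start[1] + t * (line.end[1] - line.start[1])
    return map_coordinates(img, np.stack([rows, cols]), order=1, mode="nearest")


@dataclass
class MetricsReport:
    """Per-image metric rows plus per-(rate, method) aggregates."""

    rows: list[dict]  # image_id, rate, method, psnr_db, ssim
    summary: dict  # {(rate, method): {psnr_mean, psnr_std, ssim_mean, ssim_std, n}}

    @staticmethod
    def from_rows(rows: list[dict]) -> "MetricsReport":
        summary: dict = {}
        keys = sorted({(r["rate"], r["method"]) for r in rows})
        for rate, method in keys:
            sel_p = [r["psnr_db"] for r in rows if r["rate"] == rate and r["method"] == method]
            sel_s = [r["ssim"] for r in rows if r["rate"] == rate and r["method"] == method]
            summary[f"{rate}/{method}"] = {
                "psnr_mean": float(np.mean(sel_p)), "psnr_std": float(np.std(sel_p)),
                "ssim_mean": float(np.mean(sel_s)), "ssim_std": float(np.std(sel_s)),
                "n": len(sel_p),
            }
        return MetricsReport(rows, summary)

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "metrics.csv", "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["image_id", "rate", "method", "psnr_db", "ssim"]
            )
            writer.writeheader()
            writer.writerows(self.rows)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2)


def evaluate(model, dataset, rates=None, out_dir=None,
             restore_fn=None) -> MetricsReport:
    """Metric grid over a test set: restored vs. raw-degraded baseline.

    ``model`` is an RCST instance or a checkpoint path; ``restore_fn``
    overrides it (e.g. identity for a no-op baseline).  Every test image is
    restored, both metrics are computed per rate for the restoration and
    for the degraded input itself, and CSV + JSON reports are written when
    ``out_dir`` is given.
    """
    if restore_fn is None:
        if isinstance(model, (str, Path)):
            from .network import load_checkpoint

            model, _ = load_checkpoint(model)
        restore_fn = model.restore
    rows = []
    for i, pair in enumerate(dataset):
        if rates is not None and pair.rate not in rates:
            continue
        y = pair.degraded.values
        x = pair.target
        restored = np.asarray(restore_fn(y), dtype=np.float64)
        for method, img in (("input", y), ("restored", restored)):
            rows.append({
                "image_id": i, "rate": pair.rate, "method": method,
                "psnr_db": psnr(img, x, data_range=1.0),
                "ssim": ssim(img, x, data_range=1.0),
            })
    report = MetricsReport.from_rows(rows)
    if out_dir is not None:
        report.write(out_dir)
    return report
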