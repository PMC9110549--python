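"""Full-reference (PSNR, SSIM) and no-reference (GCF, NIQE) image quality
metrics for evaluating B-scan enhancement.

PSNR and SSIM compare an image against a reference; GCF (global contrast
factor) and NIQE (natural image quality evaluator, see
:mod:`ioct_hrfuse.niqe`) score a single image.  Orientations: higher is
better for PSNR/SSIM/GCF, lower is better for NIQE.

Deep-feature metrics (perceptual loss, FID) need an externally trained
convolutional network and are not computed here; `MetricReport` accepts
externally computed per-image values for them so evaluation tables remain
complete.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .errors import InvalidInputError, ShapeMismatchError
from .niqe import NiqeModel, niqe_fit, niqe_score  # noqa: F401  (re-export)

__all__ = [
    "compute_psnr",
    "compute_ssim",
    "compute_gcf",
    "niqe_fit",
    "niqe_score",
    "NiqeModel",
    "MetricReport",
    "GCF_WEIGHT_COEFFS",
]


def compute_psnr(a: np.ndarray, b: np.ndarray, max_val: float = 255.0) -> float:
    """Peak signal-to-noise ratio ``10 log10(max_val^2 / MSE)`` in dB.

    Identical images have zero MSE and return ``math.inf``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"shape mismatch {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return math.inf
    return float(10.0 * math.log10(max_val**2 / mse))


def compute_ssim(a: np.ndarray, b: np.ndarray, data_range: float = 255.0) -> float:
    """Mean structural similarity with the standard reference settings:
    11x11 Gaussian window (sigma 1.5), K1=0.01, K2=0.03."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"shape mismatch {a.shape} vs {b.shape}")
    if min(a.shape) < 11:
        raise InvalidInputError("image smaller than the 11x11 SSIM window")
    return float(
        structural_similarity(
            a,
            b,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


# --------------------------------------------------------------------------
# global contrast factor

#: Resolution-weight polynomial w(f) = (a f + b) f + c with f = i / n_levels,
#: from the metric's original calibration against observer rankings.
GCF_WEIGHT_COEFFS = (-0.406385, 0.334573, 0.0877526)
GCF_N_LEVELS = 9
GCF_GAMMA = 2.2


def _local_contrast(lum: np.ndarray) -> float:
    """Mean over pixels of the mean absolute difference to the existing
    4-neighbours of the perceptual luminance image."""
    h, w = lum.shape
    if h * w <= 1:
        return 0.0
    diff = np.zeros_like(lum)
    count = np.zeros_like(lum)
    if w > 1:
        d = np.abs(lum[:, 1:] - lum[:, :-1])
        diff[:, :-1] += d
        diff[:, 1:] += d
        count[:, :-1] += 1
        count[:, 1:] += 1
    if h > 1:
        d = np.abs(lum[1:, :] - lum[:-1, :])
        diff[:-1, :] += d
        diff[1:, :] += d
        count[:-1, :] += 1
        count[1:, :] += 1
    return float(np.mean(diff / np.maximum(count, 1)))


def _superpixel_downsample(lin: np.ndarray) -> np.ndarray:
    """Halve resolution by 2x2 superpixel averaging on linear luminance.

    Odd trailing rows/columns are averaged into the last superpixel.
    """
    h, w = lin.shape
    nh, nw = max(1, h // 2), max(1, w // 2)
    row_edges = np.arange(0, 2 * nh, 2)
    col_edges = np.arange(0, 2 * nw, 2)
    sums = np.add.reduceat(np.add.reduceat(lin, row_edges, axis=0), col_edges, axis=1)
    rc = np.diff(np.append(row_edges, h))
    cc = np.diff(np.append(col_edges, w))
    return sums / np.outer(rc, cc)


def compute_gcf(image: np.ndarray, n_levels: int = GCF_N_LEVELS) -> float:
    """Global contrast factor: weighted sum of mean local contrasts over a
    pyramid of superpixel resolutions.

    Pixel values are gamma-linearized (``l = (k/255)^2.2``), converted to
    perceptual luminance ``L = 100 sqrt(l)``; each level's contrast is the
    mean absolute luminance difference to 4-neighbours, and levels are
    built by 2x superpixel averaging of the linear luminance.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise InvalidInputError("empty image")
    if img.ndim != 2:
        raise InvalidInputError("GCF expects a grayscale image")
    lin = (np.clip(img, 0, 255) / 255.0) ** GCF_GAMMA
    a, b, c = GCF_WEIGHT_COEFFS
    total = 0.0
    for i in range(1, n_levels + 1):
        f = i / n_levels
        w = (a * f + b) * f + c
        contrast = _local_contrast(100.0 * np.sqrt(lin))
        total += w * contrast
        lin = _superpixel_downsample(lin)
    return float(total)


# --------------------------------------------------------------------------
# report container


@dataclass
class MetricReport:
    """Per-image metric values for one image set, with aggregates.

    ``extra`` holds externally computed per-image metrics (e.g. perceptual
    distances from a pretrained network) keyed by metric name; missing
    metrics stay ``None`` rather than being dropped.
    """

    names: list[str]
    psnr: list[float | None] = field(default_factory=list)
    ssim: list[float | None] = field(default_factory=list)
    gcf: list[float | None] = field(default_factory=list)
    niqe: list[float | None] = field(default_factory=list)
    extra: dict[str, list[float | None]] = field(default_factory=dict)

    def aggregate(self) -> dict[str, tuple[float, float] | None]:
        """Mean and population SD per metric, ignoring missing entries."""
        out: dict[str, tuple[float, float] | None] = {}
        columns = {"psnr": self.psnr, "ssim": self.ssim, "gcf": self.gcf,
                   "niqe": self.niqe, **self.extra}
        for name, col in columns.items():
            vals = [v for v in col if v is not None and math.isfinite(v)]
            out[name] = (float(np.mean(vals)), float(np.std(vals))) if vals else None
        return out

    def to_rows(self) -> list[dict]:
        rows = []
        for i, name in enumerate(self.names):
            row = {"file": name}
            for metric, col in (
                ("psnr", self.psnr), ("ssim", self.ssim),
                ("gcf", self.gcf), ("niqe", self.niqe),
            ):
                row[metric] = col[i] if i < len(col) else None
            for metric, col in self.extra.items():
                row[metric] = col[i] if i < len(col) else None
            rows.append(row)
        return rows
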