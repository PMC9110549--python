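"""ROI-based speckle-statistics quality assessment of fused B-scans.

Image quality is scored on regions of interest anchored to retinal layers:

* ``SNR  = 10 log10( max(F^2) / sigma_b^2 )`` — peak squared intensity of
  the linear-magnitude image over the variance of a background noise ROI,
  in dB.
* ``ENL  = (1/H) sum_h mu_h^2 / sigma_h^2`` — equivalent number of looks,
  averaged over H homogeneous layer ROIs; for fully-developed speckle this
  estimates the number of averaged independent looks.
* ``CNR  = (1/R) sum_r (mu_r - mu_b) / sqrt(sigma_r^2 + sigma_b^2)`` —
  signed contrast of R layer ROIs against the background.

Five rectangles are placed per image (H=2, R=4): one background ROI, two
small homogeneous ROIs on the second and the last retinal layers, and two
large contrast ROIs on the first and the last layers; the contrast set for
CNR is the two large ROIs plus the two homogeneous ones.  ROI centres are
drawn uniformly at random among placements wholly inside their target
label.  An image is accepted when all three metrics meet their thresholds
(defaults 70.0 dB / 3.0 / 10.0 for SNR / CNR / ENL, inclusive).

All statistics use the population variance (divide by n) on the stored
0–255 intensity scale, which the thresholds assume; rescaling intensities
shifts SNR by a constant.  Intensities are treated as linear magnitude; an
``inverse_log`` option un-compresses log-display images first.

Layer masks normally come from an external semantic-segmentation model and
are read as integer-label images; :func:`segment_layers_heuristic` is a
simple intensity-profile fallback good enough to anchor ROIs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateBackgroundError,
    DegenerateRegionError,
    InvalidInputError,
    InvalidMetricError,
    PlacementFailedError,
    SegmentationFailedError,
)

__all__ = [
    "LayerMask",
    "Roi",
    "RoiSet",
    "QualityReport",
    "RoiSizes",
    "segment_layers_heuristic",
    "place_rois",
    "compute_snr",
    "compute_enl",
    "compute_cnr",
    "gate_quality",
    "assess_image",
    "DEFAULT_THRESHOLDS",
]

#: (snr_dB, cnr, enl) acceptance thresholds.
DEFAULT_THRESHOLDS = (70.0, 3.0, 10.0)


# --------------------------------------------------------------------------
# domain types


@dataclass
class LayerMask:
    """Integer label image: 0 background, 1..K layers ordered top-to-bottom."""

    labels: np.ndarray
    provenance: str = "external"  # "external" | "heuristic"

    @property
    def n_layers(self) -> int:
        return int(self.labels.max())

    def validate(self) -> None:
        present = np.unique(self.labels)
        if present.min() < 0:
            raise InvalidInputError("negative labels in mask")
        if self.n_layers < 2:
            raise InvalidInputError("mask needs at least 2 layer labels")


@dataclass
class Roi:
    """Axis-aligned rectangle tied to a mask label."""

    x: int
    y: int
    w: int
    h: int
    role: str           # "background" | "homogeneous" | "contrast"
    target_label: int

    def pixels(self, image: np.ndarray) -> np.ndarray:
        return np.asarray(image, dtype=float)[
            self.y : self.y + self.h, self.x : self.x + self.w
        ]

    def to_dict(self) -> dict:
        return {
            "x": int(self.x),
            "y": int(self.y),
            "w": int(self.w),
            "h": int(self.h),
            "role": self.role,
            "target_label": int(self.target_label),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Roi":
        return cls(**d)


@dataclass
class RoiSet:
    """The five placed rectangles: 1 background + 2 homogeneous (H=2) +
    2 large contrast; CNR's R=4 regions are contrast + homogeneous."""

    background: Roi
    homogeneous: list[Roi]
    contrast: list[Roi]
    rng_seed: int = 0

    @property
    def cnr_regions(self) -> list[Roi]:
        return list(self.contrast) + list(self.homogeneous)

    def all_rois(self) -> list[Roi]:
        return [self.background] + list(self.homogeneous) + list(self.contrast)

    def to_dict(self) -> dict:
        return {
            "background": self.background.to_dict(),
            "homogeneous": [r.to_dict() for r in self.homogeneous],
            "contrast": [r.to_dict() for r in self.contrast],
            "rng_seed": int(self.rng_seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RoiSet":
        return cls(
            background=Roi.from_dict(d["background"]),
            homogeneous=[Roi.from_dict(r) for r in d["homogeneous"]],
            contrast=[Roi.from_dict(r) for r in d["contrast"]],
            rng_seed=int(d["rng_seed"]),
        )


@dataclass
class RoiSizes:
    """(w, h) in px per ROI role; defaults sized for 440x300 B-scans."""

    background: tuple[int, int] = (32, 32)
    homogeneous: tuple[int, int] = (16, 8)
    contrast: tuple[int, int] = (96, 12)


@dataclass
class QualityReport:
    snr: float
    cnr: float
    enl: float
    roi_set: RoiSet | None
    accepted: bool
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS

    def to_dict(self) -> dict:
        return {
            "snr": float(self.snr),
            "cnr": float(self.cnr),
            "enl": float(self.enl),
            "accepted": bool(self.accepted),
            "thresholds": list(self.thresholds),
            "roi_set": None if self.roi_set is None else self.roi_set.to_dict(),
        }


# --------------------------------------------------------------------------
# heuristic layer segmentation (fallback plumbing, not a clinical model)


def segment_layers_heuristic(
    bscan: np.ndarray,
    n_layers: int = 5,
    smooth_sigma: tuple[float, float] = (1.0, 5.0),
    bg_quantile: float = 0.25,
    k_sigma: float = 4.0,
) -> LayerMask:
    """Simple intensity-profile retina segmentation.

    Per column of the smoothed image, the top surface is the first row
    whose intensity crosses an adaptive threshold (background level plus
    ``k_sigma`` background standard deviations) and the bottom surface is
    the last such row (the lower envelope of the bright band).  The
    interior is then split into ``n_layers`` bands at fixed fractional
    depths.  Columns without a crossing inherit their nearest valid
    neighbour.  Smoothing is anisotropic (``smooth_sigma`` = (axial,
    lateral)): heavy lateral averaging suppresses speckle while the light
    axial blur keeps surfaces in place.  This only aims at an acceptable
    approximation of the background and layer bands for ROI anchoring.
    """
    img = np.asarray(bscan, dtype=float)
    if img.ndim != 2:
        raise InvalidInputError("expected a grayscale B-scan")
    sm = ndimage.gaussian_filter(img, sigma=smooth_sigma, mode="nearest")
    h, w = img.shape
    # background statistics from the top band (vitreous above the retina)
    bg = sm[: max(3, int(bg_quantile * h) // 2)]
    thr = bg.mean() + k_sigma * bg.std() + 1e-6
    above = sm > thr
    has = above.any(axis=0)
    if not has.any():
        raise SegmentationFailedError("no column crosses the adaptive threshold")

    top = np.where(has, above.argmax(axis=0), np.nan).astype(float)
    bot = np.where(has, h - 1 - above[::-1, :].argmax(axis=0), np.nan).astype(float)
    # fill gaps from nearest valid columns; drop border columns where the
    # lateral smoothing is unreliable (flat-extended from the interior)
    cols = np.arange(w, dtype=float)
    valid = ~np.isnan(top)
    margin = min(6, w // 4)
    valid[:margin] = False
    valid[w - margin :] = False
    if not valid.any():
        valid = ~np.isnan(top)
    top = np.interp(cols, cols[valid], top[valid])
    bot = np.interp(cols, cols[valid], bot[valid])
    # single-column speckle outliers
    top = ndimage.median_filter(top, size=9, mode="nearest")
    bot = ndimage.median_filter(bot, size=9, mode="nearest")
    bot = np.maximum(bot, top + n_layers)  # guarantee a non-empty band

    fracs = np.linspace(0.0, 1.0, n_layers + 1)
    curves = top[None, :] + fracs[:, None] * (bot - top)[None, :]
    rows = np.arange(h, dtype=float)[:, None]
    labels = np.zeros((h, w), dtype=np.int32)
    for k in range(n_layers):
        labels += (rows >= curves[k][None, :]).astype(np.int32)
    labels[rows > curves[-1][None, :]] = 0
    labels[rows < curves[0][None, :]] = 0
    return LayerMask(labels=labels, provenance="heuristic")


# --------------------------------------------------------------------------
# ROI placement


def _valid_top_lefts(labels: np.ndarray, label: int, w: int, h: int) -> np.ndarray:
    """(n, 2) array of (x, y) top-left corners whose w x h rectangle lies
    wholly inside ``label``; uniform sampling over this set is uniform over
    valid centre placements."""
    inside = labels == label
    H, W = labels.shape
    if H < h or W < w:
        return np.empty((0, 2), dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(inside, (h, w))
    ok = windows.all(axis=(2, 3))
    ys, xs = np.nonzero(ok)
    return np.stack([xs, ys], axis=1)


def place_rois(
    mask: LayerMask,
    sizes: RoiSizes | None = None,
    rng_seed: int = 0,
) -> RoiSet:
    """Place the five prescribed ROIs at random valid positions.

    Background ROI inside label 0; the two homogeneous ROIs inside the
    second and the last layer labels; the two large contrast ROIs inside
    the first and the last layer labels.  Each centre is drawn uniformly
    from all fully contained placements.  Raises
    :class:`PlacementFailedError` naming the first impossible ROI.
    """
    mask.validate()
    sizes = sizes or RoiSizes()
    K = mask.n_layers
    rng = np.random.default_rng(rng_seed)
    plan = [
        ("background", sizes.background, 0, "background"),
        ("homogeneous_layer2", sizes.homogeneous, 2, "homogeneous"),
        (f"homogeneous_layer{K}", sizes.homogeneous, K, "homogeneous"),
        ("contrast_layer1", sizes.contrast, 1, "contrast"),
        (f"contrast_layer{K}", sizes.contrast, K, "contrast"),
    ]
    placed: dict[str, list[Roi]] = {"background": [], "homogeneous": [], "contrast": []}
    for name, (w, h), label, role in plan:
        cand = _valid_top_lefts(mask.labels, label, w, h)
        if len(cand) == 0:
            raise PlacementFailedError(name, f"label {label} admits no {w}x{h} ROI")
        x, y = cand[rng.integers(len(cand))]
        placed[role].append(Roi(int(x), int(y), w, h, role, label))
    return RoiSet(
        background=placed["background"][0],
        homogeneous=placed["homogeneous"],
        contrast=placed["contrast"],
        rng_seed=rng_seed,
    )


# --------------------------------------------------------------------------
# speckle-statistics metrics (population variance throughout)


def _stats(pix: np.ndarray) -> tuple[float, float]:
    pix = np.asarray(pix, dtype=float).ravel()
    return float(pix.mean()), float(pix.var())


def _linearize(image: np.ndarray, inverse_log: bool) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if inverse_log:
        # undo display log-compression: stored = 255 log(1+F)/log(256)
        img = np.expm1(img / 255.0 * np.log(256.0))
    return img


def compute_snr(
    image: np.ndarray, background_roi: Roi, inverse_log: bool = False
) -> float:
    """Peak-signal-to-background-noise ratio in dB:
    ``10 log10(max(F^2) / var(F_background))``."""
    f = _linearize(image, inverse_log)
    pix = background_roi.pixels(f)
    if pix.size < 2:
        raise InvalidInputError("background ROI needs at least 2 pixels")
    _, var = _stats(pix)
    if var == 0:
        raise DegenerateBackgroundError("constant background ROI")
    return float(10.0 * math.log10((f**2).max() / var))


def compute_enl(
    image: np.ndarray, homogeneous_rois: list[Roi], inverse_log: bool = False
) -> float:
    """Equivalent number of looks: mean over ROIs of ``mu^2 / sigma^2``."""
    f = _linearize(image, inverse_log)
    vals = []
    for roi in homogeneous_rois:
        pix = roi.pixels(f)
        if pix.size < 2:
            raise InvalidInputError("homogeneous ROI needs at least 2 pixels")
        mu, var = _stats(pix)
        if var == 0:
            raise DegenerateRegionError(f"constant ROI at ({roi.x}, {roi.y})")
        vals.append(mu**2 / var)
    return float(np.mean(vals))


def compute_cnr(
    image: np.ndarray,
    region_rois: list[Roi],
    background_roi: Roi,
    inverse_log: bool = False,
) -> float:
    """Contrast-to-noise ratio: mean over regions of the signed
    ``(mu_r - mu_b) / sqrt(sigma_r^2 + sigma_b^2)``."""
    f = _linearize(image, inverse_log)
    mu_b, var_b = _stats(background_roi.pixels(f))
    vals = []
    for roi in region_rois:
        mu_r, var_r = _stats(roi.pixels(f))
        denom = var_r + var_b
        if denom == 0:
            raise DegenerateRegionError(f"zero pooled variance at ({roi.x}, {roi.y})")
        vals.append((mu_r - mu_b) / math.sqrt(denom))
    return float(np.mean(vals))


def gate_quality(
    snr: float,
    cnr: float,
    enl: float,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
    roi_set: RoiSet | None = None,
) -> QualityReport:
    """Accept an image iff all three metrics meet their thresholds
    (inclusive): ``snr >= t_snr and cnr >= t_cnr and enl >= t_enl``."""
    for name, v in (("snr", snr), ("cnr", cnr), ("enl", enl)):
        if not math.isfinite(v):
            raise InvalidMetricError(f"{name} is not finite: {v}")
    t_snr, t_cnr, t_enl = thresholds
    accepted = (snr >= t_snr) and (cnr >= t_cnr) and (enl >= t_enl)
    return QualityReport(
        snr=snr, cnr=cnr, enl=enl, roi_set=roi_set,
        accepted=accepted, thresholds=tuple(thresholds),
    )


def assess_image(
    image: np.ndarray,
    mask: LayerMask,
    sizes: RoiSizes | None = None,
    rng_seed: int = 0,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
    inverse_log: bool = False,
) -> QualityReport:
    """Place ROIs from the mask, compute SNR/ENL/CNR and gate the image."""
    rois = place_rois(mask, sizes=sizes, rng_seed=rng_seed)
    snr = compute_snr(image, rois.background, inverse_log)
    enl = compute_enl(image, rois.homogeneous, inverse_log)
    cnr = compute_cnr(image, rois.cnr_regions, rois.background, inverse_log)
    return gate_quality(snr, cnr, enl, thresholds=thresholds, roi_set=rois)
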