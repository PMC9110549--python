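"""Scan-marker detection, retinal-feature tracking and stationarity analysis.

The iOCT scanning region appears in the microscope view as a bright white
rectangular outline containing cyan and magenta arrow glyphs.  Its position
is found by binary thresholding, Canny edge detection and a probabilistic
Hough line transform, grouping the detected segments into an axis-aligned
quadrilateral scored by perimeter brightness.  The two arrow glyphs give
sub-pixel scan-position anchors.  Retinal motion is monitored by tracking a
single manually seeded feature point (e.g. a vessel bifurcation) with a
pyramidal Lucas–Kanade sparse optical-flow tracker.  Frames during which
both the scan position and the retinal point stay constant (up to small
tolerances) form stability intervals whose B-scans are eligible for fusion.
"""
from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray, rgb2hsv
from skimage.draw import polygon2mask
from skimage.feature import canny
from skimage.transform import probabilistic_hough_line

from .errors import (
    ArrowNotFoundError,
    InvalidInputError,
    NoScanRegionError,
)

__all__ = [
    "ScanPosition",
    "ScanTrack",
    "StabilityInterval",
    "detect_scan_rectangle",
    "detect_arrow_points",
    "track_feature",
    "find_stable_intervals",
    "track_video",
]


# --------------------------------------------------------------------------
# domain types


@dataclass
class ScanPosition:
    """Scan-marker geometry in one frame: rectangle corners ordered
    clockwise from top-left, plus the two arrow anchor points."""

    rect_corners: np.ndarray | None  # (4, 2)
    cyan_point: np.ndarray | None
    magenta_point: np.ndarray | None
    valid: bool = True

    def to_dict(self) -> dict:
        return {
            "rect_corners": None
            if self.rect_corners is None
            else np.asarray(self.rect_corners).tolist(),
            "cyan_point": None
            if self.cyan_point is None
            else list(map(float, self.cyan_point)),
            "magenta_point": None
            if self.magenta_point is None
            else list(map(float, self.magenta_point)),
            "valid": bool(self.valid),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanPosition":
        def arr(v):
            return None if v is None else np.asarray(v, dtype=float)

        return cls(
            rect_corners=arr(d["rect_corners"]),
            cyan_point=arr(d["cyan_point"]),
            magenta_point=arr(d["magenta_point"]),
            valid=bool(d["valid"]),
        )

    @classmethod
    def invalid(cls) -> "ScanPosition":
        return cls(None, None, None, valid=False)


@dataclass
class ScanTrack:
    """Per-frame scan positions and the tracked retinal feature point."""

    positions: list[ScanPosition]
    feature_points: np.ndarray      # (n, 2); NaN where lost
    feature_status: np.ndarray      # (n,) bool

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    def frame_ok(self, i: int) -> bool:
        return bool(self.positions[i].valid and self.feature_status[i])

    def state(self, i: int) -> np.ndarray:
        """Stacked (cyan, magenta, feature) coordinates for frame ``i``."""
        p = self.positions[i]
        return np.concatenate(
            [p.cyan_point, p.magenta_point, self.feature_points[i]]
        )

    def to_dict(self) -> dict:
        return {
            "positions": [p.to_dict() for p in self.positions],
            "feature_points": self.feature_points.tolist(),
            "feature_status": self.feature_status.astype(bool).tolist(),
        }

    def save(self, path: str | os.PathLike) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "ScanTrack":
        return cls(
            positions=[ScanPosition.from_dict(p) for p in d["positions"]],
            feature_points=np.asarray(d["feature_points"], dtype=float),
            feature_status=np.asarray(d["feature_status"], dtype=bool),
        )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "ScanTrack":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class StabilityInterval:
    """Inclusive run of frames judged stationary, eligible for fusion."""

    start_frame: int
    end_frame: int
    max_scan_deviation: float = 0.0
    max_feature_deviation: float = 0.0

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def to_dict(self) -> dict:
        return {
            "start_frame": int(self.start_frame),
            "end_frame": int(self.end_frame),
            "n_frames": int(self.n_frames),
            "max_scan_deviation": float(self.max_scan_deviation),
            "max_feature_deviation": float(self.max_feature_deviation),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StabilityInterval":
        return cls(
            start_frame=int(d["start_frame"]),
            end_frame=int(d["end_frame"]),
            max_scan_deviation=float(d["max_scan_deviation"]),
            max_feature_deviation=float(d["max_feature_deviation"]),
        )


# --------------------------------------------------------------------------
# scan-rectangle detection


def _to_gray255(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 3:
        g = rgb2gray(frame[..., :3].astype(float) / 255.0) * 255.0
    else:
        g = frame.astype(float)
    return g


def _cluster_1d(values: np.ndarray, tol: float) -> list[float]:
    """Group sorted scalar coordinates into clusters within ``tol``."""
    out: list[float] = []
    cur: list[float] = []
    for v in np.sort(values):
        if cur and v - cur[-1] > tol:
            out.append(float(np.mean(cur)))
            cur = []
        cur.append(float(v))
    if cur:
        out.append(float(np.mean(cur)))
    return out


def _refine_side(
    gray: np.ndarray,
    binary: np.ndarray,
    coord: float,
    lo: float,
    hi: float,
    axis: str,
    halfband: int = 3,
) -> float:
    """Sub-pixel side position: brightness-weighted centroid of the bright
    mask in a thin band around a coarse Hough line, restricted to the side's
    extent along the rectangle."""
    h, w = gray.shape
    c = int(round(coord))
    lo_i, hi_i = int(math.floor(lo)), int(math.ceil(hi))
    if axis == "y":
        rows = slice(max(0, c - halfband), min(h, c + halfband + 1))
        sub = gray[rows, max(0, lo_i) : min(w, hi_i + 1)]
        msk = binary[rows, max(0, lo_i) : min(w, hi_i + 1)]
        idx = np.arange(max(0, c - halfband), min(h, c + halfband + 1), dtype=float)
        weights = (sub * msk).sum(axis=1)
    else:
        cols = slice(max(0, c - halfband), min(w, c + halfband + 1))
        sub = gray[max(0, lo_i) : min(h, hi_i + 1), cols]
        msk = binary[max(0, lo_i) : min(h, hi_i + 1), cols]
        idx = np.arange(max(0, c - halfband), min(w, c + halfband + 1), dtype=float)
        weights = (sub * msk).sum(axis=0)
    tot = weights.sum()
    if tot <= 0:
        return coord
    return float((idx * weights).sum() / tot)


def _perimeter_brightness(
    binary: np.ndarray, x0: float, x1: float, y0: float, y1: float
) -> float:
    """Fraction of sampled perimeter points lying on the bright mask."""
    n = 40
    xs = np.linspace(x0, x1, n)
    ys = np.linspace(y0, y1, n)
    pts = np.concatenate(
        [
            np.stack([xs, np.full(n, y0)], axis=1),
            np.stack([xs, np.full(n, y1)], axis=1),
            np.stack([np.full(n, x0), ys], axis=1),
            np.stack([np.full(n, x1), ys], axis=1),
        ]
    )
    h, w = binary.shape
    r = np.clip(np.round(pts[:, 1]).astype(int), 0, h - 1)
    c = np.clip(np.round(pts[:, 0]).astype(int), 0, w - 1)
    # tolerate 1 px rasterization offset
    hits = np.zeros(len(pts), dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            hits |= binary[np.clip(r + dr, 0, h - 1), np.clip(c + dc, 0, w - 1)]
    return float(hits.mean())


def detect_scan_rectangle(
    scene_frame: np.ndarray,
    threshold_frac: float = 0.9,
    min_side: int = 20,
    hough_threshold: int = 10,
    line_length: int = 15,
    line_gap: int = 3,
    min_perimeter_frac: float = 0.9,
) -> np.ndarray:
    """Locate the white scan-marker rectangle in a microscope-view frame.

    Pipeline: grayscale -> binary threshold at ``threshold_frac * max`` ->
    Canny edges -> probabilistic Hough segments -> cluster near-horizontal /
    near-vertical segment positions -> enumerate candidate axis-aligned
    quadrilaterals -> keep the one whose perimeter is most completely bright
    (ties broken by area) -> refine each side to sub-pixel by a
    brightness-weighted centroid.

    Returns corners ordered clockwise from top-left, shape (4, 2), in
    0-based (x, y) pixel coordinates.  Raises :class:`NoScanRegionError`
    when no sufficiently bright quadrilateral exists.
    """
    gray = _to_gray255(scene_frame)
    mx = gray.max()
    if mx <= 0:
        raise NoScanRegionError("frame is black")
    binary = gray >= threshold_frac * mx
    if binary.sum() < 4 * min_side:
        raise NoScanRegionError("too few bright pixels for a scan marker")

    edges = canny(binary.astype(float), sigma=1.0)
    # seeded: the probabilistic Hough transform samples edge points randomly
    segments = probabilistic_hough_line(
        edges,
        threshold=hough_threshold,
        line_length=line_length,
        line_gap=line_gap,
        rng=12345,
    )
    if not segments:
        raise NoScanRegionError("no line segments detected")

    horiz_y, vert_x = [], []
    for (x0, y0), (x1, y1) in segments:
        dx, dy = abs(x1 - x0), abs(y1 - y0)
        if dx >= dy * 3:
            horiz_y.append((y0 + y1) / 2.0)
        elif dy >= dx * 3:
            vert_x.append((x0 + x1) / 2.0)
    ys = _cluster_1d(np.asarray(horiz_y), tol=4.0)
    xs = _cluster_1d(np.asarray(vert_x), tol=4.0)
    if len(ys) < 2 or len(xs) < 2:
        raise NoScanRegionError("not enough axis-aligned segments")

    best = None
    for i, y0 in enumerate(ys):
        for y1 in ys[i + 1 :]:
            if y1 - y0 < min_side:
                continue
            for j, x0 in enumerate(xs):
                for x1 in xs[j + 1 :]:
                    if x1 - x0 < min_side:
                        continue
                    score = _perimeter_brightness(binary, x0, x1, y0, y1)
                    area = (x1 - x0) * (y1 - y0)
                    key = (score, area)
                    if score >= min_perimeter_frac and (
                        best is None or key > best[0]
                    ):
                        best = (key, (x0, x1, y0, y1))
    if best is None:
        raise NoScanRegionError("no bright quadrilateral candidate")

    x0, x1, y0, y1 = best[1]
    y0r = _refine_side(gray, binary, y0, x0, x1, "y")
    y1r = _refine_side(gray, binary, y1, x0, x1, "y")
    x0r = _refine_side(gray, binary, x0, y0, y1, "x")
    x1r = _refine_side(gray, binary, x1, y0, y1, "x")
    return np.array(
        [[x0r, y0r], [x1r, y0r], [x1r, y1r], [x0r, y1r]], dtype=float
    )


# --------------------------------------------------------------------------
# arrow detection


#: HSV gates for the glyph colours.  Hue in degrees on the 0-360 circle
#: (cyan is centred at 180, magenta at 300); saturation/value in [0, 1].
ARROW_HUE_RANGES = {"cyan": (170.0, 210.0), "magenta": (280.0, 340.0)}
ARROW_MIN_SAT = 0.4
ARROW_MIN_VAL = 0.4


def detect_arrow_points(
    scene_frame: np.ndarray,
    rect_corners: np.ndarray,
    margin: int = 2,
    hue_ranges: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sub-pixel cyan and magenta arrow anchors inside the scan rectangle.

    Each anchor is the value-weighted centroid of the corresponding colour
    blob, restricted to the rectangle's interior dilated by ``margin`` px.
    Raises :class:`ArrowNotFoundError` naming the missing colour.
    """
    frame = np.asarray(scene_frame)
    if frame.ndim != 3 or frame.shape[2] < 3:
        raise InvalidInputError("arrow detection needs an RGB frame")
    hsv = rgb2hsv(frame[..., :3].astype(float) / 255.0)
    hue = hsv[..., 0] * 360.0
    sat, val = hsv[..., 1], hsv[..., 2]

    corners = np.asarray(rect_corners, dtype=float)
    region = polygon2mask(frame.shape[:2], corners[:, ::-1])
    if margin > 0:
        region = ndimage.binary_dilation(region, iterations=margin)

    hue_ranges = hue_ranges or ARROW_HUE_RANGES
    points = {}
    for colour, (h0, h1) in hue_ranges.items():
        blob = (
            region
            & (hue >= h0)
            & (hue <= h1)
            & (sat >= ARROW_MIN_SAT)
            & (val >= ARROW_MIN_VAL)
        )
        if not blob.any():
            raise ArrowNotFoundError(colour)
        w = val * blob
        tot = w.sum()
        ys, xs = np.nonzero(blob)
        points[colour] = np.array(
            [
                float((xs * w[ys, xs]).sum() / tot),
                float((ys * w[ys, xs]).sum() / tot),
            ]
        )
    return points["cyan"], points["magenta"]


# --------------------------------------------------------------------------
# pyramidal Lucas-Kanade point tracking


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [img.astype(float)]
    for _ in range(levels - 1):
        sm = ndimage.gaussian_filter(pyr[-1], sigma=1.0, mode="nearest")
        pyr.append(sm[::2, ::2])
    return pyr


def _sample(img: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(img, [ys, xs], order=1, mode="nearest")


def _lk_point(
    prev_pyr: list[np.ndarray],
    next_pyr: list[np.ndarray],
    grad_pyr: list[tuple[np.ndarray, np.ndarray]],
    point: np.ndarray,
    window: int,
    max_iter: int,
    eps: float,
) -> tuple[np.ndarray, float]:
    """Track one point between two pyramids; returns (new point, residual).

    Classic coarse-to-fine Lucas-Kanade: at each level the flow estimate
    from the coarser level is doubled and refined by Gauss-Newton steps on
    the local window until the update falls below ``eps``.
    """
    half = window // 2
    offs = np.arange(-half, half + 1, dtype=float)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    oy, ox = oy.ravel(), ox.ravel()
    levels = len(prev_pyr)
    flow = np.zeros(2)
    for lev in range(levels - 1, -1, -1):
        p_lev = point / (2**lev)
        flow = flow * 2.0
        prev = prev_pyr[lev]
        nxt = next_pyr[lev]
        gy, gx = grad_pyr[lev]
        ys, xs = p_lev[1] + oy, p_lev[0] + ox
        tmpl = _sample(prev, ys, xs)
        ix = _sample(gx, ys, xs)
        iy = _sample(gy, ys, xs)
        g = np.array([[np.dot(ix, ix), np.dot(ix, iy)], [np.dot(ix, iy), np.dot(iy, iy)]])
        det = np.linalg.det(g)
        if det < 1e-6:
            break
        g_inv = np.linalg.inv(g)
        for _ in range(max_iter):
            cur = _sample(nxt, ys + flow[1], xs + flow[0])
            di = tmpl - cur
            b = np.array([np.dot(di, ix), np.dot(di, iy)])
            step = g_inv @ b
            flow += step
            if np.hypot(*step) < eps:
                break
    new_point = point + flow
    final = _sample(
        next_pyr[0], new_point[1] + oy, new_point[0] + ox
    )
    tmpl0 = _sample(prev_pyr[0], point[1] + oy, point[0] + ox)
    residual = float(np.mean(np.abs(final - tmpl0)))
    return new_point, residual


def track_feature(
    frames: list[np.ndarray],
    seed_point: tuple[float, float],
    levels: int = 3,
    window: int = 21,
    max_iter: int = 30,
    eps: float = 0.01,
    max_residual: float = 12.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Track a single seeded point through grayscale frames with pyramidal
    Lucas–Kanade sparse optical flow.

    Returns ``(points, status)``: an (n, 2) array of (x, y) positions and a
    boolean array that turns (and stays) False once the mean absolute
    window residual exceeds ``max_residual`` intensity levels or the point
    leaves the frame.
    """
    if len(frames) == 0:
        raise InvalidInputError("empty frame sequence")
    first = _to_gray255(frames[0])
    h, w = first.shape
    p = np.asarray(seed_point, dtype=float)
    if not (0 <= p[0] < w and 0 <= p[1] < h):
        raise InvalidInputError("seed point outside the first frame")

    n = len(frames)
    points = np.full((n, 2), np.nan)
    status = np.zeros(n, dtype=bool)
    points[0] = p
    status[0] = True

    prev_pyr = _pyramid(first, levels)
    lost = False
    for t in range(1, n):
        nxt_gray = _to_gray255(frames[t])
        nxt_pyr = _pyramid(nxt_gray, levels)
        if not lost:
            grad_pyr = [np.gradient(lvl) for lvl in prev_pyr]
            p_new, residual = _lk_point(
                prev_pyr, nxt_pyr, grad_pyr, p, window, max_iter, eps
            )
            inside = 0 <= p_new[0] < w and 0 <= p_new[1] < h
            if residual > max_residual or not inside:
                lost = True
            else:
                p = p_new
                points[t] = p
                status[t] = True
        prev_pyr = nxt_pyr
    return points, status


# --------------------------------------------------------------------------
# stability intervals


def find_stable_intervals(
    track: ScanTrack,
    min_len: int = 8,
    tol_step: float = 1.5,
    tol_total: float = 3.0,
) -> list[StabilityInterval]:
    """Extract maximal disjoint stationary intervals from a track.

    A frame extends the current interval when every tracked point (both
    arrow anchors and the retinal feature) moves at most ``tol_step`` px
    from the previous frame and at most ``tol_total`` px from the
    interval's first frame.  Frames with invalid detections break
    intervals.  Only intervals of at least ``min_len`` frames are kept.
    """
    if min_len < 2:
        raise InvalidInputError("min_len must be at least 2")
    n = track.n_frames
    out: list[StabilityInterval] = []
    i = 0
    while i < n:
        if not track.frame_ok(i):
            i += 1
            continue
        ref = track.state(i)
        prev = ref
        j = i
        max_scan = 0.0
        max_feat = 0.0
        while j + 1 < n and track.frame_ok(j + 1):
            cur = track.state(j + 1)
            step = _point_devs(cur, prev)
            total = _point_devs(cur, ref)
            if step.max() > tol_step or total.max() > tol_total:
                break
            max_scan = max(max_scan, float(total[:2].max()))
            max_feat = max(max_feat, float(total[2]))
            prev = cur
            j += 1
        if j - i + 1 >= min_len:
            out.append(
                StabilityInterval(
                    start_frame=i,
                    end_frame=j,
                    max_scan_deviation=max_scan,
                    max_feature_deviation=max_feat,
                )
            )
        i = j + 1
    return out


def _point_devs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean deviation per tracked point (cyan, magenta, feature)."""
    d = (a - b).reshape(3, 2)
    return np.hypot(d[:, 0], d[:, 1])


# --------------------------------------------------------------------------
# convenience driver


def track_video(
    scene_frames: list[np.ndarray],
    seed_point: tuple[float, float],
    **lk_kwargs,
) -> ScanTrack:
    """Detect the scan marker in every frame and track the seeded feature."""
    if len(scene_frames) == 0:
        raise InvalidInputError("empty frame sequence")
    positions = []
    for frame in scene_frames:
        try:
            corners = detect_scan_rectangle(frame)
            cyan, magenta = detect_arrow_points(frame, corners)
            positions.append(ScanPosition(corners, cyan, magenta, valid=True))
        except (NoScanRegionError, ArrowNotFoundError):
            positions.append(ScanPosition.invalid())
    pts, status = track_feature(scene_frames, seed_point, **lk_kwargs)
    return ScanTrack(positions=positions, feature_points=pts, feature_status=status)
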