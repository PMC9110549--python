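"""Synthetic iOCT surgery scenes: layered B-scan phantoms with speckle,
microscope-view frames with a scan marker, and a ground-truth manifest.

The generator stands in for surgical video so every downstream stage
(marker detection, point tracking, stationarity extraction, rigid fusion,
quality gating) can be exercised and verified against known ground truth.

What it emulates
----------------
* B-scans: a piecewise-constant reflectivity map of ``n_layers`` retinal
  layers bounded by smooth sinusoidal surfaces, degraded by fully-developed
  multiplicative speckle — i.i.d. gamma noise with shape ``L`` (the number
  of looks) and unit mean, so a homogeneous region has ENL ``mu^2/sigma^2
  ~= L``.  ``L = inf`` yields the noise-free map.
* Microscope view: a textured fundus that moves rigidly with the retina, a
  white rectangular outline marking the iOCT scanning region, filled cyan
  and magenta arrow glyphs inside it, and a high-contrast trackable feature
  (a bright blob, standing in for a vessel bifurcation).
* Motion: a scripted trajectory containing stationary segments, during
  which all positions are constant up to an optional sub-pixel jitter.

All geometry is recorded in a JSON manifest so tests can compare detector
and tracker output against ground truth.
"""
from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.draw import disk, polygon

from .errors import InvalidScriptError, InvalidSpecError
from .rigid import RigidTransform

__all__ = [
    "PhantomSpec",
    "Phantom",
    "SceneScript",
    "SynthManifest",
    "make_bscan_phantom",
    "make_scene_script",
    "make_surgery_video",
    "recompute_stationary_segments",
]


# --------------------------------------------------------------------------
# phantom


@dataclass
class PhantomSpec:
    """Geometry, reflectivity and noise model of a layered B-scan phantom.

    ``layer_reflectivities`` are mean intensities on the stored 0–255 scale,
    top layer first.  ``speckle_looks`` is the gamma shape parameter L of
    the multiplicative noise (``math.inf`` disables noise).  Surface shape
    is a sum of low-order sinusoids shared by all boundaries (parallel
    layers), parameterised by ``surface_amplitudes`` / ``surface_frequencies``
    (cycles across the image width) / ``surface_phases``.
    """

    width: int = 440
    height: int = 300
    n_layers: int = 5
    layer_reflectivities: tuple[float, ...] = (40.0, 170.0, 90.0, 120.0, 200.0)
    layer_fractions: tuple[float, ...] | None = None
    surface_amplitudes: tuple[float, ...] = (10.0, 4.0)
    surface_frequencies: tuple[float, ...] = (0.9, 2.3)
    surface_phases: tuple[float, ...] = (0.4, 1.7)
    top_frac: float = 0.22
    bottom_frac: float = 0.80
    lateral_modulation: float = 0.12
    speckle_looks: float = math.inf
    background_level: float = 8.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise InvalidSpecError("phantom dimensions must be positive")
        if self.n_layers < 2:
            raise InvalidSpecError("need at least 2 layers")
        if len(self.layer_reflectivities) != self.n_layers:
            raise InvalidSpecError("one reflectivity per layer required")
        if any(not (0.0 <= r <= 255.0) for r in self.layer_reflectivities):
            raise InvalidSpecError("reflectivities must lie in [0, 255]")
        if not (self.speckle_looks > 0):
            raise InvalidSpecError("speckle_looks must be positive")
        if self.layer_fractions is not None:
            if len(self.layer_fractions) != self.n_layers:
                raise InvalidSpecError("one thickness fraction per layer")
            if abs(sum(self.layer_fractions) - 1.0) > 1e-9:
                raise InvalidSpecError("layer fractions must sum to 1")
        if not (0.0 < self.top_frac < self.bottom_frac < 1.0):
            raise InvalidSpecError("require 0 < top_frac < bottom_frac < 1")

    def fractions(self) -> np.ndarray:
        if self.layer_fractions is None:
            return np.full(self.n_layers, 1.0 / self.n_layers)
        return np.asarray(self.layer_fractions, dtype=float)


@dataclass
class Phantom:
    """One rendered phantom: speckled image, noise-free map, labels, curves."""

    image: np.ndarray          # float64, [0, 255], speckled
    reflectivity: np.ndarray   # float64 noise-free reflectivity map
    mask: np.ndarray           # int labels: 0 background, 1..n_layers
    boundaries: np.ndarray     # (n_layers + 1, width) y(x) curves, top first

    def manifest_entry(self) -> dict:
        return {"boundaries": self.boundaries.tolist()}


def boundary_curves(spec: PhantomSpec) -> np.ndarray:
    """Layer boundary curves ``y_k(x)``, k = 0 (top surface) .. n_layers."""
    x = np.arange(spec.width, dtype=float)
    wave = np.zeros_like(x)
    for a, f, p in zip(
        spec.surface_amplitudes, spec.surface_frequencies, spec.surface_phases
    ):
        wave += a * np.sin(2.0 * np.pi * f * x / spec.width + p)
    top = spec.height * spec.top_frac + wave
    bottom = spec.height * spec.bottom_frac + wave
    cum = np.concatenate([[0.0], np.cumsum(spec.fractions())])
    return top[None, :] + cum[:, None] * (bottom - top)[None, :]


def _label_map(spec: PhantomSpec, curves: np.ndarray) -> np.ndarray:
    rows = np.arange(spec.height, dtype=float)[:, None]
    lab = np.zeros((spec.height, spec.width), dtype=np.int32)
    for k in range(spec.n_layers):
        lab += (rows >= curves[k][None, :]).astype(np.int32)
    lab[rows >= curves[-1][None, :]] = 0
    lab[rows < curves[0][None, :]] = 0
    return lab


def speckle_field(
    shape: tuple[int, int], looks: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-mean multiplicative gamma speckle; ones when ``looks`` is inf."""
    if math.isinf(looks):
        return np.ones(shape)
    return rng.gamma(shape=looks, scale=1.0 / looks, size=shape)


def make_bscan_phantom(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> Phantom:
    """Render one layered B-scan phantom with multiplicative speckle.

    Returns the speckled image (float64, clipped to [0, 255]), the
    noise-free reflectivity map, the integer label mask (0 = background,
    1..n_layers top-to-bottom) and the boundary curves.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    curves = boundary_curves(spec)
    mask = _label_map(spec, curves)
    refl = np.full(mask.shape, spec.background_level, dtype=float)
    for k, r in enumerate(spec.layer_reflectivities, start=1):
        refl[mask == k] = r
    if spec.lateral_modulation > 0:
        # smooth lateral reflectivity variation (vessels, tissue texture);
        # deterministic from the spec seed, independent of the speckle draw
        rng_mod = np.random.default_rng(spec.rng_seed + 1331)
        mod = ndimage.gaussian_filter1d(
            rng_mod.standard_normal(spec.width), sigma=8.0, mode="wrap"
        )
        mod /= max(np.max(np.abs(mod)), 1e-12)
        refl = refl * (1.0 + spec.lateral_modulation * mod)[None, :]
    img = np.clip(refl * speckle_field(refl.shape, spec.speckle_looks, rng), 0, 255)
    return Phantom(image=img, reflectivity=refl, mask=mask, boundaries=curves)


# --------------------------------------------------------------------------
# scene script


@dataclass
class SceneScript:
    """Scripted per-frame geometry for one synthetic surgery video.

    ``rect_trajectory``: (n, 4, 2) corner coordinates (TL, TR, BR, BL).
    ``arrow_offsets``: (2, 2) cyan/magenta arrow-tip positions relative to
    the rectangle's top-left corner.  ``feature_trajectory``: (n, 2) retina
    feature point.  ``bscan_transforms``: true rigid motion of the phantom
    per frame.  ``stationary_segments``: inclusive frame ranges during
    which every scripted position is constant up to ``jitter``.
    """

    n_frames: int
    rect_trajectory: np.ndarray
    arrow_offsets: np.ndarray
    feature_trajectory: np.ndarray
    bscan_transforms: list[RigidTransform]
    stationary_segments: list[tuple[int, int]]
    jitter: float = 0.0
    rng_seed: int = 0
    scene_shape: tuple[int, int] = (360, 480)  # (h, w)

    def validate(self) -> None:
        if self.n_frames < 1:
            raise InvalidScriptError("a scene script needs at least one frame")
        n = self.n_frames
        if (
            len(self.rect_trajectory) != n
            or len(self.feature_trajectory) != n
            or len(self.bscan_transforms) != n
        ):
            raise InvalidScriptError("trajectory lengths must equal n_frames")
        for s, e in self.stationary_segments:
            if not (0 <= s <= e < n):
                raise InvalidScriptError(
                    f"stationary segment [{s}, {e}] outside [0, {n})"
                )


def make_scene_script(
    n_frames: int,
    stationary_segments: list[tuple[int, int]],
    rng_seed: int = 0,
    scene_shape: tuple[int, int] = (360, 480),
    rect_size: tuple[int, int] = (140, 90),
    drift_step: float = 3.0,
    jitter: float = 0.0,
    theta_step: float = 0.3,
    bscan_step: float = 1.2,
) -> SceneScript:
    """Script a video: smooth drift interrupted by stationary segments.

    Outside stationary segments the scan rectangle, the retina feature and
    the true B-scan transform all take a step of magnitude ``drift_step`` /
    ``bscan_step`` px (``theta_step`` degrees) per frame; inside a segment
    they stay at the segment's first-frame value up to ``jitter`` px.
    """
    if n_frames < 1:
        raise InvalidScriptError("a scene script needs at least one frame")
    segs = sorted((int(s), int(e)) for s, e in stationary_segments)
    for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
        if s2 <= e1:
            raise InvalidScriptError("stationary segments must be disjoint")
    rng = np.random.default_rng(rng_seed)
    h, w = scene_shape
    rw, rh = rect_size

    in_seg = np.full(n_frames, -1, dtype=int)
    for i, (s, e) in enumerate(segs):
        if not (0 <= s <= e < n_frames):
            raise InvalidScriptError(f"segment [{s}, {e}] outside [0, {n_frames})")
        in_seg[s : e + 1] = i

    rect_tl = np.empty((n_frames, 2))
    feature = np.empty((n_frames, 2))
    theta = np.empty(n_frames)
    txy = np.empty((n_frames, 2))

    rect_tl[0] = [w * 0.52, h * 0.14]
    feature[0] = [w * 0.22, h * 0.68]
    theta[0] = 0.0
    txy[0] = [0.0, 0.0]
    rect_dir = rng.uniform(0, 2 * np.pi)
    feat_dir = rng.uniform(0, 2 * np.pi)

    def _bounded_step(pos, direction, lo, hi):
        direction += rng.normal(0.0, 0.5)
        step = drift_step * np.array([np.cos(direction), np.sin(direction)])
        nxt = pos + step
        for a in (0, 1):
            if nxt[a] < lo[a] or nxt[a] > hi[a]:
                step[a] = -step[a]
                nxt[a] = pos[a] + step[a]
        return nxt, direction

    rect_lo = np.array([10.0, 10.0])
    rect_hi = np.array([w - rw - 10.0, h - rh - 10.0])
    feat_lo = np.array([30.0, 30.0])
    feat_hi = np.array([w - 30.0, h - 30.0])

    for t in range(1, n_frames):
        k = in_seg[t]
        if k >= 0 and in_seg[t - 1] == k:
            base = segs[k][0]
            jit = rng.uniform(-1, 1, size=7)
            jit *= jitter / max(1.0, np.max(np.abs(jit))) if jitter > 0 else 0.0
            rect_tl[t] = rect_tl[base] + jit[0:2]
            feature[t] = feature[base] + jit[2:4]
            theta[t] = theta[base] + jit[4] * 0.01
            txy[t] = txy[base] + jit[5:7]
        else:
            rect_tl[t], rect_dir = _bounded_step(rect_tl[t - 1], rect_dir, rect_lo, rect_hi)
            feature[t], feat_dir = _bounded_step(feature[t - 1], feat_dir, feat_lo, feat_hi)
            theta[t] = np.clip(theta[t - 1] + rng.choice([-1, 1]) * theta_step, -3.0, 3.0)
            step = rng.uniform(-1, 1, 2)
            step *= bscan_step / max(np.linalg.norm(step), 1e-9)
            txy[t] = np.clip(txy[t - 1] + step, -10.0, 10.0)

    corners = np.empty((n_frames, 4, 2))
    corners[:, 0] = rect_tl
    corners[:, 1] = rect_tl + [rw, 0]
    corners[:, 2] = rect_tl + [rw, rh]
    corners[:, 3] = rect_tl + [0, rh]
    transforms = [
        RigidTransform(theta=float(theta[t]), tx=float(txy[t, 0]), ty=float(txy[t, 1]))
        for t in range(n_frames)
    ]
    arrow_offsets = np.array([[18.0, rh / 2.0], [rw - 18.0, rh / 2.0]])
    return SceneScript(
        n_frames=n_frames,
        rect_trajectory=corners,
        arrow_offsets=arrow_offsets,
        feature_trajectory=feature,
        bscan_transforms=transforms,
        stationary_segments=segs,
        jitter=jitter,
        rng_seed=rng_seed,
        scene_shape=scene_shape,
    )


# --------------------------------------------------------------------------
# manifest


@dataclass
class SynthManifest:
    """Ground truth for one generated video; JSON-serializable losslessly."""

    scene_shape: tuple[int, int]
    bscan_shape: tuple[int, int]
    n_layers: int
    boundaries: np.ndarray           # base phantom curves (n_layers+1, width)
    stationary_segments: list[tuple[int, int]]
    jitter: float
    frames: list[dict] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def rect_corners(self, i: int) -> np.ndarray:
        return np.asarray(self.frames[i]["rect_corners"], dtype=float)

    def arrow_points(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        f = self.frames[i]
        return (
            np.asarray(f["cyan_point"], dtype=float),
            np.asarray(f["magenta_point"], dtype=float),
        )

    def feature_point(self, i: int) -> np.ndarray:
        return np.asarray(self.frames[i]["feature_point"], dtype=float)

    def transform(self, i: int) -> RigidTransform:
        return RigidTransform.from_dict(self.frames[i]["transform"])

    def frame_boundaries(self, i: int) -> np.ndarray:
        """Boundary curves of frame ``i``'s B-scan, resampled on the x grid."""
        tr = self.transform(i)
        w = self.bscan_shape[1]
        x = np.arange(w, dtype=float)
        out = np.empty_like(self.boundaries)
        for k, curve in enumerate(self.boundaries):
            pts = tr.apply_points(np.stack([x, curve], axis=1), self.bscan_shape)
            order = np.argsort(pts[:, 0])
            out[k] = np.interp(x, pts[order, 0], pts[order, 1])
        return out

    def to_dict(self) -> dict:
        return {
            "scene_shape": list(self.scene_shape),
            "bscan_shape": list(self.bscan_shape),
            "n_layers": int(self.n_layers),
            "boundaries": np.asarray(self.boundaries).tolist(),
            "stationary_segments": [list(s) for s in self.stationary_segments],
            "jitter": float(self.jitter),
            "frames": self.frames,
        }

    def save(self, path: str | os.PathLike) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "SynthManifest":
        return cls(
            scene_shape=tuple(d["scene_shape"]),
            bscan_shape=tuple(d["bscan_shape"]),
            n_layers=int(d["n_layers"]),
            boundaries=np.asarray(d["boundaries"], dtype=float),
            stationary_segments=[tuple(s) for s in d["stationary_segments"]],
            jitter=float(d["jitter"]),
            frames=list(d["frames"]),
        )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "SynthManifest":
        return cls.from_dict(json.loads(Path(path).read_text()))


def recompute_stationary_segments(
    manifest: SynthManifest, tol: float | None = None, min_len: int = 2
) -> list[tuple[int, int]]:
    """Re-derive stationary segments from per-frame manifest position deltas.

    A frame-to-frame step is stationary when every recorded quantity (all
    rectangle corners, both arrow points, the feature point, the B-scan
    translation, and the rotation as an edge displacement) moves at most
    ``tol`` px.  Default tolerance is ``2 * jitter`` plus numerical slack.
    """
    if tol is None:
        tol = 2.0 * manifest.jitter + 1e-6
    n = manifest.n_frames
    if n == 0:
        return []

    def _state(i: int) -> np.ndarray:
        f = manifest.frames[i]
        tr = manifest.transform(i)
        ang_px = math.radians(tr.theta) * manifest.bscan_shape[1] / 2.0
        return np.concatenate(
            [
                np.asarray(f["rect_corners"], float).ravel(),
                np.asarray(f["cyan_point"], float),
                np.asarray(f["magenta_point"], float),
                np.asarray(f["feature_point"], float),
                [tr.tx, tr.ty, ang_px],
            ]
        )

    states = np.stack([_state(i) for i in range(n)])
    still = np.abs(np.diff(states, axis=0)).max(axis=1) <= tol
    segs: list[tuple[int, int]] = []
    i = 0
    while i < n - 1:
        if still[i]:
            j = i
            while j < n - 1 and still[j]:
                j += 1
            if j - i + 1 >= min_len:
                segs.append((i, j))
            i = j + 1
        else:
            i += 1
    return segs


# --------------------------------------------------------------------------
# scene rendering


_FEATURE_SIGMA = 2.5
_FEATURE_AMP = 110.0
_SCENE_CEIL = 220.0  # fundus+feature stay below the white-marker threshold


def _render_fundus(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    tex = ndimage.gaussian_filter(rng.uniform(0, 1, (h, w)), sigma=5.0, mode="wrap")
    tex = (tex - tex.min()) / max(float(np.ptp(tex)), 1e-12)
    return 55.0 + 85.0 * tex


def _draw_feature(img: np.ndarray, centre: np.ndarray) -> None:
    h, w = img.shape
    x0, y0 = centre
    r = int(4 * _FEATURE_SIGMA)
    ys = np.arange(max(0, int(y0) - r), min(h, int(y0) + r + 1))
    xs = np.arange(max(0, int(x0) - r), min(w, int(x0) + r + 1))
    if ys.size == 0 or xs.size == 0:
        return
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    bump = _FEATURE_AMP * np.exp(
        -((gx - x0) ** 2 + (gy - y0) ** 2) / (2 * _FEATURE_SIGMA**2)
    )
    img[ys[0] : ys[-1] + 1, xs[0] : xs[-1] + 1] += bump


def _draw_rect_outline(rgb: np.ndarray, corners: np.ndarray) -> None:
    h, w = rgb.shape[:2]
    x0 = int(np.clip(round(corners[0, 0]), 0, w - 1))
    y0 = int(np.clip(round(corners[0, 1]), 0, h - 1))
    x1 = int(np.clip(round(corners[2, 0]), 0, w - 1))
    y1 = int(np.clip(round(corners[2, 1]), 0, h - 1))
    rgb[y0, x0 : x1 + 1] = 255
    rgb[y1, x0 : x1 + 1] = 255
    rgb[y0 : y1 + 1, x0] = 255
    rgb[y0 : y1 + 1, x1] = 255


def _draw_arrow(
    rgb: np.ndarray, tip: np.ndarray, direction: int, colour: tuple[int, int, int]
) -> np.ndarray:
    """Filled triangle with apex at ``tip`` pointing left/right; returns its
    drawn-pixel centroid (the quantity arrow detection estimates)."""
    length, half_h = 14.0, 6.0
    base_x = tip[0] - direction * length
    verts = np.array(
        [tip, [base_x, tip[1] - half_h], [base_x, tip[1] + half_h]]
    )
    rr, cc = polygon(verts[:, 1], verts[:, 0], shape=rgb.shape[:2])
    rgb[rr, cc] = colour
    return np.array([cc.mean(), rr.mean()])


def render_scene_frame(
    fundus: np.ndarray,
    fundus_shift: np.ndarray,
    rect_corners: np.ndarray,
    arrow_tips: np.ndarray,
    feature_point: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compose one RGB microscope-view frame.

    Returns the uint8 frame plus the drawn cyan and magenta centroids.
    """
    shifted = ndimage.shift(
        fundus, (fundus_shift[1], fundus_shift[0]), order=1, mode="reflect"
    )
    _draw_feature(shifted, feature_point)
    gray = np.clip(shifted, 0, _SCENE_CEIL)
    rgb = np.repeat(gray[:, :, None], 3, axis=2)
    _draw_rect_outline(rgb, rect_corners)
    cyan = _draw_arrow(rgb, arrow_tips[0], direction=1, colour=(0, 255, 255))
    magenta = _draw_arrow(rgb, arrow_tips[1], direction=-1, colour=(255, 0, 255))
    return np.round(np.clip(rgb, 0, 255)).astype(np.uint8), cyan, magenta


# --------------------------------------------------------------------------
# video generation


def make_surgery_video(
    phantom_spec: PhantomSpec,
    script: SceneScript,
    out_dir: str | os.PathLike,
) -> SynthManifest:
    """Write a full synthetic surgery video and its ground-truth manifest.

    Produces ``frames/scene_%05d.png`` (RGB microscope view),
    ``frames/bscan_%05d.png`` (8-bit grayscale B-scan, independently
    re-speckled each frame), ``masks/mask_%05d.png`` (integer labels) and
    ``manifest.json`` under ``out_dir``.
    """
    phantom_spec.validate()
    script.validate()
    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    base = make_bscan_phantom(
        PhantomSpec(**{**phantom_spec.__dict__, "speckle_looks": math.inf})
    )
    rng_speckle = np.random.default_rng(script.rng_seed)
    rng_tex = np.random.default_rng(phantom_spec.rng_seed + 977)
    fundus = _render_fundus(script.scene_shape, rng_tex)
    feat0 = script.feature_trajectory[0]

    manifest = SynthManifest(
        scene_shape=script.scene_shape,
        bscan_shape=base.image.shape,
        n_layers=phantom_spec.n_layers,
        boundaries=base.boundaries,
        stationary_segments=list(script.stationary_segments),
        jitter=script.jitter,
    )

    for t in range(script.n_frames):
        corners = script.rect_trajectory[t]
        tips = corners[0] + script.arrow_offsets
        feature = script.feature_trajectory[t]
        scene, cyan_c, magenta_c = render_scene_frame(
            fundus, feature - feat0, corners, tips, feature
        )
        scene_path = f"frames/scene_{t:05d}.png"
        iio.imwrite(out / scene_path, scene)

        tr = script.bscan_transforms[t]
        refl_t = tr.warp(base.reflectivity, order=1, cval=phantom_spec.background_level)
        spk = speckle_field(refl_t.shape, phantom_spec.speckle_looks, rng_speckle)
        bscan = np.clip(refl_t * spk, 0, 255)
        bscan_path = f"frames/bscan_{t:05d}.png"
        iio.imwrite(out / bscan_path, np.round(bscan).astype(np.uint8))

        mask_t = tr.warp(base.mask.astype(float), order=0, cval=0.0).astype(np.uint8)
        mask_path = f"masks/mask_{t:05d}.png"
        iio.imwrite(out / mask_path, mask_t)

        manifest.frames.append(
            {
                "index": t,
                "scene": scene_path,
                "bscan": bscan_path,
                "mask": mask_path,
                "transform": tr.to_dict(),
                "rect_corners": corners.tolist(),
                "cyan_point": cyan_c.tolist(),
                "magenta_point": magenta_c.tolist(),
                "feature_point": feature.tolist(),
            }
        )

    manifest.save(out / "manifest.json")
    return manifest
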