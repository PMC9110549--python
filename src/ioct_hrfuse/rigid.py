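"""2-D rigid (rotation + translation) transforms about the image centre.

Convention used throughout the package: pixel coordinates are 0-based pixel
centres, x to the right and y down.  A :class:`RigidTransform` maps a point
``p`` in the *moving* image to ``R(theta) @ (p - c) + c + t`` in the *fixed*
image, where ``c`` is the image centre ``((w-1)/2, (h-1)/2)`` and ``theta``
is in degrees, counter-clockwise in the (x, y) axes (which appears clockwise
on screen because y points down).  There is no scale or shear component.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


def _rot(theta_deg: float) -> np.ndarray:
    a = np.deg2rad(theta_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


def image_centre(shape: tuple[int, int]) -> np.ndarray:
    """Centre ``(x, y)`` of an ``(h, w)`` image on the pixel-centre grid."""
    h, w = shape[:2]
    return np.array([(w - 1) / 2.0, (h - 1) / 2.0])


@dataclass
class RigidTransform:
    """Rotation by ``theta`` degrees about the image centre plus translation.

    ``score`` optionally carries the normalized cross-correlation achieved
    when the transform was estimated by registration.
    """

    theta: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    score: float | None = field(default=None, compare=False)

    @property
    def t(self) -> np.ndarray:
        return np.array([self.tx, self.ty])

    def apply_points(self, pts: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        """Map ``(n, 2)`` moving-image points into fixed-image coordinates."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        c = image_centre(shape)
        return (pts - c) @ _rot(self.theta).T + c + self.t

    def inverse(self) -> "RigidTransform":
        t_inv = -_rot(-self.theta) @ self.t
        return RigidTransform(theta=-self.theta, tx=t_inv[0], ty=t_inv[1])

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``first`` then ``self``.

        Valid when both transforms share the same image centre (equal
        moving/fixed shapes), which is the only case the pipeline needs.
        """
        t = _rot(self.theta) @ first.t + self.t
        return RigidTransform(theta=self.theta + first.theta, tx=t[0], ty=t[1])

    def warp(
        self,
        moving: np.ndarray,
        order: int = 1,
        cval: float = 0.0,
    ) -> np.ndarray:
        """Resample ``moving`` onto the fixed grid (inverse mapping, bilinear
        by default)."""
        moving = np.asarray(moving, dtype=float)
        h, w = moving.shape
        c = image_centre(moving.shape)
        xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        fixed_pts = np.stack([xs.ravel(), ys.ravel()], axis=1)
        mov_pts = (fixed_pts - c - self.t) @ _rot(-self.theta).T + c
        out = ndimage.map_coordinates(
            moving,
            [mov_pts[:, 1].reshape(h, w), mov_pts[:, 0].reshape(h, w)],
            order=order,
            mode="constant",
            cval=cval,
        )
        return out

    def warp_with_mask(
        self, moving: np.ndarray, order: int = 1, cval: float = 0.0
    ) -> tuple[np.ndarray, np.ndarray]:
        """Warp and return ``(warped, valid)`` where ``valid`` marks fixed
        pixels whose inverse-mapped source lies inside the moving frame."""
        moving = np.asarray(moving, dtype=float)
        h, w = moving.shape
        c = image_centre(moving.shape)
        xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        fixed_pts = np.stack([xs.ravel(), ys.ravel()], axis=1)
        mov_pts = (fixed_pts - c - self.t) @ _rot(-self.theta).T + c
        mx = mov_pts[:, 0].reshape(h, w)
        my = mov_pts[:, 1].reshape(h, w)
        out = ndimage.map_coordinates(
            moving, [my, mx], order=order, mode="constant", cval=cval
        )
        valid = (mx >= 0) & (mx <= w - 1) & (my >= 0) & (my <= h - 1)
        return out, valid

    def coverage(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of fixed-grid pixels fully interpolated from data."""
        ones = np.ones(shape, dtype=float)
        return self.warp(ones, order=1, cval=0.0) > 0.999

    def magnitude(self, shape: tuple[int, int]) -> float:
        """Largest corner displacement (px) the transform induces."""
        h, w = shape[:2]
        corners = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], float)
        d = self.apply_points(corners, shape) - corners
        return float(np.max(np.hypot(d[:, 0], d[:, 1])))

    def to_dict(self) -> dict:
        d = {"theta": float(self.theta), "tx": float(self.tx), "ty": float(self.ty)}
        if self.score is not None:
            d["score"] = float(self.score)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            theta=float(d["theta"]),
            tx=float(d["tx"]),
            ty=float(d["ty"]),
            score=d.get("score"),
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(0.0, 0.0, 0.0)
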