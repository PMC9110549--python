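"""Natural Image Quality Evaluator (NIQE): a completely blind, opinion-free
image quality score.

The model summarises the natural-scene statistics of a pristine corpus:
images are MSCN-normalized (local mean subtracted, local contrast
divided out), per-patch features are extracted — a generalized Gaussian
(GGD) fit to the MSCN coefficients plus asymmetric generalized Gaussian
(AGGD) fits to the four orientations of pairwise products — at two scales,
and a multivariate Gaussian (mean + covariance) is fitted to the pooled
patch features.  A test image is scored by the Mahalanobis-type distance

    d = sqrt( (nu1 - nu2)^T [ (Sigma1 + Sigma2) / 2 ]^-1 (nu1 - nu2) )

between its own feature statistics and the corpus model; lower means more
similar to the corpus.  During fitting, only the sharpest patches (local
contrast above 75% of the maximum) contribute, so the model describes
structured retinal content rather than empty background.

The AGGD shape parameter is estimated by moment matching against a dense
grid of the gamma-function ratio r(alpha) = Gamma(2/a)^2 / (Gamma(1/a)
Gamma(3/a)); the grid (alpha in [0.2, 10], step 0.001) is fixed here for
reproducibility.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.special import gamma as gamma_fn

from .errors import InsufficientCorpusError, InvalidInputError

__all__ = ["NiqeModel", "niqe_fit", "niqe_score", "extract_niqe_features"]

# moment-matching grid for the GGD/AGGD shape parameter
_ALPHA_GRID = np.arange(0.2, 10.0 + 1e-9, 0.001)
_R_GRID = gamma_fn(2.0 / _ALPHA_GRID) ** 2 / (
    gamma_fn(1.0 / _ALPHA_GRID) * gamma_fn(3.0 / _ALPHA_GRID)
)

_MSCN_SIGMA = 7.0 / 6.0
_MSCN_TRUNCATE = 3.0 / _MSCN_SIGMA  # 7x7 Gaussian support


def _mscn(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-subtracted contrast-normalized coefficients and the local-sigma
    (sharpness) field."""
    img = img.astype(float)
    mu = ndimage.gaussian_filter(img, _MSCN_SIGMA, truncate=_MSCN_TRUNCATE, mode="nearest")
    sigma = np.sqrt(
        np.maximum(
            ndimage.gaussian_filter(img * img, _MSCN_SIGMA, truncate=_MSCN_TRUNCATE, mode="nearest")
            - mu * mu,
            0.0,
        )
    )
    return (img - mu) / (sigma + 1.0), sigma


def _fit_ggd(x: np.ndarray) -> tuple[float, float]:
    """Moment-matched generalized Gaussian fit: (shape alpha, variance)."""
    x = x.ravel()
    m2 = np.mean(x * x)
    if m2 < 1e-12:
        return 2.0, 0.0
    rho = np.mean(np.abs(x)) ** 2 / m2
    alpha = _ALPHA_GRID[np.argmin(np.abs(_R_GRID - rho))]
    return float(alpha), float(m2)


def _fit_aggd(x: np.ndarray) -> tuple[float, float, float, float]:
    """Moment-matched asymmetric GGD fit: (alpha, eta, var_left, var_right).

    ``eta`` is the distribution mean implied by the fitted parameters; the
    left/right variances capture the asymmetry of the product coefficients.
    """
    x = x.ravel()
    left = x[x < 0]
    right = x[x >= 0]
    sl = np.sqrt(np.mean(left**2)) if left.size else 0.0
    sr = np.sqrt(np.mean(right**2)) if right.size else 0.0
    if sl < 1e-12 or sr < 1e-12:
        return 2.0, 0.0, float(sl**2), float(sr**2)
    g = sl / sr
    m1 = np.mean(np.abs(x))
    m2 = np.mean(x**2)
    rho = m1**2 / m2
    rhat = rho * (g**3 + 1.0) * (g + 1.0) / (g**2 + 1.0) ** 2
    alpha = _ALPHA_GRID[np.argmin(np.abs(_R_GRID - rhat))]
    ratio = gamma_fn(2.0 / alpha) / gamma_fn(1.0 / alpha)
    eta = (sr - sl) * ratio * np.sqrt(
        gamma_fn(1.0 / alpha) / gamma_fn(3.0 / alpha)
    )
    return float(alpha), float(eta), float(sl**2), float(sr**2)


def _patch_features(mscn: np.ndarray) -> np.ndarray:
    """18 features of one patch: GGD(alpha, var) of the MSCN coefficients
    plus AGGD(alpha, eta, var_l, var_r) of the H, V, D1, D2 products."""
    feats = list(_fit_ggd(mscn))
    shifts = [(0, 1), (1, 0), (1, 1), (1, -1)]
    for dy, dx in shifts:
        prod = mscn[: mscn.shape[0] - dy, : mscn.shape[1] - abs(dx)]
        if dx >= 0:
            nbr = mscn[dy:, dx:]
        else:
            prod = mscn[: mscn.shape[0] - dy, abs(dx):]
            nbr = mscn[dy:, : mscn.shape[1] - abs(dx)]
        feats.extend(_fit_aggd(prod * nbr))
    return np.asarray(feats)


def extract_niqe_features(
    image: np.ndarray,
    patch_size: int = 96,
    sharpness_frac: float | None = 0.75,
) -> np.ndarray:
    """Per-patch NIQE features at two scales, shape (n_patches, 36).

    With ``sharpness_frac`` set, only patches whose mean local sigma
    exceeds that fraction of the sharpest patch's are kept (all patches
    are kept if fewer than two would survive).  Pass ``None`` to keep all
    patches, as done when scoring a test image.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InvalidInputError("NIQE expects a grayscale image")
    if min(img.shape) < patch_size:
        raise InvalidInputError(
            f"image {img.shape} smaller than patch size {patch_size}"
        )
    half = _superpixel_half(img)
    scales = [(img, patch_size), (half, patch_size // 2)]

    mscn0, sigma0 = _mscn(img)
    h, w = img.shape
    ny, nx = h // patch_size, w // patch_size

    sharp = np.empty((ny, nx))
    for iy in range(ny):
        for ix in range(nx):
            sharp[iy, ix] = sigma0[
                iy * patch_size : (iy + 1) * patch_size,
                ix * patch_size : (ix + 1) * patch_size,
            ].mean()
    if sharpness_frac is None:
        keep = np.ones((ny, nx), dtype=bool)
    else:
        keep = sharp > sharpness_frac * sharp.max()
        if keep.sum() < 2:
            keep = np.ones((ny, nx), dtype=bool)

    mscn1, _ = _mscn(half)
    mscns = [mscn0, mscn1]
    feats = []
    for iy in range(ny):
        for ix in range(nx):
            if not keep[iy, ix]:
                continue
            row = []
            for (im, ps), mscn in zip(scales, mscns):
                y0, x0 = iy * ps, ix * ps
                row.append(_patch_features(mscn[y0 : y0 + ps, x0 : x0 + ps]))
            feats.append(np.concatenate(row))
    return np.stack(feats)


def _superpixel_half(img: np.ndarray) -> np.ndarray:
    h, w = img.shape
    h2, w2 = h - h % 2, w - w % 2
    v = img[:h2, :w2]
    return 0.25 * (v[0::2, 0::2] + v[1::2, 0::2] + v[0::2, 1::2] + v[1::2, 1::2])


@dataclass
class NiqeModel:
    """Multivariate-Gaussian summary of a pristine corpus' NIQE features."""

    mean: np.ndarray
    cov: np.ndarray
    n_images: int
    n_patches: int
    patch_size: int

    @property
    def n_features(self) -> int:
        return int(self.mean.shape[0])

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "n_images": int(self.n_images),
            "n_patches": int(self.n_patches),
            "patch_size": int(self.patch_size),
        }

    def save(self, path: str | os.PathLike) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "NiqeModel":
        return cls(
            mean=np.asarray(d["mean"], dtype=float),
            cov=np.asarray(d["cov"], dtype=float),
            n_images=int(d["n_images"]),
            n_patches=int(d["n_patches"]),
            patch_size=int(d["patch_size"]),
        )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "NiqeModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_feature_gaussian(features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean vector and covariance matrix of pooled patch features."""
    features = np.asarray(features, dtype=float)
    mean = features.mean(axis=0)
    cov = np.cov(features, rowvar=False)
    return mean, np.atleast_2d(cov)


def niqe_fit(
    corpus: list[np.ndarray], patch_size: int = 96
) -> NiqeModel:
    """Fit the pristine-corpus model from at least two images."""
    if len(corpus) < 2:
        raise InsufficientCorpusError(
            f"NIQE fitting needs >= 2 images, got {len(corpus)}"
        )
    feats = np.concatenate(
        [extract_niqe_features(im, patch_size=patch_size) for im in corpus]
    )
    mean, cov = fit_feature_gaussian(feats)
    return NiqeModel(
        mean=mean,
        cov=cov,
        n_images=len(corpus),
        n_patches=feats.shape[0],
        patch_size=patch_size,
    )


def niqe_score(
    image: np.ndarray, model: NiqeModel, ridge: float = 1e-6
) -> float:
    """Score one image against a fitted model; lower is more corpus-like.

    A singular pooled covariance is regularized by a small ridge on the
    diagonal (scaled by the mean variance)."""
    feats = extract_niqe_features(
        image, patch_size=model.patch_size, sharpness_frac=None
    )
    mean2, cov2 = fit_feature_gaussian(feats)
    pooled = (model.cov + cov2) / 2.0
    diff = model.mean - mean2
    scale = max(np.trace(pooled) / pooled.shape[0], 1.0)
    try:
        sol = np.linalg.solve(
            pooled + ridge * scale * np.eye(pooled.shape[0]), diff
        )
    except np.linalg.LinAlgError:
        sol = np.linalg.pinv(pooled) @ diff
    return float(np.sqrt(max(np.dot(diff, sol), 0.0)))
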