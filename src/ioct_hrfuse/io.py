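"""Frame, mask and artefact readers/writers.

Images are stored as 8-bit grayscale PNG (or RGB PNG for microscope
views); all computation happens on float64 copies.  Fused means can
optionally be written as 16-bit PNG to avoid quantizing averages.
"""
from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import InvalidInputError


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read an image as float64; 16-bit grayscale is rescaled to [0, 255]."""
    arr = np.asarray(iio.imread(path))
    out = arr.astype(float)
    if arr.dtype == np.uint16:
        out /= 257.0
    return out


def load_gray(path: str | os.PathLike) -> np.ndarray:
    img = load_image(path)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    return img


def save_image_u8(path: str | os.PathLike, image: np.ndarray) -> None:
    """Round-half-even to 8 bits and write PNG."""
    iio.imwrite(path, np.round(np.clip(image, 0, 255)).astype(np.uint8))


def save_image_u16(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write a [0, 255] float image as 16-bit PNG (scale 257)."""
    iio.imwrite(path, np.round(np.clip(image, 0, 255) * 257.0).astype(np.uint16))


def load_mask(path: str | os.PathLike) -> np.ndarray:
    """Integer-label mask image."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr.astype(np.int32)


def list_frames(directory: str | os.PathLike, pattern: str) -> list[Path]:
    paths = sorted(Path(directory).glob(pattern))
    return paths


@dataclass
class VideoInput:
    """Scene/B-scan/mask frame paths for one video directory."""

    root: Path
    scene_paths: list[Path]
    bscan_paths: list[Path]
    mask_paths: list[Path]

    @property
    def n_frames(self) -> int:
        return len(self.scene_paths)


def open_video_dir(input_dir: str | os.PathLike) -> VideoInput:
    """Resolve a generated or converted video directory.

    Expects ``frames/scene_*.png`` and ``frames/bscan_*.png``; masks under
    ``masks/`` are optional.
    """
    root = Path(input_dir)
    scenes = list_frames(root / "frames", "scene_*.png")
    bscans = list_frames(root / "frames", "bscan_*.png")
    masks = list_frames(root / "masks", "mask_*.png") if (root / "masks").is_dir() else []
    if not scenes or not bscans:
        raise InvalidInputError(f"no scene/bscan frames under {root}")
    if len(scenes) != len(bscans):
        raise InvalidInputError(
            f"{len(scenes)} scene frames vs {len(bscans)} B-scans"
        )
    return VideoInput(root=root, scene_paths=scenes, bscan_paths=bscans, mask_paths=masks)
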