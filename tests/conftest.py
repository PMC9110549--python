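"""Shared fixtures: phantoms and one small synthetic surgery video.

Everything is generated programmatically at test time; nothing is read
from checked-in data.
"""
from __future__ import annotations

import math

import numpy as np
import pytest

from ioct_hrfuse.synthgen import (
    PhantomSpec,
    make_bscan_phantom,
    make_scene_script,
    make_surgery_video,
)

#: Flat, unmodulated two-layer phantom with low reflectivity: a clean
#: stage for speckle-statistics checks (no clipping, no lateral texture).
FLAT_SPEC = dict(
    width=260,
    height=200,
    n_layers=2,
    layer_reflectivities=(40.0, 40.0),
    surface_amplitudes=(),
    surface_frequencies=(),
    surface_phases=(),
    top_frac=0.1,
    bottom_frac=0.95,
    lateral_modulation=0.0,
)

#: 64x64 region wholly inside layer 1 of FLAT_SPEC (rows 20..190 retina).
FLAT_ROI = (np.s_[40:104], np.s_[60:124])


def flat_phantom(looks: float, seed: int):
    return make_bscan_phantom(
        PhantomSpec(**FLAT_SPEC, speckle_looks=looks, rng_seed=seed)
    )


@pytest.fixture(scope="session")
def phantom_nf():
    """Default noise-free phantom (440x300, 5 layers)."""
    return make_bscan_phantom(PhantomSpec(speckle_looks=math.inf, rng_seed=0))


@pytest.fixture(scope="session")
def video_dir(tmp_path_factory):
    """One 30-frame video with a single scripted stationary segment."""
    out = tmp_path_factory.mktemp("video")
    spec = PhantomSpec(speckle_looks=4.0, rng_seed=1)
    script = make_scene_script(30, [(5, 16)], rng_seed=2)
    manifest = make_surgery_video(spec, script, out)
    return out, manifest, script


@pytest.fixture(scope="session")
def scene_frames(video_dir):
    import imageio.v3 as iio

    out, manifest, _ = video_dir
    frames = [
        iio.imread(out / manifest.frames[t]["scene"])
        for t in range(manifest.n_frames)
    ]
    return frames
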