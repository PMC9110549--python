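"""ROI placement, SNR/ENL/CNR statistics and the acceptance gate."""
import math

import numpy as np
import pytest

from ioct_hrfuse.errors import (
    DegenerateBackgroundError,
    DegenerateRegionError,
    InvalidMetricError,
    PlacementFailedError,
    SegmentationFailedError,
)
from ioct_hrfuse.quality import (
    LayerMask,
    Roi,
    RoiSizes,
    compute_cnr,
    compute_enl,
    compute_snr,
    gate_quality,
    place_rois,
    segment_layers_heuristic,
)
from ioct_hrfuse.synthgen import PhantomSpec, make_bscan_phantom


# ---- independent single-expression oracles -------------------------------

def snr_oracle(img, roi):
    f = img.astype(float)
    bg = f[roi.y : roi.y + roi.h, roi.x : roi.x + roi.w]
    return 10.0 * np.log10((f ** 2).max() / bg.var())


def enl_oracle(img, rois):
    f = img.astype(float)
    return np.mean(
        [
            f[r.y : r.y + r.h, r.x : r.x + r.w].mean() ** 2
            / f[r.y : r.y + r.h, r.x : r.x + r.w].var()
            for r in rois
        ]
    )


def cnr_oracle(img, rois, bg):
    f = img.astype(float)
    b = f[bg.y : bg.y + bg.h, bg.x : bg.x + bg.w]
    vals = []
    for r in rois:
        p = f[r.y : r.y + r.h, r.x : r.x + r.w]
        vals.append((p.mean() - b.mean()) / np.sqrt(p.var() + b.var()))
    return np.mean(vals)


def _random_rois(rng, shape, n):
    rois = []
    for _ in range(n):
        w, h = int(rng.integers(4, 16)), int(rng.integers(4, 16))
        x = int(rng.integers(0, shape[1] - w))
        y = int(rng.integers(0, shape[0] - h))
        rois.append(Roi(x, y, w, h, "homogeneous", 1))
    return rois


class TestSegmentation:
    def test_noise_free_phantom_agreement(self, phantom_nf):
        mask = segment_layers_heuristic(phantom_nf.image, n_layers=5)
        agree = (mask.labels == phantom_nf.mask).mean()
        assert agree >= 0.95
        assert mask.provenance == "heuristic"

    def test_all_zero_image_fails(self):
        with pytest.raises(SegmentationFailedError):
            segment_layers_heuristic(np.zeros((100, 120)))

    def test_speckled_top_surface_rms(self):
        ph = make_bscan_phantom(PhantomSpec(speckle_looks=4.0, rng_seed=5))
        mask = segment_layers_heuristic(ph.image, n_layers=5)
        top_est = np.full(ph.image.shape[1], np.nan)
        has = (mask.labels > 0).any(axis=0)
        top_est[has] = (mask.labels > 0).argmax(axis=0)[has]
        rms = np.sqrt(np.nanmean((top_est - ph.boundaries[0]) ** 2))
        assert rms < 3.0


class TestRoiPlacement:
    def test_all_five_rois_contained(self, phantom_nf):
        mask = LayerMask(phantom_nf.mask)
        rois = place_rois(mask, rng_seed=7)
        assert len(rois.all_rois()) == 5
        assert len(rois.cnr_regions) == 4
        for roi in rois.all_rois():
            patch = mask.labels[roi.y : roi.y + roi.h, roi.x : roi.x + roi.w]
            assert patch.shape == (roi.h, roi.w)  # inside bounds
            assert (patch == roi.target_label).all()

    def test_impossible_background_placement(self):
        labels = np.ones((60, 60), dtype=int)
        labels[40:, :] = 2
        labels[0:2, 0:2] = 0  # background smaller than the 32x32 ROI
        with pytest.raises(PlacementFailedError, match="background"):
            place_rois(LayerMask(labels))

    def test_different_seeds_different_centres(self, phantom_nf):
        mask = LayerMask(phantom_nf.mask)
        a = place_rois(mask, rng_seed=1)
        b = place_rois(mask, rng_seed=2)
        assert a.to_dict() != b.to_dict()
        assert place_rois(mask, rng_seed=1).to_dict() == a.to_dict()

    def test_homogeneous_rois_on_second_and_last_layers(self, phantom_nf):
        rois = place_rois(LayerMask(phantom_nf.mask), rng_seed=3)
        assert sorted(r.target_label for r in rois.homogeneous) == [2, 5]
        assert sorted(r.target_label for r in rois.contrast) == [1, 5]
        assert rois.background.target_label == 0


class TestMetricFormulas:
    def test_snr_hand_example(self):
        img = np.zeros((10, 10))
        img[0, 0] = 10.0
        img[8:10, 0:2] = [[0, 2], [2, 0]]  # variance 1
        roi = Roi(0, 8, 2, 2, "background", 0)
        assert compute_snr(img, roi) == pytest.approx(20.0, abs=1e-12)

    def test_snr_constant_background_rejected(self):
        img = np.random.default_rng(0).random((20, 20)) * 255
        img[0:4, 0:4] = 5.0
        with pytest.raises(DegenerateBackgroundError):
            compute_snr(img, Roi(0, 0, 4, 4, "background", 0))

    def test_enl_hand_example(self):
        img = np.zeros((4, 8))
        img[0] = [2, 6, 2, 6, 2, 6, 2, 6]          # mu=4, sigma=2
        img[1] = [3, 9, 3, 9, 3, 9, 3, 9]          # mu=6, sigma=3
        rois = [Roi(0, 0, 8, 1, "homogeneous", 1), Roi(0, 1, 8, 1, "homogeneous", 2)]
        assert compute_enl(img, rois) == pytest.approx(4.0, abs=1e-12)

    def test_enl_constant_roi_rejected(self):
        img = np.ones((10, 10))
        with pytest.raises(DegenerateRegionError):
            compute_enl(img, [Roi(0, 0, 4, 4, "homogeneous", 1)])

    def test_cnr_zero_when_means_equal(self):
        rng = np.random.default_rng(1)
        img = np.zeros((20, 20))
        img[0:4, :] = rng.permutation(np.tile([1.0, 3.0], 40)).reshape(4, 20)
        img[10:14, :] = rng.permutation(np.tile([1.0, 3.0], 40)).reshape(4, 20)
        bg = Roi(0, 0, 20, 4, "background", 0)
        r = Roi(0, 10, 20, 4, "contrast", 1)
        assert compute_cnr(img, [r], bg) == pytest.approx(0.0, abs=1e-12)

    def test_cnr_hand_example(self):
        # region mu=3 sigma=1, background mu=1 sigma=1 -> 2/sqrt(2)
        img = np.zeros((4, 4))
        img[0] = [0, 2, 0, 2]
        img[2] = [2, 4, 2, 4]
        bg = Roi(0, 0, 4, 1, "background", 0)
        r = Roi(0, 2, 4, 1, "contrast", 1)
        assert compute_cnr(img, [r], bg) == pytest.approx(2 / math.sqrt(2), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_all_three_match_brute_force_oracles(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((64, 64)) * 255
        bg = _random_rois(rng, img.shape, 1)[0]
        homog = _random_rois(rng, img.shape, 2)
        regions = _random_rois(rng, img.shape, 4)
        assert compute_snr(img, bg) == pytest.approx(snr_oracle(img, bg), rel=1e-12)
        assert compute_enl(img, homog) == pytest.approx(enl_oracle(img, homog), rel=1e-12)
        assert compute_cnr(img, regions, bg) == pytest.approx(
            cnr_oracle(img, regions, bg), rel=1e-12
        )

    def test_snr_monotone_in_background_noise(self):
        rng = np.random.default_rng(9)
        base = np.full((64, 64), 10.0)
        base[0, 0] = 200.0
        bg = Roi(32, 32, 16, 16, "background", 0)
        values = []
        for sigma in (2.0, 5.0, 10.0):
            img = base + rng.normal(0, sigma, base.shape)
            values.append(compute_snr(np.clip(img, 0, 255), bg))
        assert values[0] > values[1] > values[2]


class TestGate:
    def test_paper_thresholds_accept(self):
        rep = gate_quality(71.0, 3.5, 12.0)
        assert rep.accepted

    def test_one_metric_below_rejects(self):
        assert not gate_quality(69.9, 5.0, 50.0).accepted

    def test_boundary_inclusive(self):
        assert gate_quality(70.0, 3.0, 10.0).accepted

    def test_nan_rejected(self):
        with pytest.raises(InvalidMetricError):
            gate_quality(float("nan"), 3.0, 10.0)

    def test_custom_thresholds(self):
        rep = gate_quality(50.0, 1.0, 2.0, thresholds=(40.0, 0.5, 1.0))
        assert rep.accepted and rep.thresholds == (40.0, 0.5, 1.0)
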