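"""PSNR, SSIM, GCF and NIQE against independent implementations and
ordering properties."""
import math

import numpy as np
import pytest
from scipy import ndimage
from scipy.special import gamma as gamma_fn

from ioct_hrfuse.errors import (
    InsufficientCorpusError,
    InvalidInputError,
    ShapeMismatchError,
)
from ioct_hrfuse.metrics import (
    GCF_WEIGHT_COEFFS,
    MetricReport,
    compute_gcf,
    compute_psnr,
    compute_ssim,
)
from ioct_hrfuse.niqe import (
    NiqeModel,
    extract_niqe_features,
    fit_feature_gaussian,
    niqe_fit,
    niqe_score,
)


class TestPsnr:
    def test_identical_images_infinite(self):
        img = np.random.default_rng(0).random((32, 32))
        assert compute_psnr(img, img) == math.inf

    def test_hand_example(self):
        a = np.array([[0.0, 0.0]])
        b = np.array([[0.0, 255.0]])
        assert compute_psnr(a, b) == pytest.approx(10 * math.log10(2), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random((40, 50)) * 255, rng.random((40, 50)) * 255
        expected = 10 * np.log10(255.0**2 / np.mean((a - b) ** 2))
        assert compute_psnr(a, b) == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeMismatchError):
            compute_psnr(np.zeros((4, 4)), np.zeros((4, 5)))

    def test_decreases_with_noise_level(self):
        rng = np.random.default_rng(3)
        a = rng.random((64, 64)) * 255
        vals = [
            compute_psnr(a, np.clip(a + rng.normal(0, s, a.shape), 0, 255))
            for s in (5.0, 15.0, 40.0)
        ]
        assert vals[0] > vals[1] > vals[2]


def ssim_reference(a, b, data_range=255.0):
    """Independent SSIM: Gaussian-weighted local moments via correlate."""
    k = np.arange(-5, 6, dtype=float)
    g = np.exp(-(k**2) / (2 * 1.5**2))
    win = np.outer(g, g)
    win /= win.sum()

    def f(x):
        return ndimage.correlate(x, win, mode="reflect")

    a = a.astype(float)
    b = b.astype(float)
    c1, c2 = (0.01 * data_range) ** 2, (0.03 * data_range) ** 2
    mu_a, mu_b = f(a), f(b)
    va = f(a * a) - mu_a**2
    vb = f(b * b) - mu_b**2
    cab = f(a * b) - mu_a * mu_b
    s = ((2 * mu_a * mu_b + c1) * (2 * cab + c2)) / (
        (mu_a**2 + mu_b**2 + c1) * (va + vb + c2)
    )
    pad = 5  # skimage crops the filter radius off the edges
    return float(s[pad:-pad, pad:-pad].mean())


class TestSsim:
    def test_identity(self):
        img = np.random.default_rng(1).random((32, 32)) * 255
        assert compute_ssim(img, img) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((32, 32)) * 255, rng.random((32, 32)) * 255
        assert compute_ssim(a, b) == pytest.approx(compute_ssim(b, a), rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_implementation(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((48, 56)) * 255
        b = np.clip(a + rng.normal(0, 20, a.shape), 0, 255)
        assert compute_ssim(a, b) == pytest.approx(ssim_reference(a, b), abs=1e-6)

    def test_too_small_image_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_ssim(np.zeros((8, 8)), np.zeros((8, 8)))

    def test_bounded(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a, b = rng.random((16, 16)) * 255, rng.random((16, 16)) * 255
            assert -1.0 <= compute_ssim(a, b) <= 1.0


def gcf_reference(image, n_levels=9):
    """Independent GCF with explicit python loops."""
    lin = (np.clip(image.astype(float), 0, 255) / 255.0) ** 2.2
    a, b, c = GCF_WEIGHT_COEFFS
    total = 0.0
    for i in range(1, n_levels + 1):
        lum = 100.0 * np.sqrt(lin)
        h, w = lum.shape
        lc = 0.0
        for y in range(h):
            for x in range(w):
                s, n = 0.0, 0
                for dy, dx in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w:
                        s += abs(lum[y, x] - lum[yy, xx])
                        n += 1
                lc += s / n if n else 0.0
        total += ((a * i / n_levels + b) * i / n_levels + c) * (lc / (h * w) if h * w > 1 else 0.0)
        # 2x superpixels, ragged edge folded into the last one
        nh, nw = max(1, h // 2), max(1, w // 2)
        new = np.zeros((nh, nw))
        for y in range(nh):
            for x in range(nw):
                y1 = h if y == nh - 1 else 2 * y + 2
                x1 = w if x == nw - 1 else 2 * x + 2
                new[y, x] = lin[2 * y : y1, 2 * x : x1].mean()
        lin = new
    return total


class TestGcf:
    def test_constant_image_zero(self):
        assert compute_gcf(np.full((64, 64), 128.0)) == 0.0

    def test_checkerboard_matches_reference(self):
        yy, xx = np.indices((64, 64))
        board = 255.0 * ((yy + xx) % 2)
        assert compute_gcf(board) == pytest.approx(gcf_reference(board), abs=1e-9)

    def test_random_image_matches_reference(self):
        img = np.random.default_rng(4).random((40, 56)) * 255
        assert compute_gcf(img) == pytest.approx(gcf_reference(img), abs=1e-9)

    def test_contrast_stretch_increases_gcf(self, phantom_nf):
        img = phantom_nf.image
        stretched = np.clip((img - img.mean()) * 1.5 + img.mean(), 0, 255)
        assert compute_gcf(stretched) > compute_gcf(img)

    def test_translation_invariance_whole_superpixels(self):
        rng = np.random.default_rng(5)
        img = np.full((1024, 512), 30.0)
        img[300:420, 150:300] = 30 + 150 * rng.random((120, 150))
        rolled = np.roll(img, 256, axis=0)
        assert compute_gcf(rolled) == pytest.approx(compute_gcf(img), rel=1e-9)

    def test_empty_image_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_gcf(np.zeros((0, 0)))


def _textured(rng, shape=(128, 128)):
    base = ndimage.gaussian_filter(rng.random(shape), 3.0) * 255
    return base + rng.normal(0, 10, shape)


class TestNiqe:
    def test_duplicate_corpus_mean_equals_single_image_mean(self):
        img = _textured(np.random.default_rng(0))
        model = niqe_fit([img, img], patch_size=64)
        single = extract_niqe_features(img, patch_size=64).mean(axis=0)
        assert np.allclose(model.mean, single, atol=1e-12)

    def test_gaussian_parameter_recovery(self):
        """Fitting bypassing extraction recovers a known Gaussian."""
        rng = np.random.default_rng(6)
        true_mean = np.array([1.0, -2.0, 0.5])
        chol = np.array([[1.0, 0, 0], [0.3, 0.8, 0], [-0.2, 0.1, 0.6]])
        true_cov = chol @ chol.T
        x = rng.standard_normal((1000, 3)) @ chol.T + true_mean
        mean, cov = fit_feature_gaussian(x)
        assert np.abs(mean - true_mean).max() < 0.05 * np.abs(true_mean).max() + 0.05
        assert np.abs(cov - true_cov).max() < 0.05 * np.abs(true_cov).max() + 0.05

    def test_single_image_corpus_rejected(self):
        with pytest.raises(InsufficientCorpusError):
            niqe_fit([np.zeros((96, 96))])

    def test_noisy_version_scores_higher(self):
        rng = np.random.default_rng(8)
        corpus = [_textured(rng) for _ in range(4)]
        model = niqe_fit(corpus, patch_size=64)
        clean = corpus[0]
        noisy = clean + rng.normal(0, 30, clean.shape)
        assert niqe_score(clean, model) < niqe_score(noisy, model)

    def test_score_nonnegative_and_deterministic(self):
        rng = np.random.default_rng(9)
        corpus = [_textured(rng) for _ in range(3)]
        model = niqe_fit(corpus, patch_size=64)
        refit = niqe_fit(corpus, patch_size=64)
        probe = _textured(rng)
        s1, s2 = niqe_score(probe, model), niqe_score(probe, refit)
        assert s1 >= 0.0
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_model_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(10)
        model = niqe_fit([_textured(rng) for _ in range(2)], patch_size=64)
        p = tmp_path / "model.json"
        model.save(p)
        back = NiqeModel.load(p)
        assert np.array_equal(back.mean, model.mean)
        assert np.array_equal(back.cov, model.cov)
        assert back.patch_size == model.patch_size
        # covariance symmetric PSD
        assert np.allclose(model.cov, model.cov.T)
        assert np.linalg.eigvalsh(model.cov).min() > -1e-8


class TestMetricReport:
    def test_aggregate_ignores_missing(self):
        rep = MetricReport(
            names=["a", "b", "c"],
            psnr=[20.0, None, 30.0],
            ssim=[0.5, 0.6, 0.7],
            gcf=[None, None, None],
            niqe=[1.0, 2.0, 3.0],
        )
        agg = rep.aggregate()
        assert agg["psnr"] == (25.0, 5.0)
        assert agg["gcf"] is None
        rows = rep.to_rows()
        assert rows[1]["psnr"] is None and rows[1]["ssim"] == 0.6
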