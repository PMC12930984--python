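import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from skimage.metrics import structural_similarity

from defaceqc import (
    DefaceSimSpec,
    SimilarityConfig,
    fsim,
    normalize,
    psnr,
    render_all_views,
    rmse,
    simulate_defacing,
    similarity_features,
    ssim,
)
from _fsim_reference import reference_fsim


def structured_image(rng, n=64):
    """Smooth random field with edges — structured enough for FSIM/SSIM."""
    base = gaussian_filter(rng.random((n, n)), 3.0)
    base += 0.3 * (np.indices((n, n)).sum(axis=0) > n)  # a hard edge
    base -= base.min()
    return base / base.max()


class TestRmsePsnr:
    def test_identical_images(self):
        a = np.full((8, 8), 0.3)
        assert rmse(a, a) == 0.0
        assert psnr(a, a) == 100.0

    def test_constant_offset(self):
        a = np.zeros((2, 2))
        b = np.ones((2, 2))
        assert rmse(a, b) == 1.0

    def test_rmse_matches_double_loop(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((4, 4)), rng.random((4, 4))
        total = 0.0
        for i in range(4):
            for j in range(4):
                total += (a[i, j] - b[i, j]) ** 2
        assert abs(rmse(a, b) - np.sqrt(total / 16)) < 1e-12

    def test_psnr_closed_form(self):
        a = np.zeros((10, 10))
        b = np.full((10, 10), 0.1)  # rmse exactly 0.1
        assert psnr(a, b) == pytest.approx(20.0, abs=1e-12)

    def test_psnr_strictly_decreasing_in_rmse(self):
        a = np.zeros((10, 10))
        values = [
            psnr(a, np.full((10, 10), d)) for d in (0.05, 0.1, 0.2, 0.4)
        ]
        assert values == sorted(values, reverse=True)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="differ"):
            rmse(np.zeros((2, 2)), np.zeros((3, 3)))


class TestSsim:
    def test_identical_images(self):
        rng = np.random.default_rng(2)
        a = structured_image(rng)
        assert ssim(a, a) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        a = structured_image(rng)
        b = np.clip(a + rng.normal(0, 0.08, a.shape), 0, 1)
        ref = structural_similarity(
            a, b, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, data_range=1.0,
        )
        assert ssim(a, b) == pytest.approx(ref, abs=1e-6)

    def test_constant_shift_below_one(self):
        rng = np.random.default_rng(3)
        a = 0.4 * structured_image(rng)
        b = a + 0.5
        val = ssim(a, b)
        ref = structural_similarity(
            a, b, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, data_range=1.0,
        )
        assert val < 1.0
        assert val == pytest.approx(ref, abs=1e-6)

    def test_negative_image_near_minus_one(self):
        """Inverting a high-contrast pattern centered on 0.5 flips the
        structure term to -1 while leaving luminance untouched."""
        x, y = np.indices((64, 64))
        a = 0.5 + 0.45 * (2.0 * ((x + y) % 2) - 1.0)  # checkerboard
        b = 1.0 - a
        val = ssim(a, b)
        ref = structural_similarity(
            a, b, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, data_range=1.0,
        )
        assert val == pytest.approx(ref, abs=1e-6)
        assert val < -0.8

    def test_too_small_image_fails(self):
        with pytest.raises(ValueError, match="window"):
            ssim(np.zeros((8, 8)), np.zeros((8, 8)))


class TestFsim:
    def test_identical_images(self):
        rng = np.random.default_rng(4)
        a = structured_image(rng)
        assert fsim(a, a) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_implementation(self, seed):
        rng = np.random.default_rng(10 + seed)
        a = structured_image(rng)
        b = np.clip(a + rng.normal(0, 0.1, a.shape), 0, 1)
        assert fsim(a, b) == pytest.approx(reference_fsim(a, b), abs=1e-3)

    def test_identical_constants_give_one(self):
        a = np.full((64, 64), 0.5)
        assert fsim(a, a) == 1.0

    def test_differing_constants_use_unweighted_mean(self):
        """Two featureless constants carry zero phase congruency everywhere;
        the unweighted-mean fallback evaluates (both similarity terms are 1
        for zero PC and zero gradient) instead of dividing by zero."""
        a = np.full((64, 64), 0.2)
        b = np.full((64, 64), 0.8)
        val = fsim(a, b)
        assert val == 1.0

    def test_too_small_image_fails(self):
        with pytest.raises(ValueError, match="small"):
            fsim(np.zeros((16, 16)), np.zeros((16, 16)))

    def test_face_removal_lowers_fsim(self, quiet_phantom):
        """Removing the whole face must score lower than an intact pair."""
        ph = quiet_phantom
        vol = normalize(ph.volume)
        views = render_all_views(vol, ph.head, 64)
        removal = {f: 1.0 for f in ph.feature_masks}
        defaced = normalize(simulate_defacing(ph, DefaceSimSpec(removal)))
        views_d = render_all_views(defaced, ph.head, 64)
        intact = fsim(views["frontal"], views["frontal"])
        removed = fsim(views["frontal"], views_d["frontal"])
        assert removed < intact == 1.0


class TestBoundsAndSymmetry:
    @pytest.mark.parametrize("seed", range(20))
    def test_bounds_on_random_pairs(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b = rng.random((48, 48)), rng.random((48, 48))
        assert -1.0 <= ssim(a, b) <= 1.0
        assert 0.0 <= fsim(a, b) <= 1.0
        assert rmse(a, b) >= 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(42)
        a = structured_image(rng)
        b = structured_image(rng)
        assert rmse(a, b) == rmse(b, a)
        assert psnr(a, b) == psnr(b, a)
        assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-12)
        assert fsim(a, b) == pytest.approx(fsim(b, a), abs=1e-12)


class TestAggregation:
    def test_identity_viewsets(self, quiet_phantom):
        ph = quiet_phantom
        vol = normalize(ph.volume)
        views = render_all_views(vol, ph.head, 64)
        feats = similarity_features(views, views)
        assert feats.rmse == 0.0
        assert feats.psnr == 100.0
        assert feats.ssim == pytest.approx(1.0, abs=1e-12)
        assert feats.fsim == 1.0

    def test_mean_aggregation_arithmetic(self, quiet_phantom):
        """The aggregate equals the arithmetic mean of the per-view values."""
        ph = quiet_phantom
        vol = normalize(ph.volume)
        views = render_all_views(vol, ph.head, 64)
        defaced = normalize(
            simulate_defacing(ph, DefaceSimSpec({"nose": 1.0}))
        )
        views_d = render_all_views(defaced, ph.head, 64)
        feats = similarity_features(views, views_d)
        per_view = [fsim(a, b) for a, b in zip(views, views_d)]
        assert feats.fsim == pytest.approx(np.mean(per_view), abs=1e-12)

    def test_frontal_only_damage_minimizes_frontal_view(self):
        """Damage carved into the anterior surface of a sphere is invisible
        to profile rays (they hit the lateral surface first), so the frontal
        view carries the lowest similarity."""
        from defaceqc import Mask, Volume

        n = 48
        coords = np.indices((n, n, n), dtype=float)
        c = (n - 1) / 2.0
        sphere = sum((coords[i] - c) ** 2 for i in range(3)) <= (0.4 * n) ** 2
        orig = np.where(sphere, 0.7, 0.0)
        defaced = orig.copy()
        # anterior midline plug: small |x - c|, |z - c|, y near the front
        plug = (
            sphere
            & (np.abs(coords[0] - c) < 0.12 * n)
            & (np.abs(coords[2] - c) < 0.12 * n)
            & (coords[1] > c + 0.25 * n)
        )
        assert plug.any()
        defaced[plug] = 0.0
        views = render_all_views(Volume(orig), Mask(sphere), 64)
        views_d = render_all_views(Volume(defaced), Mask(sphere), 64)
        per_view = {
            a.view.name: fsim(a, b) for a, b in zip(views, views_d)
        }
        assert min(per_view, key=per_view.get) == "frontal"

    def test_view_mismatch_fails(self, quiet_phantom):
        from defaceqc.render import ViewSet

        ph = quiet_phantom
        vol = normalize(ph.volume)
        views = render_all_views(vol, ph.head, 64)
        shuffled = ViewSet(tuple(reversed(views.images)))
        with pytest.raises(ValueError, match="do not match"):
            similarity_features(views, shuffled)
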