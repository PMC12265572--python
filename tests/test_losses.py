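"""Foreground estimation and the three loss terms, against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spotlight3d import (
    DegenerateHistogramError,
    EmptyForegroundError,
    InvalidParameterError,
    SpotlightLossConfig,
    ValidationError,
    dice_loss,
    foreground_mask,
    masked_mse,
    normalize_volume,
    otsu_threshold,
    soft_foreground,
    spotlight_loss,
    tunable_sigmoid,
)
from spotlight3d._autodiff import Tensor


def brute_force_otsu(volume, n_bins=256):
    """Independent oracle: exhaustive inter-class-variance search, plain loops."""
    a = np.asarray(volume, dtype=float).ravel()
    counts, edges = np.histogram(a, bins=n_bins, range=(a.min(), a.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    variances = np.full(n_bins - 1, -np.inf)
    for c in range(n_bins - 1):
        w0 = counts[: c + 1].sum()
        w1 = counts[c + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: c + 1] * centers[: c + 1]).sum() / w0
        mu1 = (counts[c + 1 :] * centers[c + 1 :]).sum() / w1
        variances[c] = w0 * w1 * (mu0 - mu1) ** 2
    # lowest cut among (numerically) tied maximizers
    best = variances.max()
    best_cut = int(np.flatnonzero(variances >= best - 1e-9 * abs(best))[0])
    return edges[best_cut + 1]


class TestOtsu:
    def test_two_class_volume_separates_exactly(self):
        vol = np.zeros((10, 10, 10))
        vol.ravel()[:100] = 1.0
        t = otsu_threshold(vol)
        assert 0.0 < t <= 1.0
        mask = foreground_mask(vol, t).mask
        np.testing.assert_array_equal(mask.astype(bool), vol == 1.0)

    def test_constant_volume_raises(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(np.full((4, 4, 4), 0.5))

    def test_non_finite_rejected(self):
        vol = np.zeros((3, 3, 3))
        vol[0, 0, 0] = np.nan
        with pytest.raises(ValidationError):
            otsu_threshold(vol)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_search_on_random_volumes(self, seed):
        rng = np.random.default_rng(seed)
        # mixture so the histogram is genuinely bimodal sometimes, flat others
        vol = np.where(
            rng.uniform(size=(16, 16, 16)) < 0.2,
            rng.normal(0.8, 0.05, size=(16, 16, 16)),
            rng.normal(0.2, 0.1, size=(16, 16, 16)),
        )
        assert otsu_threshold(vol) == pytest.approx(brute_force_otsu(vol), abs=0)

    def test_agrees_with_skimage_to_one_bin(self):
        # independent cross-check: same variance objective, different tie/return
        # conventions, so agreement is to within one histogram bin width
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(3)
        vol = np.concatenate([rng.normal(0.2, 0.05, 2000), rng.normal(0.7, 0.1, 500)])
        bin_width = (vol.max() - vol.min()) / 256
        assert abs(otsu_threshold(vol.reshape(10, 10, 25)) - threshold_otsu(vol)) <= bin_width


class TestForegroundMask:
    def test_direct_comparison(self):
        m = foreground_mask(np.array([[[0.2, 0.8]]]), 0.5)
        np.testing.assert_array_equal(m.mask, [[[0, 1]]])
        assert m.threshold == 0.5

    def test_threshold_below_minimum_gives_all_ones(self):
        m = foreground_mask(np.full((2, 2, 2), 0.4), 0.1)
        assert m.mask.all()

    def test_comparison_is_inclusive_at_the_threshold(self):
        m = foreground_mask(np.array([[[0.5, 0.4999]]]), 0.5)
        np.testing.assert_array_equal(m.mask, [[[1, 0]]])


class TestMaskedMSE:
    def test_identity_gives_zero(self, rng):
        vol = rng.uniform(size=(4, 4, 4))
        mask = np.zeros_like(vol)
        mask[0] = 1
        assert masked_mse(vol, vol, mask) == 0.0

    def test_hand_computed_value(self):
        # M=[0,1]: only the second voxel counts, (2-0)^2 / 1 = 4
        y = np.array([[[1.0, 2.0]]])
        yhat = np.array([[[0.0, 0.0]]])
        m = np.array([[[0.0, 1.0]]])
        assert masked_mse(y, yhat, m) == pytest.approx(4.0, abs=1e-10)

    def test_full_mask_reduces_to_plain_mse(self, rng):
        y, yhat = rng.uniform(size=(5, 5, 5)), rng.uniform(size=(5, 5, 5))
        full = masked_mse(y, yhat, np.ones_like(y))
        assert full == pytest.approx(np.mean((y - yhat) ** 2), rel=1e-12)

    def test_empty_mask_raises_not_zero(self, rng):
        y = rng.uniform(size=(3, 3, 3))
        with pytest.raises(EmptyForegroundError):
            masked_mse(y, y, np.zeros_like(y))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            masked_mse(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)), np.zeros((2, 2, 2)))


class TestTunableSigmoid:
    @pytest.mark.parametrize("k", [-0.99, -0.9, -0.5, 0.0, 0.5])
    def test_fixed_points(self, k):
        assert tunable_sigmoid(0.0, k) == pytest.approx(0.0, abs=1e-12)
        assert tunable_sigmoid(1.0, k) == pytest.approx(1.0, abs=1e-12)
        assert tunable_sigmoid(-1.0, k) == pytest.approx(-1.0, abs=1e-12)

    def test_k_zero_is_identity(self, rng):
        x = rng.uniform(-1, 1, size=50)
        np.testing.assert_allclose(tunable_sigmoid(x, 0.0), x, atol=1e-14)

    @pytest.mark.parametrize("k", [1.0, 1.5, -1.0])
    def test_inadmissible_k_rejected(self, k):
        with pytest.raises(InvalidParameterError):
            tunable_sigmoid(np.array([0.5]), k)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        x=st.floats(-1.0, 1.0),
        k=st.floats(-0.99, 0.99),
    )
    def test_odd_symmetry(self, x, k):
        assert tunable_sigmoid(-x, k) == pytest.approx(-tunable_sigmoid(x, k), abs=1e-10)

    @pytest.mark.parametrize("k", [-0.99, -0.5, 0.0, 0.5, 0.9])
    def test_monotone_nondecreasing_on_domain(self, k):
        x = np.linspace(-1, 1, 401)
        y = tunable_sigmoid(x, k)
        assert np.all(np.diff(y) >= -1e-12)
        assert np.all((y >= -1 - 1e-12) & (y <= 1 + 1e-12))


class TestSoftForeground:
    def test_voxel_at_transition_maps_to_half(self):
        cfg = SpotlightLossConfig(center_policy="otsu_center")
        out = soft_foreground(np.full((1, 1, 1), 0.3), cfg, threshold=0.3)
        assert out[0, 0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_k_zero_is_affine_recentring(self):
        cfg = SpotlightLossConfig(sigmoid_k=0.0, center_policy="otsu_center")
        p = np.array([[[0.0, 0.3, 1.0]]])
        out = soft_foreground(p, cfg, threshold=0.3)
        scale = max(0.3, 0.7)
        expected = (np.clip((p - 0.3) / scale, -1, 1) + 1) / 2
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_sharper_k_approaches_step(self):
        # a voxel 0.1 above the transition approaches soft value 1 as k -> -1
        prev = 0.0
        for k in (-0.9, -0.99, -0.999):
            cfg = SpotlightLossConfig(sigmoid_k=k, center_policy="otsu_center")
            val = soft_foreground(np.full((1, 1, 1), 0.4), cfg, threshold=0.3)[0, 0, 0]
            assert val > prev
            prev = val
        assert prev > 0.98

    def test_direct_policy_fixes_zero_and_one(self):
        cfg = SpotlightLossConfig(center_policy="direct")
        out = soft_foreground(np.array([[[0.0, 1.0]]]), cfg)
        np.testing.assert_allclose(out, [[[0.0, 1.0]]], atol=1e-12)


class TestDiceLoss:
    def test_perfect_overlap_bounded_by_eps_term(self):
        m = np.zeros((4, 4, 4))
        m[:2] = 1
        s = m.sum()
        eps = 1e-3
        val = dice_loss(m.copy(), m, eps)
        assert val == pytest.approx(1 - 2 * s / (2 * s + eps), abs=1e-12)
        assert val <= eps / (2 * s + eps) + 1e-12

    def test_disjoint_support_gives_one(self):
        a = np.zeros((2, 2, 2))
        b = np.zeros((2, 2, 2))
        a[0], b[1] = 1.0, 1.0
        assert dice_loss(a, b, 1e-6) == pytest.approx(1.0, abs=1e-6)

    def test_hand_computed_value(self):
        s = np.array([[[0.5, 0.5]]])
        m = np.array([[[1.0, 0.0]]])
        assert dice_loss(s, m, eps=1.0) == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_value_in_unit_interval(self, rng):
        for _ in range(10):
            s = rng.uniform(size=(3, 3, 3))
            m = (rng.uniform(size=(3, 3, 3)) > 0.5).astype(float)
            assert 0.0 <= dice_loss(s, m, 1e-6) <= 1.0

    def test_vanishes_with_eps_on_exact_match(self):
        m = np.zeros((3, 3, 3))
        m[1] = 1
        vals = [dice_loss(m.copy(), m, eps) for eps in (1e-2, 1e-4, 1e-8)]
        assert vals[0] > vals[1] > vals[2]
        assert vals[-1] < 1e-8


class TestSpotlightLoss:
    @pytest.fixture
    def pair(self, rng):
        tgt = rng.uniform(0, 0.3, size=(8, 8, 8))
        tgt[2:5, 2:5, 2:5] = rng.uniform(0.7, 1.0, size=(3, 3, 3))
        pred = rng.uniform(0, 1, size=(8, 8, 8))
        return tgt, pred

    def test_lambda_one_is_pure_masked_mse(self, pair):
        tgt, pred = pair
        lv = spotlight_loss(tgt, pred, SpotlightLossConfig(lambda_weight=1.0))
        assert lv.value == pytest.approx(lv.components["mmse"], abs=1e-12)

    def test_lambda_zero_is_pure_dice(self, pair):
        tgt, pred = pair
        lv = spotlight_loss(tgt, pred, SpotlightLossConfig(lambda_weight=0.0))
        assert lv.value == pytest.approx(lv.components["dice"], abs=1e-12)

    def test_components_match_standalone_recomputation(self, pair):
        tgt, pred = pair
        cfg = SpotlightLossConfig(lambda_weight=0.5)
        lv = spotlight_loss(tgt, pred, cfg)

        thr = otsu_threshold(tgt)
        m = foreground_mask(tgt, thr)
        mmse = masked_mse(tgt, pred, m)
        dice = dice_loss(soft_foreground(pred, cfg, thr), m, cfg.dice_eps)
        assert lv.components["mmse"] == pytest.approx(mmse, abs=1e-12)
        assert lv.components["dice"] == pytest.approx(dice, abs=1e-12)
        assert lv.value == pytest.approx(0.5 * mmse + 0.5 * dice, abs=1e-10)

    def test_self_prediction_has_zero_mmse_and_recorded_dice_residual(self, pair):
        tgt, _ = pair
        cfg = SpotlightLossConfig()
        lv = spotlight_loss(tgt, tgt.copy(), cfg)
        assert lv.components["mmse"] == 0.0
        # dice does not vanish: it equals the soft-threshold residual of the
        # target itself, recomputed here independently
        thr = otsu_threshold(tgt)
        residual = dice_loss(
            soft_foreground(tgt, cfg, thr), foreground_mask(tgt, thr), cfg.dice_eps
        )
        assert lv.components["dice"] == pytest.approx(residual, abs=1e-12)
        assert 0.0 <= lv.components["dice"] < 1.0

    def test_degenerate_target_names_the_target(self):
        with pytest.raises(DegenerateHistogramError, match="target"):
            spotlight_loss(np.full((3, 3, 3), 0.2), np.zeros((3, 3, 3)))


class TestLossGradients:
    """Autodiff gradients vs central finite differences on 4-cube volumes."""

    @staticmethod
    def _check(loss_np, loss_t, pred, rtol=1e-4):
        t = Tensor(pred, requires_grad=True)
        loss_t(t).backward()
        g = t.grad
        rng = np.random.default_rng(0)
        flat = rng.choice(pred.size, size=8, replace=False)
        eps = 1e-6
        for j in flat:
            i = np.unravel_index(j, pred.shape)
            p1, p2 = pred.copy(), pred.copy()
            p1[i] += eps
            p2[i] -= eps
            fd = (loss_np(p1) - loss_np(p2)) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=rtol, abs=1e-9)

    def test_masked_mse_gradient(self, rng):
        tgt = rng.uniform(size=(4, 4, 4))
        mask = (rng.uniform(size=(4, 4, 4)) > 0.4).astype(float)
        pred = rng.uniform(size=(4, 4, 4))
        self._check(
            lambda p: masked_mse(tgt, p, mask),
            lambda t: masked_mse(tgt, t, mask),
            pred,
        )

    def test_dice_gradient_through_soft_threshold(self, rng):
        cfg = SpotlightLossConfig(sigmoid_k=-0.7)
        mask = (rng.uniform(size=(4, 4, 4)) > 0.5).astype(float)
        pred = rng.uniform(0.05, 0.95, size=(4, 4, 4))
        self._check(
            lambda p: dice_loss(soft_foreground(p, cfg, 0.4), mask, cfg.dice_eps),
            lambda t: dice_loss(soft_foreground(t, cfg, 0.4), mask, cfg.dice_eps),
            pred,
        )

    def test_spotlight_total_gradient(self, rng):
        tgt = rng.uniform(0, 0.3, size=(4, 4, 4))
        tgt[1:3, 1:3, 1:3] = 0.9
        pred = rng.uniform(0.05, 0.95, size=(4, 4, 4))
        cfg = SpotlightLossConfig()
        self._check(
            lambda p: spotlight_loss(tgt, p, cfg).value,
            lambda t: spotlight_loss(tgt, t, cfg).tensor,
            pred,
        )


def test_normalize_volume_round_trip(rng):
    vol = rng.uniform(5, 9, size=(4, 4, 4))
    normed, (lo, hi) = normalize_volume(vol)
    assert normed.min() == 0.0 and normed.max() == 1.0
    np.testing.assert_allclose(normed * (hi - lo) + lo, vol, rtol=1e-12)
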