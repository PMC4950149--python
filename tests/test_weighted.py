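import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hsunmix import (
    FSC3Params,
    WeightParams,
    component_gain_test,
    exclusion_threshold,
    make_cell_phantom,
    select_components,
    update_weights,
    weighted_fsc3,
)


class TestUpdateWeights:
    def test_uniform_error_is_fixed_point(self):
        # E_Sp equal everywhere with zero concentration error leaves w unchanged
        w = np.array([0.5, 1.0, 2.0])
        E_Sp = np.full(3, 0.7)
        for alpha, beta in [(0.0, 0.0), (0.3, 1.0), (0.9, 0.5)]:
            np.testing.assert_allclose(
                update_weights(w, E_Sp, np.zeros(3), alpha, beta), w
            )

    def test_undamped_reduction(self):
        # α=0, β=0 reduces to w·E_Sp/mean(E_Sp)
        w = np.array([1.0, 1.0, 1.0, 1.0])
        E_Sp = np.array([2.0, 1.0, 0.5, 0.5])
        out = update_weights(w, E_Sp, np.zeros(4), 0.0, 0.0)
        np.testing.assert_allclose(out, E_Sp / E_Sp.mean())

    def test_closed_form_value(self):
        # ratio 2, α=0.3, β=1, |E_Cp|=0.5 → e^{−0.5}·2^{0.7}
        E_Sp = np.array([2.0, 1.0, 0.0])  # mean = 1
        E_Cp = np.array([0.5, 0.0, 0.0])
        out = update_weights(np.ones(3), E_Sp, E_Cp, 0.3, 1.0)
        assert out[0] == pytest.approx(np.exp(-0.5) * 2**0.7)

    def test_perfect_fit_returns_unchanged(self):
        w = np.array([1.0, 3.0])
        np.testing.assert_array_equal(
            update_weights(w, np.zeros(2), np.zeros(2), 0.3, 0.5), w
        )

    def test_zero_error_points_floored_not_zeroed(self):
        out = update_weights(np.ones(3), np.array([2.0, 1.0, 0.0]), np.zeros(3), 0.0, 0.0)
        assert out[2] > 0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.integers(0, 2**31 - 1),
        st.floats(0.0, 0.99),
        st.floats(0.0, 1.0),
    )
    def test_positivity_preserved(self, seed, alpha, beta):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.1, 10, 20)
        out = update_weights(w, rng.uniform(0, 2, 20), rng.normal(0, 0.5, 20), alpha, beta)
        assert np.all(out > 0)


class TestExclusionThreshold:
    def test_fourth_root_scaling(self):
        assert exclusion_threshold(10.0, 10000) == pytest.approx(100.0)
        assert exclusion_threshold(1.0, 1) == pytest.approx(1.0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            exclusion_threshold(0.0, 10)


class TestComponentGainTest:
    def test_zero_sigma_any_decrease(self):
        assert component_gain_test(1.0, 0.99, 0.0, 0.5, 4)

    def test_arithmetic_oracle(self):
        # per-point RMS improves 1.0 → 0.9, σ=0.1, η=0.5: 0.1 > 0.05
        P = 16
        assert component_gain_test(1.0 * np.sqrt(P), 0.9 * np.sqrt(P), 0.1, 0.5, P)
        # and fails for η=1.5: 0.1 < 0.15
        assert not component_gain_test(1.0 * np.sqrt(P), 0.9 * np.sqrt(P), 0.1, 1.5, P)

    def test_equal_norms_never_pass(self):
        assert not component_gain_test(1.0, 1.0, 0.3, 0.5, 9)
        assert not component_gain_test(1.0, 1.0, 1e-12, 0.5, 9)


class TestWeightedFSC3:
    def test_homogeneous_phantom_weights_stay_unity(self, small_axis):
        # every pixel carries the same spectrum, so E_Sp is uniform and
        # the weight update sits exactly at its fixed point
        from hsunmix import make_spectra

        s = make_spectra(1, small_axis, seed=3)[:, 0]
        D = np.tile(s, (100, 1))
        params = FSC3Params(k=1, n=3, tau_L=1e-3, seed=0)
        res = weighted_fsc3(D, params, WeightParams(max_weight_iters=5))
        np.testing.assert_allclose(res.weights, 1.0, rtol=1e-10)
        assert not res.excluded.any()

    def test_garbage_pixel_excluded_with_small_gamma(self, lowrank_phantom, small_axis):
        ph = lowrank_phantom(ny=12, nx=12, k=2, noise_sigma=0.005, seed=6, axis=small_axis)
        D = ph.matrix.copy()
        rng = np.random.default_rng(0)
        D[17] = rng.uniform(0, 1, D.shape[1])  # one pixel of pure garbage
        params = FSC3Params(k=2, n=4, tau_L=1e-2, seed=1)
        wp = WeightParams(alpha=0.0, gamma=0.9, max_weight_iters=8)
        res = weighted_fsc3(D, params, wp)
        assert res.excluded[17]
        # excluded pixels still receive concentrations by projection
        assert np.isfinite(res.C[17]).all() and res.C[17].min() >= 0

    def test_spatial_permutation_stability(self, lowrank_phantom, small_axis):
        # relabeling pixels must not change what is recovered; the random
        # initialization is tied to row order, so agreement is up to the
        # multi-start optimization scatter, not bitwise
        ph = lowrank_phantom(ny=8, nx=8, k=2, noise_sigma=0.01, seed=8, axis=small_axis)
        D = ph.matrix
        perm = np.random.default_rng(5).permutation(D.shape[0])
        params = FSC3Params(k=2, n=3, tau_L=1e-3, seed=3)
        wp = WeightParams(max_weight_iters=4)
        a = weighted_fsc3(D, params, wp)
        b = weighted_fsc3(D[perm], params, wp)
        scale = np.abs(a.S).max()
        best = min(np.abs(b.S[:, list(p)] - a.S).max() for p in ([0, 1], [1, 0]))
        assert best <= 0.05 * scale
        np.testing.assert_array_equal(b.excluded, a.excluded[perm])

    def test_deterministic(self, lowrank_phantom, small_axis):
        ph = lowrank_phantom(ny=8, nx=8, k=2, noise_sigma=0.01, seed=8, axis=small_axis)
        params = FSC3Params(k=2, n=3, tau_L=1e-2, seed=3)
        a = weighted_fsc3(ph.matrix, params, WeightParams(max_weight_iters=4))
        b = weighted_fsc3(ph.matrix, params, WeightParams(max_weight_iters=4))
        np.testing.assert_array_equal(a.C, b.C)
        np.testing.assert_array_equal(a.weights, b.weights)


class TestSelectComponents:
    def test_recovers_true_component_count(self):
        ph = make_cell_phantom(ny=30, nx=30, k=3, noise_sigma=0.0, seed=3)
        params = FSC3Params(k=1, n=5, seed=0)
        k, res = select_components(
            ph.matrix, params, WeightParams(max_weight_iters=6), eta=0.5
        )
        assert k == 3
        assert res.k == 3
        assert res.history.k_final == 3

    def test_pure_noise_yields_single_component(self):
        rng = np.random.default_rng(0)
        D = np.abs(rng.normal(1.0, 0.1, size=(400, 40)))
        params = FSC3Params(k=1, n=5, seed=0)
        k, _ = select_components(D, params, WeightParams(max_weight_iters=6), eta=0.5)
        assert k == 1
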