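import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hsunmix import (
    FSC3Params,
    multi_start_fsc3,
    nmf,
    scale_to_volume_fraction,
    spectral_error_map,
)
from conftest import matched_spectral_rms


def _random_factors(P, S, k, seed):
    rng = np.random.default_rng(seed)
    return rng.uniform(0.1, 1.0, (P, k)), rng.uniform(0.1, 1.0, (S, k))


class TestNMF:
    def test_exact_factorization_recovered_from_near_truth(self):
        C0, S0 = _random_factors(40, 15, 3, 0)
        D = C0 @ S0.T
        rng = np.random.default_rng(1)
        C, S, _, trace = nmf(
            D, 3, C0 * rng.uniform(0.9, 1.1, C0.shape), S0, tol=1e-8, max_iter=5000
        )
        assert np.linalg.norm(D - C @ S.T) / np.linalg.norm(D) < 1e-6

    def test_rank_one_recovery(self):
        rng = np.random.default_rng(2)
        c, s = rng.uniform(0.1, 1, 30), rng.uniform(0.1, 1, 12)
        D = np.outer(c, s)
        C, S, _, _ = nmf(D, 1, np.ones((30, 1)), np.ones((12, 1)), tol=1e-9, max_iter=5000)
        assert np.linalg.norm(D - C @ S.T) / np.linalg.norm(D) < 1e-8

    def test_row_weighting_equals_prescaled_data(self):
        # fitting with row weights w must equal fitting diag(w)·D and
        # unscaling the concentration rows
        rng = np.random.default_rng(3)
        D = rng.uniform(0.1, 1, (25, 10))
        w = rng.uniform(0.5, 2.0, 25)
        C0, S0 = _random_factors(25, 10, 2, 4)
        Cw, Sw, _, _ = nmf(D, 2, C0, S0, tol=1e-6, max_iter=2000, row_weights=w)
        Cs, Ss, _, _ = nmf(D * w[:, None], 2, C0 * w[:, None], S0, tol=1e-6, max_iter=2000)
        np.testing.assert_allclose(Cw, Cs / w[:, None], rtol=1e-10)
        np.testing.assert_allclose(Sw, Ss, rtol=1e-10)

    def test_residual_monotone_nonincreasing(self):
        rng = np.random.default_rng(5)
        D = rng.uniform(0.1, 1, (30, 12))
        C0, S0 = _random_factors(30, 12, 3, 6)
        _, _, _, trace = nmf(D, 3, C0, S0, tol=1e-6, max_iter=500)
        r = trace["residual_norm"]
        assert np.all(np.diff(r) <= 1e-10 * r[0])

    def test_matches_sklearn_fit_quality(self):
        # independent multiplicative-update implementation as oracle
        from sklearn.decomposition import NMF as SkNMF

        rng = np.random.default_rng(7)
        D = rng.uniform(0.0, 1.0, (40, 15))
        C0, S0 = _random_factors(40, 15, 3, 8)
        C, S, _, _ = nmf(D, 3, C0, S0, tol=1e-7, max_iter=5000)
        ours = np.linalg.norm(D - C @ S.T)
        sk = SkNMF(
            n_components=3, solver="mu", init="random", random_state=0,
            max_iter=5000, tol=1e-9,
        )
        W = sk.fit_transform(D)
        theirs = np.linalg.norm(D - W @ sk.components_)
        assert ours <= 1.02 * theirs

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="zero"):
            nmf(np.zeros((4, 4)), 2, np.ones((4, 2)), np.ones((4, 2)), 0.1)
        with pytest.raises(ValueError, match="k="):
            nmf(np.ones((3, 3)), 5, np.ones((3, 5)), np.ones((3, 5)), 0.1)


class TestSpectralErrorMap:
    def test_zero_residual(self):
        D = np.ones((5, 4))
        np.testing.assert_array_equal(spectral_error_map(np.zeros_like(D), D), np.zeros(5))

    def test_single_entry_formula(self):
        D = np.full((8, 6), 2.0)
        E = np.zeros_like(D)
        E[3, 2] = 0.7
        expected = np.sqrt(8) * 0.7 / np.linalg.norm(D)
        es = spectral_error_map(E, D)
        assert es[3] == pytest.approx(expected)
        assert np.all(es[np.arange(8) != 3] == 0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rms_identity(self, seed):
        # RMS over points of E_Sp equals ‖E‖_F/‖D‖_F
        rng = np.random.default_rng(seed)
        D = rng.uniform(0.1, 1, (12, 7))
        E = rng.normal(size=(12, 7))
        es = spectral_error_map(E, D)
        assert np.sqrt(np.mean(es**2)) == pytest.approx(
            np.linalg.norm(E) / np.linalg.norm(D)
        )

    def test_zero_data_rejected(self):
        with pytest.raises(ValueError):
            spectral_error_map(np.ones((3, 3)), np.zeros((3, 3)))


class TestVolumeFractionScaling:
    def test_fixed_point_when_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        C = rng.uniform(0.1, 1, (20, 3))
        C /= C.sum(1, keepdims=True)
        S = rng.uniform(size=(8, 3))
        _, _, a = scale_to_volume_fraction(C, S)
        np.testing.assert_allclose(a, 1.0, atol=1e-10)

    def test_single_component_closed_form(self):
        C = np.full((10, 1), 2.0)
        S = np.ones((5, 1))
        C_s, S_s, a = scale_to_volume_fraction(C, S)
        assert a[0] == pytest.approx(0.5)  # Σc/Σc² = 20/40
        np.testing.assert_allclose(C_s.sum(1), 1.0)

    def test_product_invariant(self):
        rng = np.random.default_rng(1)
        C = rng.uniform(0.1, 1, (15, 3))
        S = rng.uniform(0.1, 1, (9, 3))
        C_s, S_s, a = scale_to_volume_fraction(C, S)
        assert np.all(a > 0)
        np.testing.assert_allclose(C_s @ S_s.T, C @ S.T, atol=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            scale_to_volume_fraction(np.zeros((4, 2)), np.ones((3, 2)))


class TestMultiStart:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        D = rng.uniform(0.1, 1, (30, 10))
        params = FSC3Params(k=2, n=3, seed=42)
        a = multi_start_fsc3(D, params)
        b = multi_start_fsc3(D, params)
        np.testing.assert_array_equal(a.C, b.C)
        np.testing.assert_array_equal(a.S, b.S)
        assert a.final_error == b.final_error

    def test_noiseless_phantom_recovers_truth(self, small_axis):
        # separable mixing (both substances occur nearly pure somewhere),
        # so the factorization is identifiable up to permutation/scale
        from hsunmix import make_spectra

        truth_S = make_spectra(2, small_axis, seed=12)
        c1 = np.linspace(0.0, 1.0, 200)
        C = np.column_stack([c1, 1.0 - c1])
        D = C @ truth_S.T
        params = FSC3Params(k=2, n=8, tau_H=0.05, tau_L=1e-4, seed=0)
        res = multi_start_fsc3(D, params)
        best = 0.0
        for perm in ([0, 1], [1, 0]):
            cos = min(
                np.dot(res.S[:, perm[j]], truth_S[:, j])
                / (np.linalg.norm(res.S[:, perm[j]]) * np.linalg.norm(truth_S[:, j]))
                for j in range(2)
            )
            best = max(best, cos)
        assert best > 0.999

    def test_error_fields_recomputable(self):
        rng = np.random.default_rng(10)
        D = rng.uniform(0.1, 1, (20, 8))
        res = multi_start_fsc3(D, FSC3Params(k=2, n=2, seed=1))
        np.testing.assert_allclose(res.E, D - res.C @ res.S.T, atol=1e-12)
        np.testing.assert_allclose(res.E_Cp, res.C.sum(1) - 1.0, atol=1e-12)
        np.testing.assert_allclose(res.E_Sp, spectral_error_map(res.E, D), atol=1e-12)
        assert res.C.min() >= 0 and res.S.min() >= 0

    def test_spectral_rms_grows_with_noise(self, lowrank_phantom, small_axis):
        # recovered-spectrum deviation increases across noise levels
        devs = []
        for sigma in (0.0, 0.02, 0.08):
            ph = lowrank_phantom(
                ny=15, nx=15, k=2, noise_sigma=sigma, seed=20, axis=small_axis
            )
            res = multi_start_fsc3(ph.matrix, FSC3Params(k=2, n=6, tau_L=1e-3, seed=2))
            devs.append(
                matched_spectral_rms(res.S, [ph.truth_S[:, 0], ph.truth_S[:, 1]])
            )
        assert devs[0] < devs[1] < devs[2]
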