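"""Compression-matrix construction, round trips, and compressed fitting."""

import warnings

import numpy as np
import pytest

from fieldcomp import (HarmonicIndexing, KCoefficients, PhaseData, ProbeArray,
                       build_compression, compress_k, compressed_probing,
                       decompress_k, evaluate_basis, fit_compressed, fit_k,
                       synthesize_phase)
from fieldcomp.fitting import IllPosedFitError


def _k(max_order, arr, rng=None):
    ix = HarmonicIndexing(max_order)
    return KCoefficients(k=arr, indexing=ix, time=np.arange(arr.shape[1]) * 1e-5)


class TestBuildCompression:
    def test_rank_one_calibration(self, rng):
        """A single spatial mode times a time-course yields one singular
        value, and the retained vector is parallel to the Γ-weighted mode."""
        ix = HarmonicIndexing(3)
        mode = rng.normal(size=12)
        tc = rng.normal(size=40)
        kk = np.zeros((16, 40))
        kk[4:] = np.outer(mode, tc)
        model = build_compression(_k(3, kk), L=1)
        sv = model.singular_values
        assert sv[0] > 1e-10 and np.all(sv[1:] < 1e-10 * sv[0])
        gamma_high = 0.1 ** ix.orders[4:].astype(float)
        weighted = gamma_high * mode
        weighted /= np.linalg.norm(weighted)
        assert abs(abs(weighted @ model.C_high[:, 0]) - 1.0) < 1e-10

    def test_gamma_base_one_is_plain_svd(self, rng):
        kk = rng.normal(size=(16, 50))
        model = build_compression(_k(3, kk), L=5, gamma_base=1.0)
        U, s, _ = np.linalg.svd(kk[4:], full_matrices=False)
        for j in range(5):
            assert abs(abs(U[:, j] @ model.C_high[:, j]) - 1.0) < 1e-10
        np.testing.assert_allclose(model.singular_values, s)

    def test_rank_bound(self, rng):
        kk = rng.normal(size=(36, 20))  # Nt=20 < Nb-4=32
        with pytest.warns(UserWarning):
            model = build_compression(_k(5, kk), L=5)
        nonzero = np.sum(model.singular_values > 1e-12 * model.singular_values[0])
        assert nonzero <= min(32, 20)

    def test_L_validation_and_clamp(self, rng):
        kk = rng.normal(size=(16, 50))
        with pytest.raises(ValueError):
            build_compression(_k(3, kk), L=13)  # > Nb-4
        low_rank = np.zeros((16, 50))
        low_rank[4:] = np.outer(rng.normal(size=12), rng.normal(size=50))
        with pytest.warns(UserWarning, match="rank"):
            model = build_compression(_k(3, low_rank), L=5)
        assert model.L == 1

    def test_deterministic_sign_convention(self, rng):
        kk = rng.normal(size=(16, 50))
        m1 = build_compression(_k(3, kk), L=6)
        m2 = build_compression(_k(3, -kk[:, ::-1]), L=6)  # same row space
        np.testing.assert_allclose(np.abs(m1.C_high), np.abs(m2.C_high), atol=1e-10)
        piv = np.argmax(np.abs(m1.C_high), axis=0)
        assert np.all(m1.C_high[piv, np.arange(6)] > 0)


class TestRoundTrips:
    @pytest.fixture
    def model(self, rng):
        return build_compression(_k(3, rng.normal(size=(16, 50))), L=6)

    def test_orthonormal_columns(self, model):
        C = model.C
        np.testing.assert_allclose(C.T @ C, np.eye(model.n_compressed), atol=1e-10)
        np.testing.assert_array_equal(C[:4, :4], np.eye(4))

    def test_low_orders_pass_through(self, model, rng):
        kk = rng.normal(size=(16, 30))
        k_hat = compress_k(_k(3, kk), model)
        np.testing.assert_allclose(k_hat[:4], kk[:4], atol=1e-12)

    def test_zero_high_block_compresses_to_low_only(self, model, rng):
        kk = np.zeros((16, 10))
        kk[:4] = rng.normal(size=(4, 10))
        k_hat = compress_k(_k(3, kk), model)
        np.testing.assert_allclose(k_hat[4:], 0.0, atol=1e-14)

    def test_full_L_round_trip_exact(self, rng):
        kk = rng.normal(size=(16, 50))
        model = build_compression(_k(3, kk), L=12)
        back = decompress_k(compress_k(_k(3, kk), model), model)
        np.testing.assert_allclose(back.k, kk, atol=1e-10)

    def test_truncated_round_trip_is_projection(self, model, rng):
        """decompress∘compress equals the explicit projector Γ⁻¹C CᵀΓ."""
        kk = rng.normal(size=(16, 25))
        back = decompress_k(compress_k(_k(3, kk), model), model).k
        G = np.diag(model.gamma)
        proj = np.linalg.inv(G) @ model.C @ model.C.T @ G
        np.testing.assert_allclose(back, proj @ kk, atol=1e-10)
        np.testing.assert_allclose(proj @ proj, proj, atol=1e-8)

    def test_compress_of_decompress_is_identity(self, model, rng):
        k_hat = rng.normal(size=(model.n_compressed, 20))
        k = decompress_k(k_hat, model)
        np.testing.assert_allclose(compress_k(k, model), k_hat, atol=1e-10)

    def test_unit_compressed_vector_decompresses_to_column(self, model):
        j = 6
        e = np.zeros((model.n_compressed, 1))
        e[j] = 1.0
        k = decompress_k(e, model)
        np.testing.assert_allclose(k.k[:, 0], model.C[:, j] / model.gamma, atol=1e-12)

    def test_variance_captured_monotone_in_L(self, rng):
        kk = rng.normal(size=(16, 50))
        model = build_compression(_k(3, kk), L=12)
        sv2 = model.singular_values ** 2
        frac = np.cumsum(sv2) / np.sum(sv2)
        assert np.all(np.diff(frac) >= -1e-15)


class TestCompressedProbing:
    def test_leading_columns_equal_P(self, rng, model_probes=20):
        probes = ProbeArray(rng.uniform(-0.1, 0.1, (model_probes, 3)))
        P = evaluate_basis(probes, 3)
        model = build_compression(_k(3, rng.normal(size=(16, 50))), L=5)
        P_hat = compressed_probing(P, model)
        np.testing.assert_allclose(P_hat[:, :4], P.values[:, :4], atol=1e-12)

    def test_probe_at_origin(self, rng):
        P = evaluate_basis(ProbeArray(np.zeros((1, 3))), 3)
        model = build_compression(_k(3, rng.normal(size=(16, 50))), L=5)
        P_hat = compressed_probing(P, model)
        np.testing.assert_allclose(P_hat[0], np.eye(9)[0], atol=1e-14)

    def test_matches_explicit_triple_product(self, rng):
        probes = ProbeArray(rng.uniform(-0.1, 0.1, (3, 3)))
        P = evaluate_basis(probes, 2)
        model = build_compression(_k(2, rng.normal(size=(9, 30))), L=3)
        expected = P.values @ np.linalg.inv(np.diag(model.gamma)) @ model.C
        np.testing.assert_allclose(compressed_probing(P, model), expected, atol=1e-12)

    def test_full_L_reproduces_forward_model(self, rng):
        probes = ProbeArray(rng.uniform(-0.1, 0.1, (25, 3)))
        P = evaluate_basis(probes, 3)
        kk = rng.normal(size=(16, 40))
        model = build_compression(_k(3, kk), L=12)
        k = _k(3, kk)
        phi_hat = compressed_probing(P, model) @ compress_k(k, model)
        np.testing.assert_allclose(phi_hat, P.values @ kk, rtol=1e-9, atol=1e-10)

    def test_order_mismatch_rejected(self, rng):
        P = evaluate_basis(ProbeArray(rng.uniform(-0.1, 0.1, (5, 3))), 2)
        model = build_compression(_k(3, rng.normal(size=(16, 50))), L=5)
        with pytest.raises(ValueError):
            compressed_probing(P, model)


class TestFitCompressed:
    def test_exact_recovery_in_retained_subspace(self, rng):
        """Noiseless phase from subspace-resident k is recovered exactly
        with barely more probes than compressed unknowns."""
        kk_cal = rng.normal(size=(36, 80))
        model = build_compression(_k(5, kk_cal), L=5)
        k_hat_true = rng.normal(size=(9, 30))
        k_true = decompress_k(k_hat_true, model)
        probes = ProbeArray(rng.uniform(-0.12, 0.12, (13, 3)))  # L+4+4
        P = evaluate_basis(probes, 5)
        phase = synthesize_phase(P, k_true)
        k_hat, k = fit_compressed(phase, P, model)
        np.testing.assert_allclose(k.k, k_true.k, rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(k_hat, k_hat_true, rtol=1e-8, atol=1e-10)

    def test_full_L_equals_conventional_fit(self, rng):
        kk_cal = rng.normal(size=(16, 60))
        model = build_compression(_k(3, kk_cal), L=12)
        probes = ProbeArray(rng.uniform(-0.12, 0.12, (24, 3)))
        P = evaluate_basis(probes, 3)
        phi = rng.normal(size=(24, 30))
        phase = PhaseData(phi=phi, time=np.arange(30.0))
        _, k_comp = fit_compressed(phase, P, model)
        k_conv = fit_k(phase, P)
        np.testing.assert_allclose(k_comp.k, k_conv.k, rtol=1e-8, atol=1e-8)

    def test_too_few_probes_explains_max_L(self, rng):
        model = build_compression(_k(5, rng.normal(size=(36, 60))), L=13)
        probes = ProbeArray(rng.uniform(-0.1, 0.1, (16, 3)))
        P = evaluate_basis(probes, 5)
        phase = PhaseData(phi=np.zeros((16, 4)), time=np.arange(4.0))
        with pytest.raises(IllPosedFitError, match="maximum admissible L"):
            fit_compressed(phase, P, model)

    def test_residual_monotone_in_L(self, rng):
        """Nested subspaces: the fit residual cannot grow with L."""
        kk_cal = rng.normal(size=(16, 60))
        probes = ProbeArray(rng.uniform(-0.12, 0.12, (30, 3)))
        P = evaluate_basis(probes, 3)
        phi = rng.normal(size=(30, 20))
        phase = PhaseData(phi=phi, time=np.arange(20.0))
        model_full = build_compression(_k(3, kk_cal), L=12)
        res = []
        for L in range(1, 13):
            _, k = fit_compressed(phase, P, model_full.truncated(L))
            res.append(np.linalg.norm(phi - P.values @ k.k))
        assert np.all(np.diff(res) <= 1e-8)
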