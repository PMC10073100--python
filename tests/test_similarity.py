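"""Kernel constants, symmetrization algebra and the two loss forms."""

import numpy as np
import pytest

from deepvis import ManifoldSpec
from deepvis.geometry import project_from_tangent
from deepvis.similarity import (SimilarityConfig, gsp_loss,
                                normalizing_constant, structure_similarity,
                                symmetrize, t_kernel,
                                visualization_similarity)


class TestNormalizingConstant:
    def test_nu_one_closed_form(self):
        # Γ(1)=1, Γ(1/2)=√π  ⇒  C₁ = 2π/π² = 2/π
        assert normalizing_constant(1.0) == pytest.approx(2.0 / np.pi,
                                                          rel=1e-12)

    def test_nu_100_value_and_limit(self):
        # independent oracle: Γ(50.5) = √π·∏_{k=0}^{49}(k+½) exactly
        import math
        lg505 = 0.5 * math.log(math.pi) + sum(
            math.log(0.5 + k) for k in range(50))
        expect = 2 * math.pi * math.exp(
            2 * (lg505 - 0.5 * math.log(100 * math.pi) - math.lgamma(50)))
        assert expect == pytest.approx(0.9950126, abs=1e-6)
        assert normalizing_constant(100.0) == pytest.approx(expect, rel=1e-12)
        assert normalizing_constant(1e8) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("nu", [1e-3, 1.0, 10.0, 100.0])
    def test_in_unit_interval(self, nu):
        assert 0.0 < normalizing_constant(nu) < 1.0

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            normalizing_constant(0.0)


class TestTKernel:
    def test_zero_distance_gives_cnu(self):
        for nu in (0.005, 1.0, 100.0):
            assert t_kernel(0.0, nu) == pytest.approx(
                normalizing_constant(nu))

    def test_nu1_at_one(self):
        # (2/π)·(1+1)^−2 = 1/(2π)
        assert t_kernel(1.0, 1.0) == pytest.approx(1.0 / (2 * np.pi),
                                                   rel=1e-12)

    def test_strictly_decreasing(self, rng):
        D = np.sort(rng.random(50) * 10)
        for nu in (0.005, 100.0):
            k = t_kernel(D, nu)
            assert np.all(np.diff(k) < 0)


class TestSymmetrize:
    @pytest.mark.parametrize("u, v, expect",
                             [(1.0, 1.0, 0.0), (0.5, 0.5, 0.5),
                              (1.0, 0.0, 1.0), (0.0, 0.0, 0.0)])
    def test_values(self, u, v, expect):
        assert symmetrize(u, v) == pytest.approx(expect)

    def test_symmetric_and_bounded(self, rng):
        u, v = rng.random(1000), rng.random(1000)
        s = symmetrize(u, v)
        np.testing.assert_allclose(s, symmetrize(v, u))
        assert np.all((s >= 0.0) & (s <= 1.0))


class TestStructureSimilarity:
    def _setup(self, rng, gamma):
        cfg = SimilarityConfig(gamma=gamma)
        Z = rng.normal(size=(6, 3))
        pairing = np.array([0, 1, 2, 0, 1, 2])
        return cfg, Z, pairing

    def test_gamma_contracts_only_anchor_pairs(self, rng):
        cfg, Z, pairing = self._setup(rng, gamma=10.0)
        cfg1 = SimilarityConfig(gamma=1.0)
        U_g = np.asarray(structure_similarity(Z, pairing, cfg, n_original=3))
        U_1 = np.asarray(structure_similarity(Z, pairing, cfg1, n_original=3))
        anchors = np.zeros((6, 6), dtype=bool)
        for r, s in [(3, 0), (4, 1), (5, 2)]:
            anchors[r, s] = anchors[s, r] = True
        # only anchor pairs are affected, exactly by the D/γ kernel value
        np.testing.assert_allclose(U_g[~anchors], U_1[~anchors])
        from deepvis.geometry import pairwise_distance_matrix
        D = np.asarray(pairwise_distance_matrix(
            Z, ManifoldSpec("euclidean", latent_dim=3)))
        u = t_kernel(D[3, 0] / 10.0, cfg.nu_structure)
        assert U_g[3, 0] == pytest.approx(symmetrize(u, u), rel=1e-10)
        # the directed similarity always rises under contraction
        assert t_kernel(D[3, 0] / 10.0, cfg.nu_structure) > \
            t_kernel(D[3, 0], cfg.nu_structure)

    def test_gamma_one_is_plain_kernel(self, rng):
        cfg, Z, pairing = self._setup(rng, gamma=1.0)
        from deepvis.geometry import pairwise_distance_matrix
        D = np.asarray(pairwise_distance_matrix(
            Z, ManifoldSpec("euclidean", latent_dim=3)))
        u = t_kernel(D, cfg.nu_structure)
        np.testing.assert_allclose(
            np.asarray(structure_similarity(Z, pairing, cfg, n_original=3)),
            symmetrize(u, u.T), atol=1e-12)

    def test_identical_rows_hit_symmetrized_max(self, rng):
        cfg = SimilarityConfig(gamma=1.0)
        Z = np.vstack([np.ones(3), np.ones(3), rng.normal(size=3)])
        U = np.asarray(structure_similarity(Z, np.arange(3), cfg,
                                            n_original=3))
        c = t_kernel(1e-12, cfg.nu_structure)  # D floored by the clamp
        assert U[0, 1] == pytest.approx(symmetrize(c, c), rel=1e-6)

    def test_rejects_bad_gamma(self):
        with pytest.raises(ValueError):
            SimilarityConfig(gamma=0.0)


class TestVisualizationSimilarity:
    def test_beta_zero_reduces_to_plain_kernel(self, rng):
        spec = ManifoldSpec("poincare")
        Z = np.asarray(project_from_tangent(spec, rng.normal(size=(5, 2))))
        Y = rng.integers(0, 2, (5, 2)).astype(float)
        cfg0 = SimilarityConfig(beta=0.0)
        cfgn = SimilarityConfig(beta=0.0)
        U0 = np.asarray(visualization_similarity(Z, spec, Y, cfg0))
        Un = np.asarray(visualization_similarity(Z, spec, None, cfgn))
        np.testing.assert_allclose(U0, Un)

    def test_same_batch_pairs_unchanged_cross_batch_lower(self, rng):
        spec = ManifoldSpec("euclidean")
        Z = rng.normal(size=(4, 2))
        Y_same = np.tile([1.0, 0.0], (4, 1))
        Y_mix = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        cfg = SimilarityConfig(beta=1.0)
        U_same = np.asarray(visualization_similarity(Z, spec, Y_same, cfg))
        U_nob = np.asarray(visualization_similarity(Z, spec, None,
                                                    SimilarityConfig(beta=0.0)))
        np.testing.assert_allclose(U_same, U_nob, atol=1e-12)
        U_mix = np.asarray(visualization_similarity(Z, spec, Y_mix, cfg))
        assert U_mix[0, 2] < U_same[0, 2]  # cross-batch pair penalized
        np.testing.assert_allclose(U_mix[0, 1], U_same[0, 1])

    def test_entries_symmetric_in_unit_interval(self, rng):
        for kind in ("euclidean", "poincare", "lorentz"):
            spec = ManifoldSpec(kind)
            Z = np.asarray(project_from_tangent(spec,
                                                rng.normal(size=(30, 2))))
            U = np.asarray(visualization_similarity(
                Z, spec, None, SimilarityConfig(beta=0.0)))
            np.testing.assert_allclose(U, U.T, atol=1e-12)
            assert np.all((U >= 0.0) & (U <= 1.0))


class TestGspLoss:
    def _mats(self, rng, n=5):
        U = rng.random((n, n)) * 0.5
        U = (U + U.T) / 2
        np.fill_diagonal(U, 0.0)
        return U

    @pytest.mark.parametrize("form", ["as_printed", "standard_fuzzy_ce"])
    def test_zero_at_equality(self, rng, form):
        U = self._mats(rng)
        cfg = SimilarityConfig(loss_form=form)
        assert gsp_loss(U, U.copy(), cfg) == pytest.approx(0.0, abs=1e-12)

    def test_standard_form_nonnegative(self, rng):
        cfg = SimilarityConfig(loss_form="standard_fuzzy_ce")
        for _ in range(20):
            assert gsp_loss(self._mats(rng), self._mats(rng), cfg) >= 0.0

    def test_frozen_spot_values(self):
        # single off-diagonal pair (0.2, 0.8), both directions
        U_st = np.array([[0.0, 0.2], [0.2, 0.0]])
        U_vi = np.array([[0.0, 0.8], [0.8, 0.0]])
        per_pair_std = 0.2 * np.log(0.25) + 0.8 * np.log(4.0)      # ≈ 0.8318
        per_pair_prn = 0.2 * np.log(0.25) + 0.2 * np.log(0.25)     # ≈ −0.5545
        std = gsp_loss(U_st, U_vi, SimilarityConfig(
            loss_form="standard_fuzzy_ce"))
        prn = gsp_loss(U_st, U_vi, SimilarityConfig(loss_form="as_printed"))
        assert std == pytest.approx(2 * per_pair_std, rel=1e-10)
        assert prn == pytest.approx(2 * per_pair_prn, rel=1e-10)
        assert prn < 0  # the printed variant is not sign-definite

    @pytest.mark.parametrize("form", ["as_printed", "standard_fuzzy_ce"])
    def test_gradient_sign_pulls_vis_toward_structure(self, form):
        """d loss / d u_vi is negative when u_vi < u_st (attraction) and
        positive when u_vi > u_st (repulsion), checked by finite
        differences on a single-pair toy."""
        cfg = SimilarityConfig(loss_form=form)

        def loss_at(uvi):
            U_st = np.array([[0.0, 0.8], [0.8, 0.0]])
            U_vi = np.array([[0.0, uvi], [uvi, 0.0]])
            return float(gsp_loss(U_st, U_vi, cfg))

        h = 1e-7
        assert (loss_at(0.2 + h) - loss_at(0.2 - h)) / (2 * h) < 0
        cfg2 = SimilarityConfig(loss_form=form)

        def loss_at2(uvi):
            U_st = np.array([[0.0, 0.1], [0.1, 0.0]])
            U_vi = np.array([[0.0, uvi], [uvi, 0.0]])
            return float(gsp_loss(U_st, U_vi, cfg2))

        assert (loss_at2(0.8 + h) - loss_at2(0.8 - h)) / (2 * h) > 0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            gsp_loss(np.zeros((3, 3)), np.zeros((4, 4)), SimilarityConfig())
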