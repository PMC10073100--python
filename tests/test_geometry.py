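"""Manifold math: closed-form values, metric axioms, isometries."""

import numpy as np
import pytest

from deepvis import ManifoldSpec
from deepvis.geometry import (euclidean_distance, exp_map, lorentz_distance,
                              lorentz_inner, lorentz_to_poincare, mobius_add,
                              on_hyperboloid, origin, pairwise_distance_matrix,
                              poincare_distance, poincare_to_lorentz,
                              project_from_tangent)
from conftest import random_ball_points, random_hyperboloid_points


class TestClosedForms:
    def test_euclidean_345(self):
        assert euclidean_distance([0, 0], [3, 4]) == pytest.approx(5.0)

    def test_euclidean_identity_and_symmetry(self, rng):
        x, y = rng.normal(size=(2, 4))
        assert euclidean_distance(x, x) == 0.0
        assert euclidean_distance(x, y) == pytest.approx(
            euclidean_distance(y, x))

    def test_euclidean_dim_mismatch(self):
        with pytest.raises(ValueError):
            euclidean_distance([0, 0], [1, 2, 3])

    def test_poincare_half_radius(self):
        # both closed forms: arcosh(5/3) and 2·artanh(1/2) = ln 3
        d = poincare_distance([0.5, 0.0], [0.0, 0.0], K=1.0)
        assert d == pytest.approx(np.arccosh(5.0 / 3.0), abs=1e-12)
        assert d == pytest.approx(np.log(3.0), abs=1e-12)
        assert d == pytest.approx(2.0 * np.arctanh(0.5), abs=1e-12)

    def test_poincare_identity(self):
        assert poincare_distance([0.3, -0.2], [0.3, -0.2]) == 0.0

    def test_poincare_near_boundary_finite(self):
        d = poincare_distance([0.99, 0.0], [-0.99, 0.0], K=1.0)
        assert np.isfinite(d) and d > 8.0

    def test_poincare_rejects_outside_ball(self):
        with pytest.raises(ValueError):
            poincare_distance([1.2, 0.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            poincare_distance([0.9, 0.0], [0.0, 0.0], K=2.0)

    def test_lorentz_inner_basics(self):
        o = np.array([1.0, 0.0, 0.0])
        assert lorentz_inner(o, o) == pytest.approx(-1.0)
        assert lorentz_inner([1, 0, 0], [0, 1, 0]) == pytest.approx(0.0)
        x = np.array([1.2, 0.3, -0.4])
        y = np.array([2.0, 1.0, 0.5])
        assert lorentz_inner(3.0 * x, y) == pytest.approx(
            3.0 * lorentz_inner(x, y))

    def test_lorentz_distance_unit_boost(self):
        o = np.array([1.0, 0.0, 0.0])
        y = np.array([np.cosh(1.0), np.sinh(1.0), 0.0])
        assert lorentz_distance(o, y) == pytest.approx(1.0, abs=1e-12)
        assert lorentz_distance(y, y) == pytest.approx(0.0, abs=1e-7)

    def test_lorentz_rejects_off_manifold(self):
        with pytest.raises(ValueError):
            lorentz_distance([1.0, 0.5, 0.0], [1.0, 0.0, 0.0])


class TestMobius:
    def test_identity_element(self, rng):
        x = random_ball_points(rng, 5)
        z = np.zeros(2)
        np.testing.assert_allclose(mobius_add(x, np.zeros_like(x)), x,
                                   atol=1e-12)
        np.testing.assert_allclose(mobius_add(np.zeros_like(x), x), x,
                                   atol=1e-12)

    def test_left_inverse_standard_sign(self, rng):
        x = random_ball_points(rng, 200)
        np.testing.assert_allclose(mobius_add(-x, x), np.zeros_like(x),
                                   atol=1e-9)

    def test_printed_sign_variant_breaks_inverse(self, rng):
        # the sign-flipped variant fails (−x) ⊕ x = 0 away from the origin
        x = random_ball_points(rng, 50)
        res = mobius_add(-x, x, printed_sign=True)
        assert np.max(np.linalg.norm(res, axis=1)) > 0.01

    def test_result_stays_inside_ball(self, rng):
        x = random_ball_points(rng, 1000, rmax=0.999)
        y = random_ball_points(rng, 1000, rmax=0.999)
        out = mobius_add(x, y)
        assert np.all(np.linalg.norm(out, axis=1) < 1.0)


class TestExpMap:
    def test_euclidean_translation(self):
        spec = ManifoldSpec("euclidean")
        np.testing.assert_allclose(
            exp_map(spec, np.array([1.0, 2.0]), np.array([3.0, 4.0])),
            [4.0, 6.0])

    def test_poincare_origin_conformal_factor(self):
        spec = ManifoldSpec("poincare")
        v = np.array([0.5, 0.0])
        p = exp_map(spec, np.zeros(2), v)
        np.testing.assert_allclose(p, [np.tanh(0.5), 0.0], atol=1e-12)
        # distance from origin equals λ₀‖v‖ = 2‖v‖
        assert poincare_distance(np.zeros(2), p) == pytest.approx(1.0,
                                                                  abs=1e-10)

    def test_poincare_zero_tangent(self):
        spec = ManifoldSpec("poincare")
        base = np.array([0.2, 0.1])
        np.testing.assert_allclose(exp_map(spec, base, np.zeros(2)), base)

    def test_lorentz_unit_tangent(self):
        spec = ManifoldSpec("lorentz")
        base = np.array([1.0, 0.0, 0.0])
        v = np.array([0.0, 1.0, 0.0])
        out = exp_map(spec, base, v)
        np.testing.assert_allclose(out, [np.cosh(1), np.sinh(1), 0.0],
                                   atol=1e-12)
        assert lorentz_distance(base, out) == pytest.approx(1.0, abs=1e-10)

    def test_lorentz_rejects_non_tangent(self):
        spec = ManifoldSpec("lorentz")
        with pytest.raises(ValueError):
            exp_map(spec, np.array([1.0, 0.0, 0.0]),
                    np.array([1.0, 0.0, 0.0]))  # not Lorentz-orthogonal

    def test_lorentz_output_on_sheet(self, rng):
        spec = ManifoldSpec("lorentz")
        base = np.array([1.0, 0.0, 0.0])
        v = np.hstack([np.zeros((100, 1)), rng.normal(size=(100, 2))])
        out = exp_map(spec, np.broadcast_to(base, (100, 3)), v)
        assert on_hyperboloid(out, tol=1e-9)


class TestIsometry:
    """Hyperboloid → ball projection preserves distances (master oracle)."""

    def test_origin_maps_to_origin(self):
        np.testing.assert_allclose(
            lorentz_to_poincare([1.0, 0.0, 0.0]), [0.0, 0.0])

    def test_half_angle_formula(self):
        out = lorentz_to_poincare([np.cosh(1.0), np.sinh(1.0), 0.0])
        np.testing.assert_allclose(out, [np.tanh(0.5), 0.0], atol=1e-12)

    def test_distance_preservation_sweep(self, rng):
        x = random_hyperboloid_points(rng, 1000)
        y = random_hyperboloid_points(rng, 1000)
        dl = lorentz_distance(x, y)
        dp = poincare_distance(lorentz_to_poincare(x), lorentz_to_poincare(y))
        np.testing.assert_allclose(dl, dp, atol=1e-8)

    def test_round_trip(self, rng):
        x = random_hyperboloid_points(rng, 100)
        np.testing.assert_allclose(
            poincare_to_lorentz(lorentz_to_poincare(x)), x, atol=1e-9)


@pytest.mark.parametrize("kind", ["euclidean", "poincare", "lorentz"])
class TestMetricAxioms:
    def _points(self, rng, kind, n):
        if kind == "euclidean":
            return rng.normal(size=(n, 2))
        if kind == "poincare":
            return random_ball_points(rng, n)
        return random_hyperboloid_points(rng, n)

    def _dist(self, kind):
        return {"euclidean": euclidean_distance,
                "poincare": poincare_distance,
                "lorentz": lorentz_distance}[kind]

    def test_symmetry_identity_triangle(self, rng, kind):
        n = 1000
        x = self._points(rng, kind, n)
        y = self._points(rng, kind, n)
        z = self._points(rng, kind, n)
        d = self._dist(kind)
        dxy, dyx = d(x, y), d(y, x)
        np.testing.assert_allclose(dxy, dyx, atol=1e-8)
        np.testing.assert_allclose(d(x, x), 0.0, atol=1e-6)
        assert np.all(dxy >= 0)
        assert np.all(d(x, z) <= dxy + d(y, z) + 1e-8)


class TestBatchedForms:
    """The differentiable pairwise/projection paths agree with the
    scalar closed forms."""

    @pytest.mark.parametrize("kind", ["euclidean", "poincare", "lorentz"])
    def test_pairwise_matches_pointwise(self, rng, kind):
        spec = ManifoldSpec(kind)
        if kind == "euclidean":
            Z = rng.normal(size=(20, 2))
        elif kind == "poincare":
            Z = random_ball_points(rng, 20)
        else:
            Z = random_hyperboloid_points(rng, 20)
        D = np.asarray(pairwise_distance_matrix(Z, spec))
        d = {"euclidean": euclidean_distance, "poincare": poincare_distance,
             "lorentz": lorentz_distance}[kind]
        expect = np.array([[d(Z[i], Z[j]) for j in range(20)]
                           for i in range(20)])
        off = ~np.eye(20, dtype=bool)  # diagonal is clamp-limited by design
        np.testing.assert_allclose(D[off], expect[off], atol=1e-6)
        np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-5)

    @pytest.mark.parametrize("kind", ["poincare", "lorentz"])
    def test_projection_matches_exp_map_at_origin(self, rng, kind):
        spec = ManifoldSpec(kind)
        V = rng.normal(size=(50, 2))
        out = np.asarray(project_from_tangent(spec, V))
        o = origin(spec)
        if kind == "poincare":
            expect = np.vstack([exp_map(spec, o, v) for v in V])
        else:
            expect = np.vstack([exp_map(spec, o, np.hstack([0.0, v]))
                                for v in V])
        np.testing.assert_allclose(out, expect, atol=1e-9)


class TestManifoldSpec:
    def test_rejects_bad_kind_and_curvature(self):
        with pytest.raises(ValueError):
            ManifoldSpec("spherical")
        with pytest.raises(ValueError):
            ManifoldSpec("poincare", curvature=-1.0)
        with pytest.raises(ValueError):
            ManifoldSpec("lorentz", curvature=2.0)

    def test_ambient_dim(self):
        assert ManifoldSpec("euclidean", latent_dim=2).ambient_dim == 2
        assert ManifoldSpec("lorentz", latent_dim=2).ambient_dim == 3
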