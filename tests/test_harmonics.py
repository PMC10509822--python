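"""Harmonic-basis correctness: the printed closed forms are the oracle."""

import math

import numpy as np
import pytest
from scipy.special import binom

from opmarray import geometry
from opmarray.exceptions import InvalidParameterError, SingularPointError
from opmarray.harmonics import (
    HarmonicBasis,
    assoc_legendre,
    build_basis,
    evaluate_basis_at,
    n_terms,
    real_sph_harm,
    solid_harmonic,
    solid_harmonic_gradient,
    term_index,
)


def legendre_closed_form(l, m, u):
    """Finite-sum closed form of P_l^m with generalized binomial coefficients:

    (-1)^m 2^l (1-u^2)^(m/2) * sum_{k=m}^{l} k!/(k-m)! u^(k-m) C(l,k) C((l+k-1)/2, l)
    """
    s = sum(
        math.factorial(k) / math.factorial(k - m) * u ** (k - m)
        * binom(l, k) * binom((l + k - 1) / 2.0, l)
        for k in range(m, l + 1)
    )
    return (-1.0) ** m * 2.0 ** l * (1.0 - u * u) ** (m / 2.0) * s


def normalization_closed_form(l, m):
    if m == 0:
        return np.sqrt((2 * l + 1) / (4 * np.pi))
    return (-1.0) ** m * np.sqrt((2 * l + 1) / (2 * np.pi)
                                 * math.factorial(l - abs(m))
                                 / math.factorial(l + abs(m)))


def sph_harm_closed_form(l, m, point):
    """Direct evaluation through the printed angular formulas (test oracle)."""
    x, y, z = point
    r = np.sqrt(x * x + y * y + z * z)
    a = normalization_closed_form(l, m)
    P = legendre_closed_form(l, abs(m), z / r)
    phi = np.arctan2(y, x)
    if m == 0:
        trig = 1.0
    elif m > 0:
        trig = np.cos(m * phi)
    else:
        trig = np.sin(abs(m) * phi)
    return a * P * trig


class TestAssociatedLegendre:
    @pytest.mark.parametrize("l,m,u,expected", [
        (0, 0, 0.3, 1.0), (0, 0, -0.9, 1.0),
        (1, 0, 0.42, 0.42), (1, 1, 0.0, -1.0),
    ])
    def test_low_order_values(self, l, m, u, expected):
        assert assoc_legendre(l, m, u) == pytest.approx(expected, abs=1e-12)

    def test_matches_closed_form_sum_up_to_l8(self):
        """The production recurrence equals the printed finite-sum form."""
        rng = np.random.default_rng(11)
        for l in range(0, 9):
            for m in range(0, l + 1):
                for u in rng.uniform(-0.999, 0.999, size=4):
                    assert assoc_legendre(l, m, u) == pytest.approx(
                        legendre_closed_form(l, m, u), rel=1e-9, abs=1e-9)

    def test_invalid_m_rejected(self):
        with pytest.raises(InvalidParameterError):
            assoc_legendre(2, 3, 0.5)


class TestRealSphericalHarmonics:
    def test_constant_and_dipole_values(self):
        assert real_sph_harm(0, 0, [0.3, -1.0, 2.0]) == pytest.approx(
            np.sqrt(1 / (4 * np.pi)))
        assert real_sph_harm(1, 0, [0, 0, 1.0]) == pytest.approx(
            np.sqrt(3 / (4 * np.pi)))
        # the two (-1)^m factors (Legendre and normalization) cancel
        assert real_sph_harm(1, 1, [1.0, 0, 0]) == pytest.approx(
            np.sqrt(3 / (4 * np.pi)))

    def test_matches_angular_closed_form(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            p = rng.normal(size=3)
            l = int(rng.integers(1, 7))
            m = int(rng.integers(-l, l + 1))
            assert real_sph_harm(l, m, p) == pytest.approx(
                sph_harm_closed_form(l, m, p), rel=1e-9, abs=1e-12)

    def test_pole_limit_is_zero_for_nonzero_m(self):
        for m in (1, -1, 2):
            assert real_sph_harm(3, m, [0, 0, 2.0]) == pytest.approx(0.0, abs=1e-14)

    def test_origin_is_singular(self):
        with pytest.raises(SingularPointError):
            real_sph_harm(2, 1, [0, 0, 0])

    def test_orthonormal_by_quadrature(self):
        """Gauss-Legendre x trapezoid quadrature of S_lm S_l'm' over the sphere."""
        from numpy.polynomial.legendre import leggauss
        L = 6
        nodes, wts = leggauss(80)
        phi = np.linspace(0, 2 * np.pi, 161)[:-1]
        U, PH = np.meshgrid(nodes, phi)
        rho = np.sqrt(1 - U.ravel() ** 2)
        pts = np.column_stack([rho * np.cos(PH.ravel()),
                               rho * np.sin(PH.ravel()), U.ravel()])
        w = np.tile(wts, len(phi)) * (phi[1] - phi[0])
        from opmarray.harmonics import _solid_values_and_gradients
        vals, _ = _solid_values_and_gradients(pts, L, "external")  # r=1: S_lm
        gram = (vals * w[:, None]).T @ vals
        assert np.abs(gram - np.eye(n_terms(L))).max() < 1e-6


class TestSolidHarmonicGradients:
    def test_external_dipole_gradient_is_constant(self):
        a = np.sqrt(3 / (4 * np.pi))
        for p in ([1.0, 2, 3], [0, 0, 1.0], [-0.2, 0.1, -5]):
            np.testing.assert_allclose(
                solid_harmonic_gradient(1, 0, "external", p), [0, 0, a], atol=1e-14)

    def test_internal_dipole_gradient_on_axis(self):
        a = np.sqrt(3 / (4 * np.pi))
        np.testing.assert_allclose(
            solid_harmonic_gradient(1, 0, "internal", [0, 0, 1.0]),
            [0, 0, -2 * a], atol=1e-12)

    def test_gradient_matches_central_differences(self):
        """All terms to L=8, both kinds, 20 random points, rel err < 1e-6."""
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(20, 3))
        h = 1e-6
        for kind in ("internal", "external"):
            for l in range(1, 9):
                for m in range(-l, l + 1):
                    for p in pts[:3] if l > 5 else pts[:2]:
                        g = solid_harmonic_gradient(l, m, kind, p)
                        fd = np.array([
                            (solid_harmonic(l, m, kind, p + h * e)
                             - solid_harmonic(l, m, kind, p - h * e)) / (2 * h)
                            for e in np.eye(3)])
                        assert np.linalg.norm(g - fd) <= 1e-6 * max(
                            np.linalg.norm(g), 1e-12)

    def test_both_families_are_harmonic(self):
        """Numerical Laplacian vanishes away from the singular point."""
        rng = np.random.default_rng(13)
        h = 1e-4
        for kind in ("internal", "external"):
            for _ in range(6):
                l = int(rng.integers(1, 7))
                m = int(rng.integers(-l, l + 1))
                p = rng.normal(size=3)
                f0 = solid_harmonic(l, m, kind, p)
                lap = sum(
                    (solid_harmonic(l, m, kind, p + h * e)
                     + solid_harmonic(l, m, kind, p - h * e) - 2 * f0) / h ** 2
                    for e in np.eye(3))
                scale = max(abs(f0) / np.linalg.norm(p) ** 2, 1e-6)
                assert abs(lap) < 1e-3 * scale  # FD noise floor

    def test_internal_origin_singular(self):
        with pytest.raises(SingularPointError):
            solid_harmonic_gradient(2, 0, "internal", [0, 0, 0])


class TestBasisAssembly:
    @pytest.mark.parametrize("L,cols", [(1, 3), (3, 15), (11, 143), (12, 168)])
    def test_column_count_law(self, L, cols):
        assert n_terms(L) == cols
        assert len(term_index(L)) == cols

    def test_basis_shape_and_nesting(self, small_bundle):
        arr = small_bundle["array"]
        basis = build_basis(arr, 5, "internal")
        assert basis.matrix.shape == (arr.n_channels, n_terms(5))
        sub = basis.truncated(3)
        np.testing.assert_array_equal(sub.matrix, basis.matrix[:, :15])
        assert sub.term_index == term_index(3)

    def test_external_order1_on_radial_sphere_is_homogeneous_fields(self):
        """On a radial spherical array the three L=1 external columns are the
        three homogeneous (constant) field patterns dotted with the normals."""
        rng = np.random.default_rng(2)
        dirs = rng.normal(size=(40, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pos = 0.1 * dirs
        mat = evaluate_basis_at(pos, dirs, 1, "external", np.zeros(3))
        a = np.sqrt(3 / (4 * np.pi))
        # term order: (1,-1)->grad a*y, (1,0)->grad a*z, (1,1)->grad a*x
        np.testing.assert_allclose(mat[:, 0], a * dirs[:, 1], atol=1e-12)
        np.testing.assert_allclose(mat[:, 1], a * dirs[:, 2], atol=1e-12)
        np.testing.assert_allclose(mat[:, 2], a * dirs[:, 0], atol=1e-12)

    def test_no_zero_columns_on_generic_array(self, small_bundle):
        for kind in ("internal", "external"):
            basis = build_basis(small_bundle["array"], 4, kind)
            assert np.linalg.norm(basis.matrix, axis=0).min() > 0

    def test_channel_at_origin_rejected(self):
        pos = np.array([[0.0, 0, 0], [0.1, 0, 0]])
        ori = np.array([[0.0, 0, 1], [1.0, 0, 0]])
        with pytest.raises(SingularPointError):
            evaluate_basis_at(pos, ori, 2, "internal", np.zeros(3))
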