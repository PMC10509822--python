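"""Real spherical harmonics, solid harmonics and channel-space basis matrices.

The magnetic field in a source-free region is a gradient of a harmonic
potential, so it can be expanded in the gradients of two solid-harmonic
families about a chosen origin:

* *irregular* (internal) solid harmonics ``S_lm / r^(l+1)`` decay with
  distance and model fields from sources inside the sensor array (the brain);
* *regular* (external) solid harmonics ``r^l * S_lm`` grow with distance and
  model fields from sources outside the array (environmental interference).

Projecting each gradient onto a channel's sensitive axis yields one column
per ``(l, m)`` term of the channel-space design matrices conventionally
called ``A`` (internal) and ``B`` (external) in signal space separation
(SSS).  Truncating at order ``L`` gives ``L**2 + 2*L`` columns (``l`` runs
from 1; the ``l = 0`` internal term would be a magnetic monopole).

Numerics
--------
Production evaluation never touches spherical angles.  Each real solid
harmonic is factored as ``a_lm * A_lm(z, r**2) * T_m(x, y)`` where ``A_lm``
is the polynomial part of the associated Legendre function (Condon-Shortley
phase included) and ``T_m`` is the real or imaginary part of ``(x + iy)**m``.
Both factors satisfy short stable recurrences, and their Cartesian partial
derivatives are carried through the same recurrences, so values and
gradients are exact polynomials — finite at the coordinate poles where
angle-based formulas degenerate.

The term ordering is fixed and documented: ``l`` ascending from 1, ``m``
ascending from ``-l`` to ``l`` within each ``l``.  Coefficient vectors are
therefore portable across runs, and the basis at order ``L`` is the leading
block of the basis at any higher order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import lpmv

from opmarray.exceptions import InvalidParameterError, SingularPointError

__all__ = [
    "HarmonicBasis",
    "n_terms",
    "term_index",
    "assoc_legendre",
    "real_sph_harm",
    "solid_harmonic",
    "solid_harmonic_gradient",
    "evaluate_basis_at",
    "build_basis",
]


def n_terms(L: int) -> int:
    """Number of basis columns for a truncation order ``L`` (= L**2 + 2L)."""
    if L < 1:
        raise InvalidParameterError(f"truncation order must be >= 1, got {L}")
    return L * L + 2 * L


def term_index(L: int) -> list[tuple[int, int]]:
    """The fixed ``(l, m)`` ordering: l = 1..L ascending, m = -l..l ascending."""
    return [(l, m) for l in range(1, L + 1) for m in range(-l, l + 1)]


def _normalization(l: int, m: int) -> float:
    """The real-harmonic normalization constant ``a_lm``.

    ``sqrt((2l+1)/4pi)`` for ``m = 0`` and
    ``(-1)**m * sqrt((2l+1)/2pi * (l-|m|)!/(l+|m|)!)`` otherwise.  The
    ``(-1)**m`` here cancels the Condon-Shortley phase carried by the
    associated Legendre function, which is what makes the family orthonormal
    with positive sign conventions (verified by quadrature in the tests).
    """
    am = abs(m)
    if am == 0:
        return float(np.sqrt((2 * l + 1) / (4.0 * np.pi)))
    from scipy.special import factorial

    ratio = factorial(l - am, exact=True) / factorial(l + am, exact=True)
    return float((-1.0) ** am * np.sqrt((2 * l + 1) / (2.0 * np.pi) * ratio))


def assoc_legendre(l: int, m: int, u):
    """Associated Legendre function ``P_l^m(u)`` with Condon-Shortley phase.

    Matches the closed-form finite sum (with its ``(-1)**m`` and ``2**l``
    prefactors and generalized binomial coefficients) used as the test
    oracle; evaluated here through SciPy's stable implementation.
    """
    if m > l or m < 0:
        raise InvalidParameterError(f"need 0 <= m <= l, got l={l}, m={m}")
    u = np.asarray(u, dtype=float)
    if np.any(np.abs(u) > 1 + 1e-12):
        raise InvalidParameterError("argument of P_l^m must lie in [-1, 1]")
    return lpmv(m, l, np.clip(u, -1.0, 1.0))


def _legendre_polynomial_parts(L: int, z: np.ndarray, s: np.ndarray):
    """All ``A_lm(z, s)`` polynomials and their partials, ``s = r**2``.

    ``A_lm`` is defined by ``r**l * P_l^m(z/r) * cos(m*phi) =
    A_lm(z, s) * Re[(x+iy)**m]`` (same with sin/Im), i.e. the associated
    Legendre function with the ``(sin theta)**m`` factor absorbed into the
    azimuthal polynomial.  Recurrences (Condon-Shortley phase included)::

        A_mm     = (-1)**m (2m-1)!!
        A_m+1,m  = (2m+1) z A_mm
        (l-m) A_lm = (2l-1) z A_l-1,m - (l+m-1) s A_l-2,m

    Returns dict ``(l, m) -> (A, dA/dz, dA/ds)`` for ``0 <= m <= l <= L``.
    """
    out: dict[tuple[int, int], tuple] = {}
    zero = np.zeros_like(z)
    for m in range(0, L + 1):
        if m == 0:
            amm, damm_z, damm_s = np.ones_like(z), zero, zero
        else:
            prev = out[(m - 1, m - 1)][0]
            amm = -(2 * m - 1) * prev
            damm_z, damm_s = zero, zero
        out[(m, m)] = (amm, damm_z, damm_s)
        if m + 1 <= L:
            out[(m + 1, m)] = ((2 * m + 1) * z * amm, (2 * m + 1) * amm, zero)
        for l in range(m + 2, L + 1):
            a1, d1z, d1s = out[(l - 1, m)]
            a2, d2z, d2s = out[(l - 2, m)]
            c1, c2, denom = 2 * l - 1, l + m - 1, l - m
            a = (c1 * z * a1 - c2 * s * a2) / denom
            dz = (c1 * (a1 + z * d1z) - c2 * s * d2z) / denom
            ds = (c1 * z * d1s - c2 * (a2 + s * d2s)) / denom
            out[(l, m)] = (a, dz, ds)
    return out


def _azimuthal_parts(L: int, x: np.ndarray, y: np.ndarray):
    """Real/imaginary parts ``C_m, S_m`` of ``(x + iy)**m`` for m = 0..L."""
    C = [np.ones_like(x)]
    S = [np.zeros_like(x)]
    for m in range(1, L + 1):
        C.append(x * C[-1] - y * S[-1])
        S.append(x * S[-1] + y * C[-2])
    return C, S


def _solid_values_and_gradients(points: np.ndarray, L: int, kind: str):
    """Regular or irregular solid harmonics and gradients at many points.

    Returns ``(values, gradients)`` with shapes ``(P, n_terms)`` and
    ``(P, n_terms, 3)`` in the fixed term ordering.
    """
    if kind not in ("internal", "external"):
        raise InvalidParameterError(f"kind must be 'internal' or 'external', got {kind!r}")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    s = x * x + y * y + z * z
    if kind == "internal" and np.any(s == 0.0):
        raise SingularPointError("irregular solid harmonics are singular at the origin")

    ap = _legendre_polynomial_parts(L, z, s)
    C, S = _azimuthal_parts(L, x, y)
    nt = n_terms(L)
    vals = np.empty((pts.shape[0], nt))
    grads = np.empty((pts.shape[0], nt, 3))

    t = 0
    for l in range(1, L + 1):
        for m in range(-l, l + 1):
            am = abs(m)
            a = _normalization(l, m)
            A, dAz, dAs = ap[(l, am)]
            if m == 0:
                T, dTx, dTy = np.ones_like(x), 0.0, 0.0
            elif m > 0:
                T, dTx, dTy = C[am], am * C[am - 1], -am * S[am - 1]
            else:
                T, dTx, dTy = S[am], am * S[am - 1], am * C[am - 1]
            # regular solid harmonic f = a * A(z, s) * T(x, y), s = r^2
            f = a * A * T
            gx = a * (dAs * 2.0 * x * T + A * dTx)
            gy = a * (dAs * 2.0 * y * T + A * dTy)
            gz = a * ((dAz + dAs * 2.0 * z) * T)
            if kind == "external":
                vals[:, t] = f
                grads[:, t, 0], grads[:, t, 1], grads[:, t, 2] = gx, gy, gz
            else:
                # f_int = f * s^-(l+1/2);  grad picks up -(2l+1) f r_vec / s^(l+3/2)
                pw = s ** (-(2 * l + 1) / 2.0)
                pw3 = pw / s
                vals[:, t] = f * pw
                common = (2 * l + 1) * f * pw3
                grads[:, t, 0] = gx * pw - common * x
                grads[:, t, 1] = gy * pw - common * y
                grads[:, t, 2] = gz * pw - common * z
            t += 1
    return vals, grads


def real_sph_harm(l: int, m: int, point) -> float:
    """Real surface spherical harmonic ``S_lm`` at a Cartesian point.

    ``l = 0`` returns the constant ``sqrt(1/4pi)``.  At the coordinate poles
    (x = y = 0) the ``m != 0`` harmonics vanish, which is their continuous
    limit.
    """
    if abs(m) > l:
        raise InvalidParameterError(f"need |m| <= l, got l={l}, m={m}")
    p = np.asarray(point, dtype=float)
    r2 = float(p @ p)
    if r2 == 0.0:
        raise SingularPointError("spherical harmonics are undefined at the origin")
    if l == 0:
        return float(np.sqrt(1.0 / (4.0 * np.pi)))
    vals, _ = _solid_values_and_gradients(p[None, :], l, "external")
    t = term_index(l).index((l, m))
    return float(vals[0, t] / r2 ** (l / 2.0))


def solid_harmonic(l: int, m: int, kind: str, point) -> float:
    """Regular (``r**l S_lm``) or irregular (``S_lm / r**(l+1)``) solid harmonic."""
    if abs(m) > l or l < 1:
        raise InvalidParameterError(f"need 1 <= l and |m| <= l, got l={l}, m={m}")
    vals, _ = _solid_values_and_gradients(np.asarray(point, float)[None, :], l, kind)
    return float(vals[0, term_index(l).index((l, m))])


def solid_harmonic_gradient(l: int, m: int, kind: str, point) -> np.ndarray:
    """Cartesian gradient of a single solid harmonic at one point."""
    if abs(m) > l or l < 1:
        raise InvalidParameterError(f"need 1 <= l and |m| <= l, got l={l}, m={m}")
    _, grads = _solid_values_and_gradients(np.asarray(point, float)[None, :], l, kind)
    return grads[0, term_index(l).index((l, m))]


@dataclass
class HarmonicBasis:
    """Channel-space solid-harmonic design matrix.

    Attributes
    ----------
    matrix : (channels, n_terms) array
        Column ``t`` is the gradient of term ``t`` evaluated at each channel
        position (relative to ``origin``) projected on that channel's
        sensitive axis.
    kind : {"internal", "external"}
        Internal (irregular, neural) or external (regular, interference).
    order : int
        Truncation order ``L``; ``matrix.shape[1] == L**2 + 2L``.
    origin : (3,) array, metres
        Expansion origin.
    term_index : list of (l, m)
        Fixed column ordering (l ascending, m ascending within l).
    """

    matrix: np.ndarray
    kind: str
    order: int
    origin: np.ndarray
    term_index: list = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    def truncated(self, L: int) -> "HarmonicBasis":
        """The nested sub-basis of order ``L <= self.order`` (leading columns)."""
        if L > self.order:
            raise InvalidParameterError(f"cannot truncate order {self.order} basis to {L}")
        return HarmonicBasis(self.matrix[:, : n_terms(L)], self.kind, L,
                             self.origin, term_index(L))


def evaluate_basis_at(points, orientations, L: int, kind: str, origin) -> np.ndarray:
    """Low-level basis evaluation at arbitrary positions/orientations."""
    origin = np.asarray(origin, dtype=float)
    rel = np.atleast_2d(np.asarray(points, float)) - origin[None, :]
    if kind == "internal" and np.any(np.einsum("ij,ij->i", rel, rel) == 0.0):
        raise SingularPointError("a channel position coincides with the expansion origin")
    _, grads = _solid_values_and_gradients(rel, L, kind)
    return np.einsum("ptk,pk->pt", grads, np.atleast_2d(np.asarray(orientations, float)))


def build_basis(array, L: int, kind: str, origin=None) -> HarmonicBasis:
    """Assemble the SSS design matrix for a sensor array.

    Parameters
    ----------
    array : SensorArray
        Supplies channel positions and unit sensitive axes.
    L : int
        Truncation order (columns = ``L**2 + 2L``).
    kind : {"internal", "external"}
    origin : (3,) array, optional
        Expansion origin in metres; defaults to the centroid of the sensor
        positions (the conventional SSS choice).
    """
    if origin is None:
        origin = array.sensor_positions.mean(axis=0)
    origin = np.asarray(origin, dtype=float)
    mat = evaluate_basis_at(array.channel_positions, array.channel_orientations,
                            L, kind, origin)
    return HarmonicBasis(mat, kind, L, origin, term_index(L))
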