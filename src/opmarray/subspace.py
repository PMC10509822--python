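"""Dimensionality of the neuronal field: harmonic and eigenvector subspaces.

Two nested families of channel-space subspaces can model the neuronal
signal: truncated internal solid-harmonic bases ``A`` (order ``L``,
``L**2 + 2L`` regressors) and leading eigenvectors of the lead-field
covariance ``C = L L^T = V Sigma V^T`` (``k`` regressors).  For either
family the per-source variance explained is

    VE_i = var(P L_i) / var(L_i)

with ``P`` the orthogonal projector onto the subspace and ``var`` the
across-channel sample variance.  The field counts a subspace as adequate
when at least 99% of variance is explained in at least 95% of sources; the
*saturation order* (or required eigenvector count) is the smallest
truncation meeting that criterion.

Projecting measured data onto a subspace of ``Nr`` regressors also
suppresses white sensor noise by the factor ``sqrt(Nc / Nr)`` in RMS
(``Nc`` channels) — an effective spatial oversampling factor, verified
empirically by :func:`noise_reduction_check`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from opmarray.exceptions import InvalidParameterError
from opmarray.harmonics import build_basis, n_terms
from opmarray.projection import channel_variance

__all__ = ["EigenBasis", "SaturationResult", "variance_explained_harmonic",
           "variance_explained_eigen", "saturation_order", "eigen_decompose",
           "required_eigenvectors", "noise_reduction_check"]

DEFAULT_VE = 0.99
DEFAULT_FRACTION = 0.95


@dataclass
class EigenBasis:
    """Eigendecomposition of the channel-space lead-field covariance."""

    vectors: np.ndarray        # (Nc, Nc) orthogonal, columns sorted
    eigenvalues: np.ndarray    # descending, >= 0


@dataclass
class SaturationResult:
    """Smallest truncation meeting the variance-explained criterion."""

    order_or_count: int | None      # None: not reached within the sweep
    ve_curve: np.ndarray            # fraction of sources passing, per step
    steps: np.ndarray               # the orders (or counts) swept
    thresholds: tuple = (DEFAULT_VE, DEFAULT_FRACTION)
    saturated: bool = True
    meta: dict = field(default_factory=dict)


def _ve_from_projection(P_L: np.ndarray, Lmat: np.ndarray) -> np.ndarray:
    v_in = channel_variance(Lmat)
    v_out = channel_variance(P_L)
    ve = np.full(v_in.shape, np.nan)
    ok = v_in > 0
    ve[ok] = v_out[ok] / v_in[ok]
    return ve


def _orthonormal_columns(mat: np.ndarray, rcond: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the column space, rank-truncated at ``rcond``.

    Columns are normalized first: solid-harmonic columns span many orders
    of magnitude across ``l`` and the span (not the scaling) is what
    defines the subspace.
    """
    norms = np.linalg.norm(mat, axis=0)
    norms[norms == 0] = 1.0
    u, s, _ = np.linalg.svd(mat / norms, full_matrices=False)
    rank = int(np.sum(s > rcond * s[0])) if s.size else 0
    return u[:, :rank]


def variance_explained_harmonic(A, L) -> np.ndarray:
    """Per-source VE of the internal harmonic subspace (``N = A A+``)."""
    Amat = A.matrix if hasattr(A, "matrix") else np.asarray(A, float)
    Lmat = L.matrix if hasattr(L, "matrix") else np.asarray(L, float)
    if Amat.shape[0] != Lmat.shape[0]:
        raise InvalidParameterError("basis and lead field disagree on channel count")
    U = _orthonormal_columns(Amat)
    return _ve_from_projection(U @ (U.T @ Lmat), Lmat)


def variance_explained_eigen(eig: EigenBasis, L, k: int) -> np.ndarray:
    """Per-source VE of the leading-``k`` eigenvector subspace (``O = V_k V_k^T``)."""
    Lmat = L.matrix if hasattr(L, "matrix") else np.asarray(L, float)
    Vk = eig.vectors[:, :k]
    return _ve_from_projection(Vk @ (Vk.T @ Lmat), Lmat)


def saturation_order(array, leadfield, L_max: int = 15,
                     thresholds=(DEFAULT_VE, DEFAULT_FRACTION),
                     origin=None) -> SaturationResult:
    """Smallest internal-harmonic order explaining the neuronal field.

    Builds the order-``L_max`` internal basis once and sweeps its nested
    truncations; for each order the fraction of retained sources with
    ``VE_i >= thresholds[0]`` is recorded, and the first order at which
    that fraction reaches ``thresholds[1]`` is returned.
    """
    if L_max < 1:
        raise InvalidParameterError("L_max must be >= 1")
    ve_min, frac_min = thresholds
    Lmat = leadfield.matrix
    basis = build_basis(array, L_max, "internal", origin)
    # one QR of the full basis gives every nested projection cheaply:
    # columns are ordered l-ascending, so order L spans the first L^2+2L.
    fractions = np.empty(L_max)
    v_in = channel_variance(Lmat)
    ok = v_in > 0
    for i, L in enumerate(range(1, L_max + 1)):
        U = _orthonormal_columns(basis.matrix[:, : n_terms(L)])
        v_out = channel_variance(U @ (U.T @ Lmat))
        ve = v_out[ok] / v_in[ok]
        fractions[i] = np.mean(ve >= ve_min)
    passing = np.flatnonzero(fractions >= frac_min)
    sat = passing.size > 0
    return SaturationResult(int(passing[0]) + 1 if sat else None, fractions,
                            np.arange(1, L_max + 1), thresholds, saturated=sat)


def eigen_decompose(leadfield) -> EigenBasis:
    """Eigendecomposition of ``C = L L^T`` via SVD of the lead field."""
    Lmat = leadfield.matrix if hasattr(leadfield, "matrix") else np.asarray(leadfield, float)
    if Lmat.size == 0:
        raise InvalidParameterError("empty lead field")
    u, s, _ = np.linalg.svd(Lmat, full_matrices=True)
    eigvals = np.zeros(Lmat.shape[0])
    eigvals[: s.size] = s ** 2
    return EigenBasis(u, eigvals)


def required_eigenvectors(leadfield, thresholds=(DEFAULT_VE, DEFAULT_FRACTION),
                          eig: EigenBasis | None = None) -> SaturationResult:
    """Smallest eigenvector count ``k`` meeting the VE criterion.

    Uses cumulative sums over the eigen-coordinates of the lead field, so
    the whole ``k``-curve costs one matrix product.
    """
    Lmat = leadfield.matrix if hasattr(leadfield, "matrix") else np.asarray(leadfield, float)
    if eig is None:
        eig = eigen_decompose(leadfield)
    ve_min, frac_min = thresholds
    n, _ = Lmat.shape
    W = eig.vectors.T @ Lmat                       # (Nc, Ns) eigen-coordinates
    colmeans = eig.vectors.mean(axis=0)            # channel-mean of each eigenvector
    # var(O_k L_i) = (||O_k L_i||^2 - n * mean^2) / (n - 1), both cumulative in k
    cum_norm2 = np.cumsum(W ** 2, axis=0)
    cum_mean = np.cumsum(colmeans[:, None] * W, axis=0)
    v_out = (cum_norm2 - n * cum_mean ** 2) / (n - 1)
    v_in = channel_variance(Lmat)
    ok = v_in > 0
    fractions = np.mean(v_out[:, ok] / v_in[ok] >= ve_min, axis=1)
    passing = np.flatnonzero(fractions >= frac_min)
    sat = passing.size > 0
    return SaturationResult(int(passing[0]) + 1 if sat else None, fractions,
                            np.arange(1, n + 1), thresholds, saturated=sat)


def noise_reduction_check(subspace, n_trials: int = 200, seed: int = 0,
                          n_channels: int | None = None) -> float:
    """Empirical RMS white-noise reduction from projecting onto a subspace.

    ``subspace`` is a (Nc, Nr) matrix whose column space defines the
    projection (an internal basis or leading eigenvectors).  Returns the
    ratio RMS(input) / RMS(projected), which for white noise concentrates
    on ``sqrt(Nc / Nr)``.
    """
    mat = subspace.matrix if hasattr(subspace, "matrix") else np.asarray(subspace, float)
    U = _orthonormal_columns(mat)
    nc, nr = mat.shape[0], U.shape[1]
    if n_channels is not None and n_channels != nc:
        raise InvalidParameterError("n_channels disagrees with the subspace")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((nc, n_trials))
    proj = U @ (U.T @ noise)
    return float(np.sqrt(np.mean(noise ** 2) / np.mean(proj ** 2)))
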