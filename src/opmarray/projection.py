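"""Interference projection, SSS separation, and neural-signal attenuation.

Two routes remove external interference given the channel-space bases
``A`` (internal) and ``B`` (external):

* joint SSS fit: ``c = [A B]+ Y`` and reconstruction ``Y_A = A c_A``;
* SSP-style projection: ``Y_clean = M Y`` with ``M = I - B B+``.

Because the internal and external subspaces are not exactly orthogonal on a
real array, the projector also removes some neuronal signal.  The cost for
cortical source ``i`` with lead-field column ``L_i`` is::

    attenuation_i = 10 log10( var(M L_i) / var(L_i) )

where ``var`` is the across-channel sample variance (mean subtracted,
``n - 1`` denominator).  Per-source values are signed (non-positive up to
the channel-mean term); summaries report positive loss magnitudes, with the
"worst case" taken as the 2.5% quantile of the signed distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from opmarray.exceptions import InvalidParameterError

__all__ = ["Projector", "SSSCoefficients", "AttenuationResult",
           "external_projector", "sss_separate", "leadfield_attenuation",
           "attenuation_sweep", "channel_variance"]

PINV_RCOND = 1e-10


@dataclass
class Projector:
    """Orthogonal-complement projector ``M = I - B B+`` of an external basis."""

    matrix: np.ndarray
    source_basis: object = None
    rank_removed: int = 0


@dataclass
class SSSCoefficients:
    """Joint-fit harmonic coefficients and the conditioning of the design."""

    c_internal: np.ndarray
    c_external: np.ndarray
    condition_number: float


@dataclass
class AttenuationResult:
    """Per-source signed attenuation (dB) with loss summaries."""

    per_source_db: np.ndarray       # signed, <= ~0; -inf where fully removed
    undefined: np.ndarray           # var(L_i) == 0
    median_db: float                # positive loss magnitude
    q2p5_db: float                  # positive loss magnitude, worst 2.5% of sources
    order: int | None = None
    meta: dict = field(default_factory=dict)


def external_projector(B, rcond: float = PINV_RCOND) -> Projector:
    """``M = I - B B+`` for an external harmonic basis.

    Singular values below ``rcond`` times the largest are treated as zero;
    the effective rank is recorded.  When the basis has more columns than
    its numerical rank (the statistical-limit regime) a warning is issued
    rather than an error.
    """
    mat = B.matrix if hasattr(B, "matrix") else np.asarray(B, float)
    n = mat.shape[0]
    norms = np.linalg.norm(mat, axis=0)
    norms[norms == 0] = 1.0
    u, s, _ = np.linalg.svd(mat / norms, full_matrices=False)
    rank = int(np.sum(s > rcond * s[0])) if s.size else 0
    if rank < mat.shape[1]:
        warnings.warn(f"external basis is rank deficient: rank {rank} < "
                      f"{mat.shape[1]} columns", RuntimeWarning)
    ur = u[:, :rank]
    m = np.eye(n) - ur @ ur.T
    return Projector(m, source_basis=B, rank_removed=rank)


def sss_separate(A, B, Y):
    """Joint SSS fit: ``c = [A B]+ Y``, internal reconstruction ``A c_A``.

    Returns ``(SSSCoefficients, Y_internal)``.  A design whose combined
    column count exceeds the channel count (or is otherwise
    ill-conditioned) triggers a warning with the condition number, not an
    error — the fit is still the minimum-norm least-squares solution.
    """
    Amat = A.matrix if hasattr(A, "matrix") else np.asarray(A, float)
    Bmat = B.matrix if hasattr(B, "matrix") else np.asarray(B, float)
    Y = np.asarray(Y.values if hasattr(Y, "values") else Y, float)
    design = np.hstack([Amat, Bmat])
    s = np.linalg.svd(design, compute_uv=False)
    cond = float(s[0] / s[-1]) if s[-1] > 0 else np.inf
    if design.shape[1] > design.shape[0] or cond > 1e10:
        warnings.warn(f"ill-conditioned joint SSS design (cond = {cond:.3g})",
                      RuntimeWarning)
    c = np.linalg.pinv(design, rcond=PINV_RCOND) @ Y
    nA = Amat.shape[1]
    coeffs = SSSCoefficients(c[:nA], c[nA:], cond)
    return coeffs, Amat @ c[:nA]


def channel_variance(X: np.ndarray) -> np.ndarray:
    """Across-channel sample variance of each column (mean-subtracted, n-1)."""
    X = np.asarray(X, float)
    return X.var(axis=0, ddof=1)


def leadfield_attenuation(M: Projector, L, order: int | None = None) -> AttenuationResult:
    """Per-source signal loss from applying projector ``M`` to a lead field."""
    Mmat = M.matrix if hasattr(M, "matrix") else np.asarray(M, float)
    Lmat = L.matrix if hasattr(L, "matrix") else np.asarray(L, float)
    if Mmat.shape[1] != Lmat.shape[0]:
        raise InvalidParameterError("projector and lead field disagree on channel count")
    v_in = channel_variance(Lmat)
    v_out = channel_variance(Mmat @ Lmat)
    undefined = v_in == 0.0
    att = np.full(v_in.shape, np.nan)
    ok = ~undefined
    with np.errstate(divide="ignore"):
        ratio = v_out[ok] / v_in[ok]
        # ratios at the square of machine precision mean the source lies in
        # the interference span: flag as fully removed
        ratio[ratio < 1e-20] = 0.0
        att[ok] = 10.0 * np.log10(ratio)  # -inf where fully removed
    good = att[ok]
    median = float(-np.median(good)) if good.size else np.nan
    if good.size:
        with np.errstate(invalid="ignore"):
            q = np.quantile(good, 0.025)
        if np.isnan(q) and np.isneginf(good).any():
            q = -np.inf  # interpolation straddled a fully-removed source
        q2p5 = float(-q)
    else:
        q2p5 = np.nan
    if hasattr(M, "source_basis") and order is None and M.source_basis is not None:
        order = getattr(M.source_basis, "order", None)
    return AttenuationResult(att, undefined, median, q2p5, order=order)


def attenuation_sweep(scalp, cortex, spacings=None, n_axes_list=(1, 2, 3),
                      orders=(1, 2, 3), offset_mm: float = 6.5, seed: int = 0,
                      n_sensors_list=None, floor_fraction: float = 0.05,
                      origin=None, progress=None):
    """Lead-field attenuation over sensor spacings, axis counts and orders.

    Builds one array per (spacing | sensor count, axis count), its lead
    field, and for each external order the projector and attenuation
    summaries.  Returns a long-format :class:`pandas.DataFrame` with
    columns ``spacing, n_axes, sensors, channels, order, median_db,
    q2p5_db``.
    """
    import pandas as pd

    from opmarray import forward, geometry
    from opmarray.harmonics import build_basis

    if (spacings is None) == (n_sensors_list is None):
        raise InvalidParameterError("give exactly one of spacings or n_sensors_list")
    keys = [("spacing", s) for s in spacings] if spacings is not None else \
           [("n_sensors", n) for n in n_sensors_list]
    if origin is None:
        origin = geometry.expansion_origin_for(scalp)

    rows = []
    for kind, val in keys:
        for n_axes in n_axes_list:
            kw = {"spacing_mm": val} if kind == "spacing" else {"n_sensors": val}
            array = geometry.build_array(scalp, n_axes, offset_mm=offset_mm,
                                         seed=seed, **kw)
            lf = forward.filter_weak_sources(
                forward.compute_leadfield(array, cortex), floor_fraction)
            basis = build_basis(array, max(orders), "external", origin)
            for L in orders:
                M = external_projector(basis.truncated(L))
                res = leadfield_attenuation(M, lf, order=L)
                rows.append(dict(spacing=array.spacing_mm, n_axes=n_axes,
                                 sensors=array.n_sensors,
                                 channels=array.n_channels, order=L,
                                 median_db=res.median_db, q2p5_db=res.q2p5_db))
            if progress is not None:
                progress(rows[-1])
    return pd.DataFrame(rows)
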