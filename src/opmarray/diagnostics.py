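"""Leverage diagnostics: which channels dominate the harmonic fit.

The hat matrix of the internal design ``A`` is the orthogonal projection
``A A+``; its diagonal is the statistical *leverage* of each channel — the
rate of change of the fitted model with respect to that channel's datum.
Dividing by the mean leverage ``p / n`` (``p`` the numerical rank of ``A``,
``n`` the channel count) gives a relative influence with mean 1.

On an exact sphere every channel is equally influential at every order; on
a scalp-shaped (non-spherical) array, channels far from the expansion
origin lose influence, and the effect strengthens with harmonic order
because the irregular harmonics steepen with ``r``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from opmarray.exceptions import InvalidParameterError

__all__ = ["LeverageResult", "leverage"]


@dataclass
class LeverageResult:
    leverage: np.ndarray            # per channel, in [0, 1]
    relative_leverage: np.ndarray   # per channel, mean 1
    distance_to_origin: np.ndarray  # per channel, metres (NaN if unknown)
    order: int | None
    rank: int


def leverage(A, array=None, origin=None, rcond: float = 1e-10) -> LeverageResult:
    """Leverage ``diag(A A+)`` and its relative form for a harmonic basis.

    ``array`` (with ``origin``) is optional and only used to attach each
    channel's distance to the expansion origin for the distance-influence
    analysis.  Column rescaling of ``A`` leaves leverage unchanged.
    """
    mat = A.matrix if hasattr(A, "matrix") else np.asarray(A, float)
    if mat.size == 0:
        raise InvalidParameterError("empty basis")
    norms = np.linalg.norm(mat, axis=0)
    norms[norms == 0] = 1.0
    u, s, _ = np.linalg.svd(mat / norms, full_matrices=False)
    rank = int(np.sum(s > rcond * s[0]))
    lev = np.einsum("ij,ij->i", u[:, :rank], u[:, :rank])
    n = mat.shape[0]
    rel = lev / (rank / n)
    if array is not None:
        if origin is None:
            origin = getattr(A, "origin", None)
            if origin is None:
                origin = array.expansion_origin()
        dist = np.linalg.norm(array.channel_positions - np.asarray(origin), axis=1)
    else:
        dist = np.full(n, np.nan)
    return LeverageResult(lev, rel, dist, getattr(A, "order", None), rank)
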