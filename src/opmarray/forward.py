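"""Analytic spherical-conductor (current-dipole) lead fields.

The magnetic field of a current dipole inside a homogeneous conducting
sphere has the closed form of Sarvas (1987)::

    a_vec = r - r0,   a = |a_vec|,   F = a (r a + r^2 - r0 . r_vec)
    grad F = (a^2/r + a_vec.r_vec/a + 2a + 2r) r_vec
             - (a + 2r + a_vec.r_vec/a) r0
    B(r_vec) = mu0 / (4 pi F^2) * (F (Q x r0) - ((Q x r0) . r_vec) grad F)

with all positions relative to the sphere centre.  The field depends on the
centre only — not the conductor radius — and a purely radial dipole moment
is exactly silent.  Volume currents are handled implicitly by the sphere
symmetry; no boundary meshes are needed.

A *lead field* stacks, channel by channel, the field of a unit dipole
(1 A m, moment along the cortical surface normal) at every source vertex,
projected on each channel's sensitive axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from opmarray.exceptions import EmptyLeadFieldError, GeometryError, InvalidParameterError

__all__ = ["LeadField", "fit_sphere", "sarvas_field", "compute_leadfield",
           "filter_weak_sources"]

_MU0_OVER_4PI = 1e-7  # T m / (A m)


@dataclass
class LeadField:
    """Channels x sources matrix of simulated fields (tesla per A m).

    ``source_mask`` records which columns of the *original* source space are
    retained (weak-source filtering composes masks).
    """

    matrix: np.ndarray              # (channels, retained sources)
    source_mask: np.ndarray         # (original sources,) bool
    array_ref: object = None
    source_space_ref: object = None
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1]


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere fit; returns ``(center, radius)``.

    Linear formulation: ``|p|^2 = 2 c . p + (R^2 - |c|^2)``.
    """
    p = np.atleast_2d(np.asarray(points, float))
    A = np.column_stack([2.0 * p, np.ones(len(p))])
    b = np.einsum("ij,ij->i", p, p)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center, k = sol[:3], sol[3]
    radius = float(np.sqrt(max(k + center @ center, 0.0)))
    return center, radius


def sarvas_field(dipole_pos, dipole_moment, field_points, sphere_center) -> np.ndarray:
    """Field of one current dipole at many points; shape ``(P, 3)`` tesla."""
    c = np.asarray(sphere_center, float)
    r0 = np.asarray(dipole_pos, float) - c
    q = np.asarray(dipole_moment, float)
    r = np.atleast_2d(np.asarray(field_points, float)) - c

    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    if np.any(a < 1e-12) or np.any(rn < 1e-12):
        raise GeometryError("field point coincides with the dipole or sphere centre")
    adotr = np.einsum("ij,ij->i", a_vec, r)
    F = a * (rn * a + rn ** 2 - r @ r0)
    if np.any(np.abs(F) < 1e-30):
        raise GeometryError("degenerate geometry: Sarvas denominator vanished")
    gF = ((a ** 2 / rn + adotr / a + 2.0 * a + 2.0 * rn)[:, None] * r
          - (a + 2.0 * rn + adotr / a)[:, None] * r0[None, :])
    qxr0 = np.cross(q, r0)
    B = _MU0_OVER_4PI / F[:, None] ** 2 * (F[:, None] * qxr0[None, :]
                                           - (r @ qxr0)[:, None] * gF)
    return B


def compute_leadfield(array, cortex, sphere_center=None) -> LeadField:
    """Lead field of a sensor array over a cortical source surface.

    Dipole moments are unit (1 A m) along the cortical vertex normals.
    ``sphere_center`` defaults to the cortex centre (the conductor model
    depends only on the centre).  Every source must lie strictly closer to
    the centre than every sensor, so that a conducting sphere containing
    the sources but not the sensors exists.
    """
    if sphere_center is None:
        sphere_center = cortex.metadata.get("center", np.zeros(3))
    c = np.asarray(sphere_center, float)

    src = cortex.vertices - c
    sens = array.sensor_positions - c
    r_src = np.linalg.norm(src, axis=1)
    r_sens = np.linalg.norm(sens, axis=1)
    if r_src.max() >= r_sens.min():
        raise GeometryError(
            f"sources (max radius {r_src.max():.4f} m) must lie strictly inside "
            f"the sensor shell (min radius {r_sens.min():.4f} m)")

    pos = array.channel_positions - c          # (Nc, 3)
    ori = array.channel_orientations           # (Nc, 3)
    q = cortex.normals                         # (Ns, 3), unit moments

    # vectorized Sarvas over all (channel, source) pairs, chunked on sources
    Nc, Ns = pos.shape[0], src.shape[0]
    out = np.empty((Nc, Ns))
    rn = np.linalg.norm(pos, axis=1)           # (Nc,)
    chunk = max(1, int(4e6 // max(Nc, 1)))
    for s0 in range(0, Ns, chunk):
        s1 = min(Ns, s0 + chunk)
        r0 = src[s0:s1]                        # (S, 3)
        a_vec = pos[:, None, :] - r0[None, :, :]       # (Nc, S, 3)
        a = np.linalg.norm(a_vec, axis=2)
        adotr = np.einsum("csk,ck->cs", a_vec, pos)
        F = a * (rn[:, None] * a + rn[:, None] ** 2 - pos @ r0.T)
        if np.any(a < 1e-12) or np.any(np.abs(F) < 1e-30):
            raise GeometryError("sensor coincides with a source (Sarvas singularity)")
        c1 = a ** 2 / rn[:, None] + adotr / a + 2.0 * a + 2.0 * rn[:, None]
        c2 = a + 2.0 * rn[:, None] + adotr / a
        qxr0 = np.cross(q[s0:s1], r0)                  # (S, 3)
        proj = pos @ qxr0.T                            # (Nc, S): (q x r0) . r
        # B . n  =  mu0/(4 pi F^2) [ F (q x r0) . n - proj (gradF . n) ]
        gFdotn = c1 * np.einsum("ck,ck->c", pos, ori)[:, None] - c2 * (ori @ r0.T)
        out[:, s0:s1] = _MU0_OVER_4PI / F ** 2 * (F * (ori @ qxr0.T) - proj * gFdotn)
    if not np.all(np.isfinite(out)):
        raise GeometryError("non-finite lead-field values")
    return LeadField(out, np.ones(Ns, dtype=bool), array_ref=array,
                     source_space_ref=cortex,
                     meta=dict(sphere_center=c))


def filter_weak_sources(leadfield: LeadField, floor_fraction: float = 0.05) -> LeadField:
    """Drop sources whose column norm falls below ``floor_fraction`` x median.

    Near-silent sources (radially oriented dipoles under the spherical
    conductor) carry no usable signal and would make variance ratios
    numerically meaningless downstream.
    """
    if not (0.0 <= floor_fraction < 1.0):
        raise InvalidParameterError("floor_fraction must lie in [0, 1)")
    if leadfield.matrix.shape[1] == 0:
        raise EmptyLeadFieldError("lead field has no sources")
    norms = np.linalg.norm(leadfield.matrix, axis=0)
    keep = norms >= floor_fraction * np.median(norms)
    if floor_fraction == 0.0:
        keep = np.ones_like(keep, dtype=bool)
    if not keep.any():
        raise EmptyLeadFieldError("weak-source filtering removed every source")
    mask = leadfield.source_mask.copy()
    mask[np.flatnonzero(mask)] = keep
    return LeadField(leadfield.matrix[:, keep], mask, leadfield.array_ref,
                     leadfield.source_space_ref, dict(leadfield.meta))
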