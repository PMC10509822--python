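"""Synthetic head geometry and sensor-array construction.

The scalp is an offset ellipsoid cut by a horizontal plane (helmet
coverage); sensors are packed approximately equidistantly on it by
Lloyd-style point repulsion, then displaced outward along the surface
normal by the scalp-to-sensor offset (6.5 mm for on-scalp OPMs, 24 mm to
emulate a cryogenic SQUID helmet).  The cortical source space is a
corrugated quasi-sphere whose normals are deliberately not radial, so a
spherical-conductor forward model produces non-degenerate fields.

A *sensor* is a physical device; each measured axis of a sensor is one
*channel*, so 60 triaxial sensors yield 180 channels.  Axis 1 is the
outward radial normal ``[p, q, r]``; axis 2 applies the tangential rule
``normalize([-q, p, 0])`` (orthogonal by construction: ``-pq + qp + 0``);
axis 3 is the cross product of the first two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import ConvexHull, cKDTree

from opmarray.exceptions import (
    DegenerateOrientationWarning,
    InvalidParameterError,
    SurfaceError,
)

__all__ = [
    "Surface",
    "SensorArray",
    "make_scalp_surface",
    "make_cortical_source_space",
    "pack_sensors",
    "build_orientations",
    "channel_count",
    "DEFAULT_SCALP",
    "DEFAULT_CORTEX",
]

# Default study geometry (metres): head-sized ellipsoid scalp, helmet cut low
# enough to cover the sides of the head, and a cortex that stays well inside
# the conductor implied by the scalp.
DEFAULT_SCALP = dict(
    semi_axes=(0.075, 0.095, 0.085),
    center=(0.0, 0.0, -0.02),
    cut_height=-0.075,
    mesh_resolution=4,
)
DEFAULT_CORTEX = dict(
    base_radius=0.065,
    corrugation_amplitude=0.00325,  # 5% of base radius
    corrugation_frequency=6.0,
    n_vertices=2000,
    center=(0.0, 0.0, -0.02),
)


@dataclass
class Surface:
    """Triangulated surface with per-vertex outward unit normals (metres)."""

    vertices: np.ndarray          # (V, 3)
    faces: np.ndarray             # (F, 3) int
    normals: np.ndarray           # (V, 3) unit
    metadata: dict = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def area(self) -> float:
        return float(trimesh.Trimesh(self.vertices, self.faces, process=False).area)


@dataclass
class SensorArray:
    """Sensor positions with per-channel sensitive axes.

    ``sensor_positions`` are the final (offset-applied) magnetometer
    positions.  Channels are sensor-major: channel ``k`` belongs to sensor
    ``k // n_axes`` and axis ``k % n_axes``.
    """

    sensor_positions: np.ndarray        # (N, 3), metres
    channel_orientations: np.ndarray    # (N * n_axes, 3), unit
    channel_to_sensor: np.ndarray       # (N * n_axes,) int
    n_axes: int
    spacing_mm: float | None = None
    offset_mm: float = 6.5
    scalp_normals: np.ndarray | None = None

    @property
    def n_sensors(self) -> int:
        return self.sensor_positions.shape[0]

    @property
    def n_channels(self) -> int:
        return self.channel_orientations.shape[0]

    @property
    def channel_positions(self) -> np.ndarray:
        return self.sensor_positions[self.channel_to_sensor]

    def expansion_origin(self) -> np.ndarray:
        """Centroid of the sensor positions.

        Note: for helmet-style coverage the centroid sits high enough that
        the deepest sources can fall outside the nearest-sensor radius,
        breaking the internal/external harmonic split; the experiment
        recipes therefore use the sphere-fit centre of the scalp
        (:func:`expansion_origin_for`) instead.
        """
        return self.sensor_positions.mean(axis=0)


def channel_count(array: SensorArray) -> int:
    """Number of channels: sensors times measured axes per sensor."""
    return array.n_channels


# ---------------------------------------------------------------------------
# scalp
# ---------------------------------------------------------------------------

def _ellipsoid_normal(points, center, semi_axes):
    n = (np.atleast_2d(points) - np.asarray(center)) / np.square(semi_axes)
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def make_scalp_surface(semi_axes=DEFAULT_SCALP["semi_axes"],
                       center=DEFAULT_SCALP["center"],
                       cut_height=DEFAULT_SCALP["cut_height"],
                       mesh_resolution=DEFAULT_SCALP["mesh_resolution"]) -> Surface:
    """Ellipsoidal scalp cut by the plane ``z = cut_height``.

    The ellipsoid is deliberately non-spherical and offset from the
    coordinate origin: channel distances to the expansion origin must vary,
    because sampling on an exact sphere is a degenerate special case in
    which regular and irregular harmonics become highly correlated.

    Parameters
    ----------
    semi_axes : three positive floats, metres
    center : ellipsoid centre (origin offset), metres
    cut_height : float or None
        Faces with any vertex below ``z = cut_height`` are removed
        (``None`` keeps the closed surface).
    mesh_resolution : int
        Icosphere subdivision level (4 gives 2562 vertices).
    """
    semi_axes = np.asarray(semi_axes, dtype=float)
    center = np.asarray(center, dtype=float)
    if semi_axes.shape != (3,) or np.any(semi_axes <= 0):
        raise InvalidParameterError(f"semi-axes must be three positive lengths, got {semi_axes}")

    base = trimesh.creation.icosphere(subdivisions=int(mesh_resolution))
    verts = base.vertices * semi_axes[None, :] + center[None, :]
    faces = np.asarray(base.faces, dtype=np.int64)

    if cut_height is not None:
        keep_v = verts[:, 2] >= cut_height
        keep_f = keep_v[faces].all(axis=1)
        if not keep_f.any():
            raise SurfaceError(f"cut plane z={cut_height} removes the whole surface")
        faces = faces[keep_f]
        used = np.unique(faces)
        remap = -np.ones(verts.shape[0], dtype=np.int64)
        remap[used] = np.arange(used.size)
        verts, faces = verts[used], remap[faces]

    normals = _ellipsoid_normal(verts, center, semi_axes)
    meta = dict(kind="ellipsoid", semi_axes=semi_axes, center=center,
                cut_height=cut_height)
    return Surface(verts, faces, normals, meta)


# ---------------------------------------------------------------------------
# cortex
# ---------------------------------------------------------------------------

def _corrugation(unit_dirs, freq):
    """Smooth corrugation field g and its gradient wrt the unit direction."""
    u = np.atleast_2d(unit_dirs)
    c = np.cos(np.pi * freq * u)
    s = np.sin(np.pi * freq * u)
    g = c.prod(axis=1)
    grad = np.empty_like(u)
    grad[:, 0] = -np.pi * freq * s[:, 0] * c[:, 1] * c[:, 2]
    grad[:, 1] = -np.pi * freq * c[:, 0] * s[:, 1] * c[:, 2]
    grad[:, 2] = -np.pi * freq * c[:, 0] * c[:, 1] * s[:, 2]
    return g, grad


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform unit directions (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def make_cortical_source_space(base_radius=DEFAULT_CORTEX["base_radius"],
                               corrugation_amplitude=DEFAULT_CORTEX["corrugation_amplitude"],
                               corrugation_frequency=DEFAULT_CORTEX["corrugation_frequency"],
                               n_vertices=DEFAULT_CORTEX["n_vertices"],
                               center=DEFAULT_CORTEX["center"]) -> Surface:
    """Corrugated quasi-spherical cortical source surface.

    Vertices sit at ``r(u) = base_radius + amplitude * g(u)`` along
    near-uniform unit directions ``u``, with ``g`` a smooth product-cosine
    corrugation.  Normals are computed analytically from the implicit form,
    so with zero amplitude they are exactly radial, and with the default 5%
    amplitude a large fraction deviate from radial — which is what keeps
    near-radial sources from being uniformly silent under a spherical
    conductor model.
    """
    if base_radius <= 0:
        raise InvalidParameterError("base_radius must be positive")
    if corrugation_amplitude < 0 or corrugation_amplitude >= 0.5 * base_radius:
        raise InvalidParameterError(
            f"corrugation amplitude must be in [0, {0.5 * base_radius}), "
            f"got {corrugation_amplitude}")
    if n_vertices < 100:
        raise InvalidParameterError("need at least 100 source vertices")

    center = np.asarray(center, dtype=float)
    dirs = _fibonacci_sphere(int(n_vertices))
    g, grad = _corrugation(dirs, corrugation_frequency)
    radii = base_radius + corrugation_amplitude * g
    verts = center[None, :] + dirs * radii[:, None]

    faces = ConvexHull(dirs).simplices.astype(np.int64)
    # orient all triangles outward (convex hull of the unit directions)
    tri = dirs[faces]
    n_face = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    flip = np.einsum("ij,ij->i", n_face, tri.mean(axis=1)) < 0
    faces[flip] = faces[flip][:, ::-1]

    # implicit surface F(p) = |p - c| - R(u), u = (p - c)/|p - c|;
    # grad F = u - (amplitude / r) (I - u u^T) grad g(u)
    tang = grad - np.einsum("ij,ij->i", grad, dirs)[:, None] * dirs
    normals = dirs - (corrugation_amplitude / radii)[:, None] * tang
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)

    meta = dict(kind="corrugated_sphere", base_radius=base_radius,
                corrugation_amplitude=corrugation_amplitude,
                corrugation_frequency=corrugation_frequency, center=center)
    return Surface(verts, faces, normals, meta)


# ---------------------------------------------------------------------------
# sensor packing
# ---------------------------------------------------------------------------

def _project_to_ellipsoid(points, center, semi_axes, cut_height):
    """Star-shaped projection of points onto the (cut) ellipsoid."""
    d = np.atleast_2d(points) - center
    norm = np.linalg.norm(d, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    d = d / norm
    scale = 1.0 / np.sqrt(np.sum(np.square(d / semi_axes), axis=1))
    out = center + d * scale[:, None]
    if cut_height is not None:
        below = out[:, 2] < cut_height
        if below.any():
            # clamp to the cut-plane boundary ellipse, preserving azimuth
            z = cut_height
            zc = (z - center[2]) / semi_axes[2]
            shrink = np.sqrt(max(0.0, 1.0 - zc * zc))
            xy = out[below, :2] - center[:2]
            ang = np.linalg.norm(xy / (semi_axes[:2] * shrink), axis=1)
            ang[ang == 0] = 1.0
            out[below, :2] = center[:2] + xy / ang[:, None]
            out[below, 2] = z
    return out


def expected_sensor_count(scalp: Surface, spacing_mm: float) -> int:
    """Hexagonal-packing estimate: N = area / (sqrt(3)/2 * d**2)."""
    d = spacing_mm / 1000.0
    return int(round(scalp.area() / (np.sqrt(3.0) / 2.0 * d * d)))


def spacing_for_sensor_count(scalp: Surface, n_sensors: int) -> float:
    """Inverse of :func:`expected_sensor_count` (returns mm)."""
    return 1000.0 * np.sqrt(scalp.area() / (np.sqrt(3.0) / 2.0 * n_sensors))


def pack_sensors(scalp: Surface, spacing_mm: float | None = None, seed: int = 0,
                 n_sensors: int | None = None, max_iter: int = 400,
                 tol_m: float = 1e-4) -> np.ndarray:
    """Pack sensors approximately equidistantly on the scalp.

    Points are seeded by area-weighted random sampling of the scalp faces
    (deterministic for a given ``seed``) and relaxed by iterated
    short-range pairwise repulsion with star-shaped reprojection onto the
    surface, stopping when the largest move falls below ``tol_m`` (0.1 mm).
    Either a target ``spacing_mm`` (the sensor count then follows from the
    surface area) or an explicit ``n_sensors`` may be given.
    """
    if scalp.metadata.get("kind") != "ellipsoid":
        raise InvalidParameterError("pack_sensors needs an ellipsoidal scalp surface")
    if (spacing_mm is None) == (n_sensors is None):
        raise InvalidParameterError("give exactly one of spacing_mm or n_sensors")
    if spacing_mm is not None:
        if not (15.0 <= spacing_mm <= 85.0):
            raise InvalidParameterError(f"spacing_mm must lie in [15, 85], got {spacing_mm}")
        n = expected_sensor_count(scalp, spacing_mm)
    else:
        n = int(n_sensors)
    if n < 4:
        raise InvalidParameterError(
            f"surface too small for >= 4 sensors at the requested spacing (got {n})")
    d_target = (spacing_mm / 1000.0 if spacing_mm is not None
                else spacing_for_sensor_count(scalp, n) / 1000.0)

    rng = np.random.default_rng(seed)
    center = scalp.metadata["center"]
    semi_axes = scalp.metadata["semi_axes"]
    cut = scalp.metadata["cut_height"]

    # area-weighted seeding on the triangulation
    v, f = scalp.vertices, scalp.faces
    tri = v[f]
    areas = 0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    fi = rng.choice(len(f), size=n, p=areas / areas.sum())
    u, w = rng.random(n), rng.random(n)
    flip = u + w > 1
    u[flip], w[flip] = 1 - u[flip], 1 - w[flip]
    pts = tri[fi, 0] + u[:, None] * (tri[fi, 1] - tri[fi, 0]) + w[:, None] * (tri[fi, 2] - tri[fi, 0])
    pts = _project_to_ellipsoid(pts, center, semi_axes, cut)

    k = min(7, n - 1)
    step = 0.25
    for _ in range(max_iter):
        tree = cKDTree(pts)
        dist, idx = tree.query(pts, k=k + 1)
        dist, idx = dist[:, 1:], idx[:, 1:]
        delta = pts[:, None, :] - pts[idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = delta / dist[..., None]
        # short-range linear repulsion, zero beyond 1.5 target spacings
        mag = np.maximum(0.0, 1.0 - dist / (1.5 * d_target))
        move = step * d_target * (unit * mag[..., None]).sum(axis=1)
        new = _project_to_ellipsoid(pts + move, center, semi_axes, cut)
        shift = np.linalg.norm(new - pts, axis=1).max()
        pts = new
        if shift < tol_m:
            break
    return pts


# ---------------------------------------------------------------------------
# orientations
# ---------------------------------------------------------------------------

def _tangential_axis(normal: np.ndarray) -> np.ndarray:
    """Second (tangential) axis for one radial normal ``[p, q, r]``.

    The rule zeroes the third component, swaps the first two and negates
    the first: ``[-q, p, 0]``, then normalizes.  At an exact pole
    (p = q = 0) this is the zero vector; the documented fallback projects
    the global x-axis onto the tangent plane (``[1, 0, 0]`` at the pole).
    """
    p, q, _ = normal
    t = np.array([-q, p, 0.0])
    nrm = np.linalg.norm(t)
    if nrm < 1e-12:
        warnings.warn("radial axis at an exact pole; using x-axis fallback "
                      "for the tangential axis", DegenerateOrientationWarning)
        t = np.array([1.0, 0.0, 0.0]) - normal[0] * normal
        nrm = np.linalg.norm(t)
    return t / nrm


def build_orientations(positions, scalp_normals, n_axes: int,
                       spacing_mm: float | None = None,
                       offset_mm: float = 6.5) -> SensorArray:
    """Construct a single/dual/triaxial array from packed scalp positions.

    ``positions`` lie on the scalp; each sensor is displaced ``offset_mm``
    outward along its radial normal.  Axis 1 is the radial normal, axis 2
    the tangential rule (see :func:`_tangential_axis`) and axis 3 their
    cross product, giving a right-handed orthonormal triad.
    """
    if n_axes not in (1, 2, 3):
        raise InvalidParameterError(f"n_axes must be 1, 2 or 3, got {n_axes}")
    positions = np.atleast_2d(np.asarray(positions, float))
    normals = np.atleast_2d(np.asarray(scalp_normals, float))
    if positions.shape != normals.shape:
        raise InvalidParameterError("positions and normals must match in shape")
    normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)

    n = positions.shape[0]
    sensor_positions = positions + (offset_mm / 1000.0) * normals
    orientations = np.empty((n * n_axes, 3))
    chan2sens = np.repeat(np.arange(n), n_axes)
    for i in range(n):
        axes = [normals[i]]
        if n_axes >= 2:
            axes.append(_tangential_axis(normals[i]))
        if n_axes == 3:
            axes.append(np.cross(axes[0], axes[1]))
        orientations[i * n_axes:(i + 1) * n_axes] = axes
    return SensorArray(sensor_positions, orientations, chan2sens, n_axes,
                       spacing_mm=spacing_mm, offset_mm=offset_mm,
                       scalp_normals=normals)


def expansion_origin_for(scalp: Surface) -> np.ndarray:
    """Default harmonic expansion origin: least-squares sphere fit of the scalp.

    A deep origin keeps every cortical source strictly inside every sensor
    radius (so the irregular/regular split is well-posed) and reproduces
    the conventional head-centred SSS origin.
    """
    from opmarray.forward import fit_sphere
    return fit_sphere(scalp.vertices)[0]


def build_array(scalp: Surface, n_axes: int, spacing_mm: float | None = None,
                n_sensors: int | None = None, offset_mm: float = 6.5,
                seed: int = 0) -> SensorArray:
    """Convenience: pack sensors on ``scalp`` and build the oriented array."""
    pts = pack_sensors(scalp, spacing_mm=spacing_mm, n_sensors=n_sensors, seed=seed)
    center = scalp.metadata["center"]
    semi_axes = scalp.metadata["semi_axes"]
    normals = _ellipsoid_normal(pts, center, semi_axes)
    return build_orientations(pts, normals, n_axes, spacing_mm=spacing_mm,
                              offset_mm=offset_mm)
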