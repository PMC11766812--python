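"""Analytic magnetostatics of the field applicator and the capture wire.

Provides closed-form H fields of uniformly magnetized cuboid permanent
magnets (surface charge-sheet solution), the two-magnet applicator
assembly, and the dipole-line field of a transversely magnetized
microwire.  A brute-force dipole-grid discretization of the cuboid is
included as an independent numerical oracle.

Conventions
-----------
* Positions are in millimetres at the public interfaces; the wire-field
  helpers take micrometres (their natural scale).
* Field strengths are in A/m everywhere.  Remanence enters in tesla and
  is converted with ``H = B / mu0``.
* Origin at the centre of the midplane between the two magnets; ``z``
  along the magnetization axis, ``y`` along the channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

MU0 = 4.0e-7 * math.pi

#: default decoded block dimensions, mm (3.0 x 1.5 x 0.25 inch)
DEFAULT_MAGNET_MM = (38.1, 76.2, 6.35)
#: default face-to-face magnet separation, mm
DEFAULT_GAP_MM = 34.0
#: default remanence, tesla
DEFAULT_REMANENCE_T = 1.3

__all__ = [
    "MU0",
    "CuboidMagnet",
    "ApplicatorAssembly",
    "FieldSample",
    "cuboid_field",
    "cuboid_H",
    "applicator_field",
    "applicator_H",
    "dipole_grid_H",
    "wire_external_field",
    "wire_surface_field",
    "wire_gradient_magnitude",
    "total_field",
]


def _as_point(point) -> np.ndarray:
    p = np.asarray(point, dtype=float)
    if p.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValueError(f"point must be finite, got {p}")
    return p


@dataclass(frozen=True)
class CuboidMagnet:
    """Uniformly magnetized block magnet.

    Dimensions in mm; ``remanence`` in tesla.  ``magnetization_axis`` is
    a unit vector (through-thickness, i.e. z, for the default assembly).
    """

    length_x: float = DEFAULT_MAGNET_MM[0]
    length_y: float = DEFAULT_MAGNET_MM[1]
    thickness_z: float = DEFAULT_MAGNET_MM[2]
    remanence: float = DEFAULT_REMANENCE_T
    center_position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    magnetization_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        for name in ("length_x", "length_y", "thickness_z", "remanence"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        axis = np.asarray(self.magnetization_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if not math.isclose(norm, 1.0, rel_tol=1e-9):
            raise ValueError("magnetization_axis must have unit norm")

    @property
    def half_dims(self) -> np.ndarray:
        return 0.5 * np.array([self.length_x, self.length_y, self.thickness_z])

    @property
    def magnetization(self) -> float:
        """Magnetization magnitude M = Br / mu0 in A/m."""
        return self.remanence / MU0

    @property
    def volume_m3(self) -> float:
        return self.length_x * self.length_y * self.thickness_z * 1e-9

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Strict-interior test, vectorized over (N, 3) points in mm."""
        local = np.atleast_2d(points) - np.asarray(self.center_position)
        return np.all(np.abs(local) < self.half_dims - 1e-12, axis=1)


@dataclass(frozen=True)
class ApplicatorAssembly:
    """Two block magnets facing each other across a gap.

    ``configuration='like-directed'`` means both magnets are magnetized
    in the same direction so their fields add in the gap (the
    north-south-north-south arrangement).
    """

    magnet_pair: tuple[CuboidMagnet, CuboidMagnet] = ()
    gap: float = DEFAULT_GAP_MM  # face-to-face, mm
    configuration: str = "like-directed"

    def __post_init__(self):
        if not self.gap > 0:
            raise ValueError("gap must be > 0")
        if not self.magnet_pair:
            object.__setattr__(self, "magnet_pair", self._default_pair())
        if len(self.magnet_pair) != 2:
            raise ValueError("magnet_pair must hold exactly two magnets")
        a1 = np.asarray(self.magnet_pair[0].magnetization_axis)
        a2 = np.asarray(self.magnet_pair[1].magnetization_axis)
        if self.configuration == "like-directed" and not np.allclose(a1, a2):
            raise ValueError(
                "like-directed configuration requires identical magnetization axes"
            )

    def _default_pair(self) -> tuple[CuboidMagnet, CuboidMagnet]:
        z0 = 0.5 * self.gap + 0.5 * DEFAULT_MAGNET_MM[2]
        lower = CuboidMagnet(center_position=(0.0, 0.0, -z0))
        upper = CuboidMagnet(center_position=(0.0, 0.0, +z0))
        return (lower, upper)

    @classmethod
    def from_geometry(
        cls,
        gap: float = DEFAULT_GAP_MM,
        length_x: float = DEFAULT_MAGNET_MM[0],
        length_y: float = DEFAULT_MAGNET_MM[1],
        thickness_z: float = DEFAULT_MAGNET_MM[2],
        remanence: float = DEFAULT_REMANENCE_T,
    ) -> "ApplicatorAssembly":
        z0 = 0.5 * gap + 0.5 * thickness_z
        mk = lambda z: CuboidMagnet(  # noqa: E731
            length_x, length_y, thickness_z, remanence, (0.0, 0.0, z)
        )
        return cls(magnet_pair=(mk(-z0), mk(+z0)), gap=gap)


@dataclass(frozen=True)
class FieldSample:
    """Field evaluation at a single point.

    ``position`` mm, ``H_vector`` A/m, ``grad_H_magnitude`` is the
    gradient of |H| in A/m^2.  ``inside_source`` flags evaluation inside
    a magnet body or wire core, where the external closed forms do not
    apply.
    """

    position: np.ndarray
    H_vector: np.ndarray
    H_magnitude: float
    grad_H_magnitude: np.ndarray
    inside_source: bool = False

    def __post_init__(self):
        mag = float(np.linalg.norm(self.H_vector))
        if mag > 0 and abs(mag - self.H_magnitude) > 1e-9 * mag:
            raise ValueError("H_magnitude inconsistent with H_vector")


# ---------------------------------------------------------------------------
# charge-sheet cuboid solution
# ---------------------------------------------------------------------------

def _rect_sheet_H(sigma: float, hu: float, hv: float, w0: float,
                  u: np.ndarray, v: np.ndarray, w: np.ndarray):
    """H of a uniformly charged rectangle |u|<=hu, |v|<=hv at w=w0.

    ``sigma`` is the magnetic surface charge density (A/m).  Lengths may
    be in any consistent unit; the result is in A/m.
    """
    W = w - w0
    Hu = np.zeros_like(u)
    Hv = np.zeros_like(u)
    Hw = np.zeros_like(u)
    for i, ui in enumerate((-hu, hu)):
        for j, vj in enumerate((-hv, hv)):
            s = 1.0 if (i + j) % 2 == 0 else -1.0
            U = u - ui
            V = v - vj
            R = np.sqrt(U * U + V * V + W * W)
            # ln terms: the signed sum is scale invariant; clamp the
            # argument to dodge the measure-zero edge-line singularity
            Hu -= s * np.log(np.maximum(V + R, 1e-300))
            Hv -= s * np.log(np.maximum(U + R, 1e-300))
            num = U * V
            den = W * R
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.arctan(num / den)
            t = np.where(den == 0.0, np.sign(num) * (math.pi / 2), t)
            Hw += s * t
    k = sigma / (4.0 * math.pi)
    return k * Hu, k * Hv, k * Hw


_PERM = {0: (1, 2, 0), 1: (2, 0, 1), 2: (0, 1, 2)}  # axis -> (u, v, w)


def cuboid_H(magnet: CuboidMagnet, points) -> np.ndarray:
    """H field (A/m) of the magnet at (N, 3) points in mm."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    local = pts - np.asarray(magnet.center_position, dtype=float)
    half = magnet.half_dims
    M_vec = magnet.magnetization * np.asarray(magnet.magnetization_axis, dtype=float)
    H = np.zeros_like(local)
    for axis in range(3):
        Mc = M_vec[axis]
        if Mc == 0.0:
            continue
        iu, iv, iw = _PERM[axis]
        u, v, w = local[:, iu], local[:, iv], local[:, iw]
        hu, hv, hw = half[iu], half[iv], half[iw]
        # charged sheets on the two faces normal to this axis
        for w0, sgn in ((+hw, +1.0), (-hw, -1.0)):
            Hu, Hv, Hw = _rect_sheet_H(sgn * Mc, hu, hv, w0, u, v, w)
            H[:, iu] += Hu
            H[:, iv] += Hv
            H[:, iw] += Hw
    return H


def _grad_Hmag(eval_H, point: np.ndarray, step: float) -> np.ndarray:
    """Central-difference gradient of |H| at ``point`` (step in mm)."""
    g = np.zeros(3)
    for k in range(3):
        e = np.zeros(3)
        e[k] = step
        hp = np.linalg.norm(eval_H(point + e))
        hm = np.linalg.norm(eval_H(point - e))
        g[k] = (hp - hm) / (2.0 * step * 1e-3)  # per metre
    return g


def cuboid_field(magnet: CuboidMagnet, point, grad_step_mm: float = 0.01) -> FieldSample:
    """Field sample of a single cuboid magnet at a point in mm."""
    p = _as_point(point)
    H = cuboid_H(magnet, p[None, :])[0]
    grad = _grad_Hmag(lambda q: cuboid_H(magnet, q[None, :])[0], p, grad_step_mm)
    inside = bool(magnet.contains(p[None, :])[0])
    return FieldSample(p, H, float(np.linalg.norm(H)), grad, inside)


def applicator_H(assembly: ApplicatorAssembly, points) -> np.ndarray:
    """Superposed H of both magnets at (N, 3) points in mm."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return cuboid_H(assembly.magnet_pair[0], pts) + cuboid_H(assembly.magnet_pair[1], pts)


def applicator_field(assembly: ApplicatorAssembly, point,
                     grad_step_mm: float = 0.01) -> FieldSample:
    p = _as_point(point)
    H = applicator_H(assembly, p[None, :])[0]
    grad = _grad_Hmag(lambda q: applicator_H(assembly, q[None, :])[0], p, grad_step_mm)
    inside = any(bool(m.contains(p[None, :])[0]) for m in assembly.magnet_pair)
    return FieldSample(p, H, float(np.linalg.norm(H)), grad, inside)


# ---------------------------------------------------------------------------
# dipole-grid numerical oracle
# ---------------------------------------------------------------------------

def dipole_grid_H(magnet: CuboidMagnet, points, n_cells: int | tuple = 20) -> np.ndarray:
    """Brute-force H of the magnet as a grid of point dipoles.

    Independent discretized check of :func:`cuboid_H`.  An integer
    ``n_cells`` is the count along the shortest axis; the other axes are
    scaled with the dimension ratio (capped at 4x) so cells stay close
    to cubic, which controls the near-face quadrature error.  Use for
    validation only.
    """
    if np.isscalar(n_cells):
        dims = np.array([magnet.length_x, magnet.length_y, magnet.thickness_z])
        ratio = dims / dims.min()
        counts = np.clip(np.rint(n_cells * ratio).astype(int), n_cells, 4 * n_cells)
    else:
        counts = np.asarray(n_cells, dtype=int)
    pts = np.atleast_2d(np.asarray(points, dtype=float)) * 1e-3  # m
    half = magnet.half_dims * 1e-3
    centre = np.asarray(magnet.center_position, dtype=float) * 1e-3
    axes = [
        centre[k] + (np.arange(counts[k]) + 0.5) / counts[k] * 2 * half[k] - half[k]
        for k in range(3)
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    cells = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    v_cell = np.prod(2 * half) / np.prod(counts)
    m = (magnet.magnetization * v_cell) * np.asarray(magnet.magnetization_axis)
    H = np.zeros_like(pts)
    for i, p in enumerate(pts):
        r = p - cells
        d = np.linalg.norm(r, axis=1)
        rhat = r / d[:, None]
        mdotr = rhat @ m
        H[i] = np.sum(
            (3.0 * mdotr[:, None] * rhat - m) / d[:, None] ** 3, axis=0
        ) / (4.0 * math.pi)
    return H


# ---------------------------------------------------------------------------
# dipole-line field of the transversely magnetized wire
# ---------------------------------------------------------------------------

def wire_surface_field(magnetization: float, core_radius_um: float,
                       radius_um: float) -> float:
    """|h|(r) = M a^2 / (2 r^2) of the transversely magnetized cylinder.

    A/m for ``magnetization`` in A/m; independent of azimuth.
    """
    if radius_um < core_radius_um:
        raise ValueError("radius must be >= core radius (exterior field only)")
    return magnetization * core_radius_um**2 / (2.0 * radius_um**2)


def wire_gradient_magnitude(magnetization: float, core_radius_um: float,
                            radius_um: float) -> float:
    """|d|h|/dr| = M a^2 / r^3 in A/m^2 (SI)."""
    if radius_um < core_radius_um:
        raise ValueError("radius must be >= core radius (exterior field only)")
    a = core_radius_um * 1e-6
    r = radius_um * 1e-6
    return magnetization * a**2 / r**3


def wire_external_field(wire_magnetization: float, core_radius_um: float,
                        point_radius_um: float, angle_rad: float) -> FieldSample:
    """Dipole-line field outside the wire core.

    ``angle_rad`` is measured from the magnetization direction in the
    cross-sectional plane.  Returned vectors live in that plane with x
    along the magnetization and y perpendicular; |h| is independent of
    the angle and decays as 1/r^2.
    """
    if not np.isfinite([wire_magnetization, core_radius_um, point_radius_um,
                        angle_rad]).all():
        raise ValueError("inputs must be finite")
    if point_radius_um < core_radius_um:
        raise ValueError(
            "point inside the wire core: interior field is uniform, "
            "use a point_radius >= core_radius"
        )
    mag = wire_surface_field(wire_magnetization, core_radius_um, point_radius_um)
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    rhat = np.array([c, s, 0.0])
    that = np.array([-s, c, 0.0])
    h = mag * math.cos(angle_rad) * rhat + mag * math.sin(angle_rad) * that
    grad = -wire_gradient_magnitude(wire_magnetization, core_radius_um,
                                    point_radius_um) * rhat
    pos_mm = point_radius_um * 1e-3 * rhat
    return FieldSample(pos_mm, h, float(np.linalg.norm(h)), grad)


def total_field(assembly: ApplicatorAssembly | None, wire, point,
                wire_x_mm: float = 0.0, grad_step_mm: float = 1e-4) -> FieldSample:
    """Applicator + wire superposition at a point in mm.

    ``wire`` is a :class:`magbead.materials.Microwire` (or any object
    with ``core_radius``, ``glass_outer_radius`` in um and an
    ``operating_M`` in A/m); its axis runs along y at ``x = wire_x_mm``,
    ``z = 0``.  The wire is magnetized along z (the applied-field
    direction).  The gradient of |H| uses central differences at the
    wire scale (default step 0.1 um).
    """
    p = _as_point(point)
    M_w = float(wire.operating_M)
    a_um = float(wire.core_radius)

    def eval_H(q: np.ndarray) -> np.ndarray:
        H = np.zeros(3)
        if assembly is not None:
            H += applicator_H(assembly, q[None, :])[0]
        dx = (q[0] - wire_x_mm) * 1e3  # um
        dz = q[2] * 1e3
        r = math.hypot(dx, dz)
        if M_w != 0.0 and r >= a_um:
            mag = wire_surface_field(M_w, a_um, r)
            rhat = np.array([dx / r, 0.0, dz / r])
            mhat = np.array([0.0, 0.0, 1.0])
            H += mag * (2.0 * (mhat @ rhat) * rhat - mhat)
        return H

    dx = (p[0] - wire_x_mm) * 1e3
    dz = p[2] * 1e3
    inside = math.hypot(dx, dz) < a_um
    H = eval_H(p)
    grad = _grad_Hmag(eval_H, p, grad_step_mm)
    return FieldSample(p, H, float(np.linalg.norm(H)), grad, inside)


def field_map(assembly: ApplicatorAssembly, points_mm) -> "np.ndarray":
    """Tabular field map: columns x, y, z, Hx, Hy, Hz, |H|, |grad|H||."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    rows = np.empty((len(pts), 8))
    for i, p in enumerate(pts):
        fs = applicator_field(assembly, p)
        rows[i] = [*p, *fs.H_vector, fs.H_magnitude,
                   float(np.linalg.norm(fs.grad_H_magnitude))]
    return rows
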