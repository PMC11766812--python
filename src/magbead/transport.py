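"""Bead force, trajectories, capture and retention in channel flow.

The bead motion is overdamped: micron-scale beads in water lose momentum
within microseconds, so velocity = fluid velocity + mobility x force.
The duct flow is the no-slip rectangular-duct Fourier-series profile;
the perturbation of the flow by the wire itself is neglected (documented
fidelity limit).  Brownian motion is off (deterministic dynamics).

Cross-section coordinates: x across the width, z across the height, both
centred on the wire axis; y runs along the channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .magnetics import MU0, FieldSample, wire_gradient_magnitude, wire_surface_field
from .materials import BeadModel, Microwire, bead_moment

__all__ = [
    "ChannelGeometry",
    "FlowField",
    "BeadState",
    "CaptureResult",
    "magnetic_force",
    "duct_velocity",
    "simulate_capture",
    "retention_check",
    "retained_fraction",
    "channel_volume",
]

#: dynamic viscosity of water, Pa s
DEFAULT_VISCOSITY = 1.0e-3


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular incubation channel with the wire on its axis."""

    width: float = 400.0     # um
    height: float = 600.0    # um
    length: float = 6.0      # cm
    n_channels: int = 5
    wire_outer_radius: float = 27.5  # um

    def __post_init__(self):
        if min(self.width, self.height, self.length) <= 0:
            raise ValueError("channel dimensions must be > 0")
        if self.wire_outer_radius >= min(self.width, self.height) / 2:
            raise ValueError("wire does not fit inside the channel")

    @property
    def length_um(self) -> float:
        return self.length * 1e4


def channel_volume(channel: ChannelGeometry) -> float:
    """Open channel volume in uL (duct minus the wire envelope)."""
    w = channel.width * 1e-6
    h = channel.height * 1e-6
    length = channel.length * 1e-2
    wire = math.pi * (channel.wire_outer_radius * 1e-6) ** 2 * length
    return (w * h * length - wire) * 1e9


@dataclass
class FlowField:
    """Volumetric flow through one channel cross-section.

    ``profile_kind`` is ``'duct'`` (no-slip Fourier-series solution) or
    ``'plug'``.  The profile is scaled so its cross-sectional integral
    equals the volumetric rate.
    """

    volumetric_rate: float = 50.0  # uL/min
    profile_kind: str = "duct"
    series_terms: int = 40

    def __post_init__(self):
        if self.volumetric_rate < 0:
            raise ValueError("volumetric_rate must be >= 0")
        if self.profile_kind not in ("duct", "plug"):
            raise ValueError(f"unknown profile_kind {self.profile_kind!r}")

    @property
    def rate_m3s(self) -> float:
        return self.volumetric_rate * 1e-9 / 60.0


def _duct_shape(x, z, w, h, n_terms):
    """Unnormalized duct profile; x in [-w/2, w/2], z in [-h/2, h/2] (m)."""
    a = h / 2.0
    b = w / 2.0
    u = np.zeros(np.broadcast(x, z).shape, dtype=float)
    for idx in range(n_terms):
        i = 2 * idx + 1
        k = i * math.pi / (2 * a)
        sign = -1.0 if (idx % 2) else 1.0
        u += (sign / i**3) * (1.0 - np.cosh(k * x) / math.cosh(k * b)) * np.cos(k * z)
    return u


def _duct_shape_flux(w, h, n_terms):
    """Closed-form cross-sectional integral of the unnormalized profile."""
    a = h / 2.0
    b = w / 2.0
    total = 0.0
    for idx in range(n_terms):
        i = 2 * idx + 1
        k = i * math.pi / (2 * a)
        # the sign factors of the z-integral and the series prefactor square away
        total += (1.0 / i**3) * (4 * a / (i * math.pi)) * (2 * b - (2.0 / k) * math.tanh(k * b))
    return total


def duct_velocity(flow: FlowField, channel: ChannelGeometry, point) -> float | np.ndarray:
    """Axial velocity (um/s) at cross-section point(s) (x, z) in um."""
    pt = np.asarray(point, dtype=float)
    x = pt[..., 0] * 1e-6
    z = pt[..., 1] * 1e-6
    w = channel.width * 1e-6
    h = channel.height * 1e-6
    outside = (np.abs(x) > w / 2 + 1e-15) | (np.abs(z) > h / 2 + 1e-15)
    if np.any(outside):
        raise ValueError("point outside the duct cross-section")
    if flow.profile_kind == "plug":
        u = np.full(np.shape(x), flow.rate_m3s / (w * h))
    else:
        shape = _duct_shape(x, z, w, h, flow.series_terms)
        u = shape * (flow.rate_m3s / _duct_shape_flux(w, h, flow.series_terms))
    u = u * 1e6  # m/s -> um/s
    return float(u) if u.ndim == 0 else u


@dataclass
class BeadState:
    """Kinematic state of one bead (positions um, velocities um/s)."""

    position: np.ndarray
    velocity: np.ndarray
    captured: bool = False


@dataclass
class CaptureResult:
    captured: np.ndarray        # bool per bead
    exited: np.ndarray          # bool per bead
    times: np.ndarray           # s, time of capture/exit (or duration)
    positions: np.ndarray       # final positions, um
    trajectories: list | None = None

    @property
    def capture_fraction(self) -> float:
        return float(np.mean(self.captured)) if self.captured.size else 0.0


def magnetic_force(bead: BeadModel, field: FieldSample,
                   policy: str = "operating-point") -> np.ndarray:
    """Point-dipole force F = mu0 * m(|H|) * grad|H| in newtons."""
    m = bead_moment(bead, field.H_magnitude, policy=policy)
    return MU0 * m * np.asarray(field.grad_H_magnitude, dtype=float)


def _radial_drift_speed(rho_um, bead, wire, applicator_H0, viscosity, policy):
    """Magnitude of the magnetophoretic drift toward the wire, um/s."""
    rho = np.maximum(np.asarray(rho_um, dtype=float), wire.core_radius)
    h_wire = wire.operating_M * (wire.core_radius / rho) ** 2 / 2.0
    H_loc = applicator_H0 + h_wire
    m = bead_moment(bead, H_loc, policy=policy)
    grad = wire.operating_M * (wire.core_radius * 1e-6) ** 2 / (rho * 1e-6) ** 3
    force = MU0 * m * grad
    gamma = 6.0 * math.pi * viscosity * bead.radius_m
    return force / gamma * 1e6  # m/s -> um/s


def simulate_capture(
    positions,
    flow: FlowField,
    channel: ChannelGeometry,
    bead: BeadModel,
    wire: Microwire,
    applicator_H0: float = 106e3,
    duration: float = 10.0,
    max_step: float = 1e-3,
    viscosity: float = DEFAULT_VISCOSITY,
    moment_policy: str = "operating-point",
    record_trajectories: bool = False,
) -> CaptureResult:
    """Integrate overdamped bead trajectories until capture or exit.

    ``positions`` is (n, 3) in um: (x, z) in the cross-section centred
    on the wire, y along the channel.  A bead is captured when its
    centre reaches the wire envelope (glass radius + bead radius) and
    lost when it leaves the channel axially.  Adaptive stepping limits
    the radial displacement per step because the wire gradient grows as
    1/r^3 near the surface.
    """
    if max_step <= 0:
        raise ValueError("max_step must be > 0")
    pos = np.array(positions, dtype=float, copy=True)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError("positions must be (n, 3)")
    n = len(pos)
    rho_cap = channel.wire_outer_radius + bead.diameter / 2.0
    length_um = channel.length_um

    captured = np.zeros(n, dtype=bool)
    exited = np.zeros(n, dtype=bool)
    t = np.zeros(n)
    traj = [[] for _ in range(n)] if record_trajectories else None

    wire_on = wire.operating_M != 0.0
    active = ~(captured | exited)
    # beads seeded already inside the envelope count as captured at t=0
    rho0 = np.hypot(pos[:, 0], pos[:, 2])
    captured |= rho0 <= rho_cap
    active &= ~captured

    while np.any(active):
        idx = np.nonzero(active)[0]
        x, y, z = pos[idx, 0], pos[idx, 1], pos[idx, 2]
        rho = np.hypot(x, z)
        v_ax = duct_velocity(flow, channel, np.column_stack([x, z])) \
            if flow.volumetric_rate > 0 else np.zeros_like(rho)
        if wire_on:
            v_r = _radial_drift_speed(rho, bead, wire, applicator_H0,
                                      viscosity, moment_policy)
        else:
            v_r = np.zeros_like(rho)

        # adaptive step: cap radial motion to 10% of the gap to the envelope
        gap = np.maximum(rho - rho_cap, 0.05)
        with np.errstate(divide="ignore"):
            dt_r = np.where(v_r > 0, 0.1 * gap / v_r, np.inf)
            dt_a = np.where(v_ax > 0, 0.02 * length_um / v_ax, np.inf)
        dt = np.minimum(max_step, np.minimum(dt_r, dt_a))
        dt = np.minimum(dt, duration - t[idx])
        dt = np.maximum(dt, 1e-9)

        with np.errstate(invalid="ignore"):
            ux = np.where(rho > 0, -x / rho, 0.0)
            uz = np.where(rho > 0, -z / rho, 0.0)
        pos[idx, 0] += v_r * ux * dt
        pos[idx, 1] += v_ax * dt
        pos[idx, 2] += v_r * uz * dt
        t[idx] += dt

        new_rho = np.hypot(pos[idx, 0], pos[idx, 2])
        hit = new_rho <= rho_cap
        if np.any(hit):
            # clamp onto the envelope rather than crossing it
            hidx = idx[hit]
            rr = np.maximum(np.hypot(pos[hidx, 0], pos[hidx, 2]), 1e-12)
            pos[hidx, 0] *= rho_cap / rr
            pos[hidx, 2] *= rho_cap / rr
            captured[hidx] = True
        out = pos[idx, 1] > length_um
        exited[idx[out & ~hit]] = True
        timeout = t[idx] >= duration
        active[idx[hit | out | timeout]] = False

        if record_trajectories:
            for j, i_bead in enumerate(idx):
                traj[i_bead].append((t[i_bead], *pos[i_bead]))

    return CaptureResult(captured, exited, t, pos, traj)


def retention_check(
    flow: FlowField,
    channel: ChannelGeometry,
    bead: BeadModel,
    wire: Microwire,
    angle_rad: float = 0.0,
    applicator_H0: float = 106e3,
    viscosity: float = DEFAULT_VISCOSITY,
    friction_coefficient: float | None = None,
    moment_policy: str = "operating-point",
) -> bool:
    """Drag-vs-holding-force retention test for a bead on the wire.

    The bead centre sits one bead radius off the glass surface at
    ``angle_rad`` in the cross-section.  Retained iff the Stokes drag
    from the local (unperturbed) duct velocity is below the radial
    holding force, optionally scaled by a friction coefficient.
    """
    rho = channel.wire_outer_radius + bead.diameter / 2.0
    point = np.array([rho * math.sin(angle_rad), rho * math.cos(angle_rad)])
    u = duct_velocity(flow, channel, point) * 1e-6  # m/s
    drag = 6.0 * math.pi * viscosity * bead.radius_m * abs(u)

    h_wire = wire_surface_field(wire.operating_M, wire.core_radius, rho)
    H_loc = applicator_H0 + h_wire
    m = bead_moment(bead, H_loc, policy=moment_policy)
    grad = wire_gradient_magnitude(wire.operating_M, wire.core_radius, rho)
    holding = MU0 * m * grad
    if friction_coefficient is not None:
        holding = friction_coefficient * holding
    return bool(drag < holding)


def retained_fraction(flow: FlowField, channel: ChannelGeometry, bead: BeadModel,
                      wire: Microwire, n_angles: int = 36, **kwargs) -> float:
    """Fraction of angular positions on the wire that pass retention."""
    angles = np.linspace(0.0, 2.0 * math.pi, n_angles, endpoint=False)
    kept = [retention_check(flow, channel, bead, wire, angle_rad=a, **kwargs)
            for a in angles]
    return float(np.mean(kept))


def export_trajectories(result: CaptureResult, path) -> None:
    """Write trajectories as tabular text (bead, t, x, y, z, captured)."""
    if result.trajectories is None:
        raise ValueError("simulation was run without record_trajectories")
    with open(path, "w") as fh:
        fh.write("bead\tt_s\tx_um\ty_um\tz_um\tcaptured\n")
        for i, tr in enumerate(result.trajectories):
            for (t, x, y, z) in tr:
                fh.write(f"{i}\t{t:.6g}\t{x:.4f}\t{y:.4f}\t{z:.4f}\t"
                         f"{int(result.captured[i])}\n")
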