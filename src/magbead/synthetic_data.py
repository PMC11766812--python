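"""Seeded generators for every input the pipeline consumes.

Event clouds mimic the instrument's FSC-SSC signature: a low-lying noise
cloud, a central singlet cluster and a smaller doublet cluster whose
FL4 is the sum of two independent singlet draws (which makes the
doublet-corrected mean exactly unbiased for the singlet mean, by
construction).  Calibration experiments place the per-channel singlet
FL4 mean on the saturation-exponential curve on top of the stock-bead
background, and emit a truth record for recovery scoring.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import truncnorm

from .cytometry import EventTable, Gate
from .transport import ChannelGeometry

__all__ = [
    "EventCloudSpec",
    "ExperimentSpec",
    "DEFAULT_CLOUD_GEOMETRY",
    "default_gates",
    "gen_event_cloud",
    "gen_calibration_experiment",
    "gen_bead_positions",
]

#: fixed cluster geometry so the published default gate polygons are stable
DEFAULT_CLOUD_GEOMETRY = {
    "noise_center": (80.0, 60.0),
    "noise_spread": 30.0,
    "singlet_center": (400.0, 300.0),
    "singlet_spread": 35.0,
    "doublet_center": (650.0, 520.0),
    "doublet_spread": 35.0,
}

#: default gate polygons matched to DEFAULT_CLOUD_GEOMETRY
DEFAULT_G1_VERTICES = ((220.0, 140.0), (900.0, 140.0), (900.0, 760.0),
                       (220.0, 760.0))
DEFAULT_G2_VERTICES = ((520.0, 410.0), (900.0, 410.0), (900.0, 760.0),
                       (520.0, 760.0))


def default_gates() -> tuple[Gate, Gate]:
    """(G1, G2): G1 holds singlets + doublets, G2 only doublets."""
    return (Gate("G1", DEFAULT_G1_VERTICES), Gate("G2", DEFAULT_G2_VERTICES))


@dataclass(frozen=True)
class EventCloudSpec:
    n_noise: int = 500
    n_singlet: int = 8000
    n_doublet: int = 600
    singlet_fl4_mean: float = 100.0
    singlet_fl4_sd: float = 20.0
    fl4_family: str = "truncnorm"   # or "lognormal"
    noise_fl4_mean: float = 2.0
    seed: int = 0
    geometry: dict = field(default_factory=lambda: dict(DEFAULT_CLOUD_GEOMETRY))

    def __post_init__(self):
        if min(self.n_noise, self.n_singlet, self.n_doublet) < 0:
            raise ValueError("event counts must be >= 0")
        if self.singlet_fl4_sd <= 0:
            raise ValueError("singlet_fl4_sd must be > 0")
        if self.fl4_family not in ("truncnorm", "lognormal"):
            raise ValueError(f"unknown fl4_family {self.fl4_family!r}")


def _singlet_fl4(spec: EventCloudSpec, n: int, rng: np.random.Generator):
    mu, sd = spec.singlet_fl4_mean, spec.singlet_fl4_sd
    if spec.fl4_family == "lognormal":
        # match mean/sd moments of the lognormal
        s2 = np.log(1.0 + (sd / mu) ** 2)
        return rng.lognormal(np.log(mu) - s2 / 2.0, np.sqrt(s2), n)
    a = (0.0 - mu) / sd  # truncate at zero
    return truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=n, random_state=rng)


def gen_event_cloud(spec: EventCloudSpec) -> EventTable:
    """Synthesize one event table (noise + singlets + doublets)."""
    rng = np.random.default_rng(spec.seed)
    geo = spec.geometry

    def scatter(center, spread, n):
        return rng.normal(center[0], spread, n), rng.normal(center[1], spread, n)

    fsc_n, ssc_n = scatter(geo["noise_center"], geo["noise_spread"], spec.n_noise)
    fl4_n = rng.exponential(spec.noise_fl4_mean, spec.n_noise)

    fsc_s, ssc_s = scatter(geo["singlet_center"], geo["singlet_spread"],
                           spec.n_singlet)
    fl4_s = _singlet_fl4(spec, spec.n_singlet, rng)

    fsc_d, ssc_d = scatter(geo["doublet_center"], geo["doublet_spread"],
                           spec.n_doublet)
    # a doublet event is two beads read together: FL4 adds
    fl4_d = (_singlet_fl4(spec, spec.n_doublet, rng)
             + _singlet_fl4(spec, spec.n_doublet, rng))

    fsc = np.concatenate([fsc_n, fsc_s, fsc_d])
    ssc = np.concatenate([ssc_n, ssc_s, ssc_d])
    fl4 = np.concatenate([fl4_n, fl4_s, fl4_d])
    return EventTable.from_arrays(fsc, ssc, np.maximum(fl4, 0.0))


@dataclass(frozen=True)
class ExperimentSpec:
    """A full multi-channel assay run with known ground truth.

    ``roles`` entries are 'negative', 'recombinant' or 'sample'.  For
    recombinant channels the listed concentration is the in-channel
    value; for sample channels it is the neat sample concentration,
    reaching the channel scaled by dilution / mass_ratio.
    """

    true_A: float = 355.7
    true_B: float = 0.069
    concentrations: tuple = (0.0, 20.0, 40.0, 75.0, 150.0)
    roles: tuple = ("negative", "recombinant", "recombinant", "recombinant",
                    "sample")
    dilution: float = 0.1
    mass_ratio: float = 1.6
    # keep means >> sd so the zero-truncation of the FL4 noise family does
    # not bias the negative control
    stock_mean: float = 60.0
    stock_sd: float = 2.0
    n_stock_replicates: int = 3
    fl4_sd: float = 15.0
    cloud: EventCloudSpec = field(default_factory=lambda: EventCloudSpec(
        n_noise=300, n_singlet=3000, n_doublet=250))
    seed: int = 0

    def __post_init__(self):
        if self.true_A <= 0 or self.true_B <= 0:
            raise ValueError("true_A and true_B must be > 0")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be >= 0")
        if len(self.concentrations) != len(self.roles):
            raise ValueError("one role per channel is required")
        if any(r not in ("negative", "recombinant", "sample") for r in self.roles):
            raise ValueError("roles must be negative/recombinant/sample")


def channel_concentration(spec: ExperimentSpec, index: int) -> float:
    """In-channel concentration seen by the beads in a given channel."""
    conc = spec.concentrations[index]
    if spec.roles[index] == "sample":
        return conc * spec.dilution / spec.mass_ratio
    return conc


def gen_calibration_experiment(
    spec: ExperimentSpec,
) -> tuple[list[EventTable], list[EventTable], dict]:
    """Generate per-channel event tables, stock replicates and the truth.

    Each channel's singlet FL4 mean is
    stock_mean + true_A * (1 - exp(-true_B * C_channel)).
    """
    root = np.random.default_rng(spec.seed)
    seeds = root.integers(0, 2**63 - 1, size=len(spec.roles)
                          + spec.n_stock_replicates)

    channels = []
    truth_means = []
    for i in range(len(spec.roles)):
        c_chan = channel_concentration(spec, i)
        mean = spec.stock_mean + spec.true_A * (1.0 - np.exp(-spec.true_B * c_chan))
        cloud = replace(spec.cloud, singlet_fl4_mean=float(mean),
                        singlet_fl4_sd=spec.fl4_sd, seed=int(seeds[i]))
        channels.append(gen_event_cloud(cloud))
        truth_means.append(float(mean))

    stock = []
    for j in range(spec.n_stock_replicates):
        cloud = replace(spec.cloud, singlet_fl4_mean=spec.stock_mean,
                        singlet_fl4_sd=spec.stock_sd,
                        seed=int(seeds[len(spec.roles) + j]))
        stock.append(gen_event_cloud(cloud))

    truth = {
        "true_A": spec.true_A,
        "true_B": spec.true_B,
        "stock_mean": spec.stock_mean,
        "dilution": spec.dilution,
        "mass_ratio": spec.mass_ratio,
        "roles": list(spec.roles),
        "concentrations": list(spec.concentrations),
        "channel_concentrations": [channel_concentration(spec, i)
                                   for i in range(len(spec.roles))],
        "channel_fl4_means": truth_means,
    }
    return channels, stock, truth


def gen_bead_positions(n: int, channel: ChannelGeometry, seed: int = 0,
                       bead_radius_um: float = 1.5,
                       axial_fraction: float = 1.0) -> np.ndarray:
    """Uniform bead positions in the duct, outside the wire envelope.

    Returns (n, 3) um positions (x, z cross-section, y axial in
    [0, axial_fraction * length]).  Rejection sampling keeps the
    cross-sectional density uniform.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    rho_min = channel.wire_outer_radius + bead_radius_um
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        todo = n - filled
        x = rng.uniform(-channel.width / 2 + bead_radius_um,
                        channel.width / 2 - bead_radius_um, todo)
        z = rng.uniform(-channel.height / 2 + bead_radius_um,
                        channel.height / 2 - bead_radius_um, todo)
        y = rng.uniform(0.0, axial_fraction * channel.length_um, todo)
        ok = np.hypot(x, z) > rho_min
        k = int(ok.sum())
        out[filled:filled + k] = np.column_stack([x[ok], y[ok], z[ok]])
        filled += k
    return out
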