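"""Pump/valve protocol model: duty-cycled multiplexing over five channels.

A single syringe pump feeds a distribution valve that cycles across the
channel ports with period T, so each channel sees the full pump rate Q0
for T and rests for (n_ports - 1) * T; the time-averaged per-channel
rate is Q0 / n_ports.  The default step table is the twelve-step assay
protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProtocolStep",
    "PumpProgram",
    "default_protocol",
    "average_channel_rate",
    "extraction_rate",
    "total_assay_time",
    "schedule_timeline",
    "delivered_volume",
    "load_protocol_csv",
    "save_protocol_csv",
]

MODES = ("infuse", "withdraw", "withdraw-then-infuse", "manual")


@dataclass(frozen=True)
class ProtocolStep:
    index: int
    name: str
    mode: str
    volume_per_channel: float  # uL
    duration: float            # min

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.volume_per_channel < 0:
            raise ValueError("volume must be >= 0")


@dataclass(frozen=True)
class PumpProgram:
    """Syringe pump + distribution valve settings."""

    base_rate: float = 50.0   # Q0, uL/min
    valve_period: float = 3.0  # T, s
    n_ports: int = 5
    extraction_multiplier: float = 6.0  # Qf = multiplier * Q0
    dead_volume: float = 350.0  # per buffer line, uL

    def __post_init__(self):
        if self.base_rate < 0:
            raise ValueError("base_rate must be >= 0")
        if self.valve_period <= 0:
            raise ValueError("valve_period must be > 0")
        if self.n_ports < 1:
            raise ValueError("n_ports must be >= 1")


def default_protocol() -> list[ProtocolStep]:
    """The twelve-step assay protocol (durations sum to 151 min)."""
    rows = [
        (1, "Initial filling", "manual", 1000.0, 5),
        (2, "Air priming", "withdraw", 50.0, 3),
        (3, "Magnetic functionalization", "manual", 15.0, 3),
        (4, "Wash #1", "infuse", 300.0, 10),
        (5, "Sample incubation", "withdraw-then-infuse", 300.0, 30),
        (6, "Wash #2", "infuse", 300.0, 10),
        (7, "Detection antibody", "withdraw-then-infuse", 300.0, 30),
        (8, "Wash #3", "infuse", 300.0, 10),
        (9, "Fluorescence labeling", "withdraw-then-infuse", 150.0, 15),
        (10, "Wash #4", "infuse", 300.0, 10),
        (11, "Bead extraction", "withdraw-then-infuse", 300.0, 15),
        (12, "Quantification", "manual", 0.0, 10),
    ]
    return [ProtocolStep(i, n, m, v, d) for i, n, m, v, d in rows]


def average_channel_rate(program: PumpProgram) -> float:
    """Time-averaged per-channel rate Q0 / n_ports in uL/min."""
    return program.base_rate / program.n_ports


def extraction_rate(program: PumpProgram) -> float:
    """Bead extraction rate Qf = 6 * Q0 in uL/min."""
    return program.extraction_multiplier * program.base_rate


def total_assay_time(steps: list[ProtocolStep]) -> float:
    """Sum of step durations in minutes."""
    if not steps:
        raise ValueError("step list is empty")
    if any(s.duration < 0 for s in steps):
        raise ValueError("negative step duration")
    return float(sum(s.duration for s in steps))


def schedule_timeline(steps: list[ProtocolStep],
                      program: PumpProgram) -> pd.DataFrame:
    """Piecewise-constant per-channel flow profile.

    Returns a DataFrame with columns (t_start_s, t_end_s, channel,
    rate_uL_min, step).  During pumped steps, channel c receives the
    full rate for one valve period out of every n_ports; manual steps
    produce no flow.  Withdraw segments carry negative rates; the
    withdraw-then-infuse mode splits the step in half.
    """
    rows = []
    t0 = 0.0
    n = program.n_ports
    T = program.valve_period
    for step in steps:
        dur_s = step.duration * 60.0
        if step.mode != "manual" and program.base_rate > 0:
            phases = [(step.mode, t0, t0 + dur_s)]
            if step.mode == "withdraw-then-infuse":
                mid = t0 + dur_s / 2.0
                phases = [("withdraw", t0, mid), ("infuse", mid, t0 + dur_s)]
            for mode, a, b in phases:
                sign = -1.0 if mode == "withdraw" else 1.0
                t = a
                while t < b - 1e-9:
                    cycle_pos = (t - a) % (n * T)
                    chan = int(cycle_pos // T) % n
                    t_next = min(t + (T - cycle_pos % T), b)
                    rows.append((t, t_next, chan, sign * program.base_rate,
                                 step.index))
                    t = t_next
        t0 += dur_s
    return pd.DataFrame(rows, columns=["t_start_s", "t_end_s", "channel",
                                       "rate_uL_min", "step"])


def delivered_volume(timeline: pd.DataFrame, channel: int | None = None,
                     signed: bool = True) -> float:
    """Integrate a timeline into delivered volume (uL).

    ``channel=None`` sums over all channels (the syringe-side balance).
    """
    df = timeline if channel is None else timeline[timeline["channel"] == channel]
    dt_min = (df["t_end_s"] - df["t_start_s"]) / 60.0
    rates = df["rate_uL_min"] if signed else df["rate_uL_min"].abs()
    return float((rates * dt_min).sum())


# ---------------------------------------------------------------------------
# protocol table IO (CSV mirroring the published table columns)
# ---------------------------------------------------------------------------

def save_protocol_csv(steps: list[ProtocolStep], path) -> None:
    df = pd.DataFrame(
        [(s.index, s.name, s.mode, s.volume_per_channel, s.duration) for s in steps],
        columns=["index", "step", "mode", "volume_uL_per_channel", "time_min"],
    )
    df.to_csv(path, index=False)


def load_protocol_csv(path) -> list[ProtocolStep]:
    df = pd.read_csv(path)
    return [
        ProtocolStep(int(r["index"]), str(r["step"]), str(r["mode"]),
                     float(r["volume_uL_per_channel"]), float(r["time_min"]))
        for _, r in df.iterrows()
    ]
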