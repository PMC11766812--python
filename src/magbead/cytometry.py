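"""Event-table ingestion, polygonal gating and doublet-corrected means.

The quantification reads three numbers from a gated scatter plot: the
event count N_tot and mean fluorescence I_FL4 inside a gate G1 holding
singlets and doublets, and the doublet count N_2 in a sub-gate G2.  The
per-bead mean is then N_tot * I_FL4 / (N_tot + N_2), since each doublet
event carries the fluorescence of two beads.  Stock-bead background is
subtracted afterwards.

Gate membership is boundary-inclusive so that grid-valued synthetic
events behave deterministically.  The mean is the arithmetic mean of
FL4 (required for the bead-conservation identity of the correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from ._fcs import FCSFormatError, read_fcs, write_fcs

__all__ = [
    "EventTable",
    "Gate",
    "GatingResult",
    "BackgroundReference",
    "apply_gate",
    "gate_events",
    "doublet_corrected_mean",
    "background_subtract",
    "read_events",
    "write_events",
    "FCSFormatError",
]

REQUIRED_COLUMNS = ("FSC", "SSC", "FL4")


@dataclass(frozen=True)
class EventTable:
    """Cytometry events with FSC/SSC scatter and FL4 fluorescence (ERF)."""

    df: pd.DataFrame
    sample_id: str = ""
    fl4_channel: str = "FL4"

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise FCSFormatError(f"event table missing column(s): {missing}")
        values = self.df[list(REQUIRED_COLUMNS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("event intensities must be finite")
        if np.any(self.df["FL4"].to_numpy(dtype=float) < 0):
            raise ValueError("FL4 must be >= 0")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def fl4(self) -> np.ndarray:
        return self.df["FL4"].to_numpy(dtype=float)

    @classmethod
    def from_arrays(cls, fsc, ssc, fl4, sample_id: str = "") -> "EventTable":
        df = pd.DataFrame({"FSC": np.asarray(fsc, dtype=float),
                           "SSC": np.asarray(ssc, dtype=float),
                           "FL4": np.asarray(fl4, dtype=float)})
        return cls(df, sample_id=sample_id)


@dataclass(frozen=True)
class Gate:
    """Named simple polygon in the FSC-SSC plane."""

    name: str
    vertices: tuple

    def __post_init__(self):
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
            raise ValueError("gate needs >= 3 (FSC, SSC) vertices")
        object.__setattr__(self, "vertices", tuple(map(tuple, verts)))
        poly = shapely.Polygon(verts)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(f"gate {self.name!r} polygon is degenerate or "
                             "self-intersecting")

    @property
    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)

    def contains(self, fsc, ssc) -> np.ndarray:
        """Boundary-inclusive membership, vectorized."""
        pts = shapely.points(np.column_stack([np.asarray(fsc, dtype=float),
                                              np.asarray(ssc, dtype=float)]))
        return shapely.covers(self.polygon, pts)


@dataclass(frozen=True)
class GatingResult:
    """The three gated quantities feeding the doublet correction."""

    N_tot: int
    I_FL4: float  # mean FL4 inside G1; nan when the gate is empty
    N_2: int

    def __post_init__(self):
        if self.N_tot < 0 or self.N_2 < 0:
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class BackgroundReference:
    """Mean stock-bead fluorescence from replicate measurements."""

    I_stock: float
    n_replicates: int

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("need at least one stock replicate")

    @classmethod
    def from_replicates(cls, means) -> "BackgroundReference":
        means = np.asarray(means, dtype=float)
        return cls(float(means.mean()), int(means.size))


def apply_gate(events: EventTable, gate: Gate) -> tuple[EventTable, int]:
    """Events inside (or on the boundary of) the gate, with their count."""
    mask = gate.contains(events.df["FSC"], events.df["SSC"])
    sub = EventTable(events.df[mask].reset_index(drop=True),
                     sample_id=events.sample_id)
    return sub, int(mask.sum())


def gate_events(events: EventTable, g1: Gate, g2: Gate) -> GatingResult:
    """Evaluate N_tot, I_FL4 and N_2 for the two-gate readout."""
    inside1, n_tot = apply_gate(events, g1)
    _, n_2 = apply_gate(events, g2)
    mean = float(inside1.fl4.mean()) if n_tot else float("nan")
    return GatingResult(n_tot, mean, n_2)


def doublet_corrected_mean(result: GatingResult) -> float:
    """Per-bead mean fluorescence N_tot * I_FL4 / (N_tot + N_2)."""
    denom = result.N_tot + result.N_2
    if denom == 0:
        raise ValueError("doublet correction undefined: no events in the gates")
    return result.N_tot * result.I_FL4 / denom


def background_subtract(corrected: float, reference: BackgroundReference,
                        clip_negative: bool = False) -> float:
    """Subtract the stock-bead background from the per-bead mean.

    Negative results are reported as-is by default so the (0, 0)
    calibration anchor stays unbiased; set ``clip_negative`` to floor
    at zero.
    """
    value = corrected - reference.I_stock
    return max(value, 0.0) if clip_negative else value


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_events(events: EventTable, path, fmt: str | None = None,
                 channel_map: dict | None = None) -> None:
    path = Path(path)
    fmt = fmt or ("fcs" if path.suffix.lower() == ".fcs" else "csv")
    df = events.df[list(REQUIRED_COLUMNS)]
    if channel_map:
        df = df.rename(columns=channel_map)
    if fmt == "csv":
        df.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "fcs":
        write_fcs(path, df)
    else:
        raise ValueError(f"unknown event-table format {fmt!r}")


def read_events(path, fmt: str | None = None,
                channel_map: dict | None = None,
                sample_id: str | None = None) -> EventTable:
    """Read an event table from CSV or FCS.

    ``channel_map`` maps instrument channel names onto the canonical
    columns, e.g. ``{"FSC-H": "FSC", "SSC-H": "SSC", "FL4-H": "FL4"}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or ("fcs" if path.suffix.lower() == ".fcs" else "csv")
    if fmt == "csv":
        try:
            # round-trip parsing keeps write->read bit-exact
            df = pd.read_csv(path, float_precision="round_trip")
        except pd.errors.EmptyDataError as exc:
            raise FCSFormatError(f"{path}: empty event file") from exc
    elif fmt == "fcs":
        _, df = read_fcs(path)
    else:
        raise ValueError(f"unknown event-table format {fmt!r}")
    if channel_map:
        df = df.rename(columns=channel_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FCSFormatError(
            f"{path}: missing channel column(s) {missing}; available: "
            f"{list(df.columns)}")
    return EventTable(df[list(REQUIRED_COLUMNS)].copy(),
                      sample_id=sample_id or path.stem)
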