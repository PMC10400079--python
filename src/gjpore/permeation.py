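"""Ion compartment-crossing detection with hysteresis and permeation
statistics across replicates.

The channel axis is split into four stations by three boundary planes
(HC1 cytosolic boundary, junction midplane, HC2 cytosolic boundary):

    station 0 | z_cyt1 | station 1 | z_mid | station 2 | z_cyt2 | station 3

Each plane is widened into a buffer band of half-width ``hysteresis``;
an ion is *confirmed* in a station only while it sits outside every
band.  A hemichannel event is a traversal between the two planes that
bound it (confirmed-station pattern 0-1-2 or 2-1-0 for HC1, 1-2-3 or
3-2-1 for HC2); a full gap-junction (GJC) event is a continuous
cytosol-to-cytosol passage (0-1-2-3 or 3-2-1-0), which by construction
also contains one HC1 and one HC2 traversal.  Oscillations inside a
buffer band register nothing, which suppresses thermal re-crossings.

Ion z coordinates must be unwrapped (``gjpore.core.unwrapped_z``)
before detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AxisFrame, CompartmentSpec, SimulationMeta, Trajectory, unwrapped_z

__all__ = ["CrossingEvent", "PermeationTable", "detect_events", "summarize_events"]


@dataclass(frozen=True)
class CrossingEvent:
    ion_id: int
    species: str
    kind: str  # "HC1" | "HC2" | "GJC"
    direction: str  # "forward" (+z) | "backward" (-z)
    t_enter: float  # ps
    t_exit: float  # ps

    def __post_init__(self):
        if self.t_enter >= self.t_exit:
            raise ValueError("t_enter must precede t_exit")


@dataclass
class PermeationTable:
    """Mean +/- SD event counts per replicate, keyed by
    (voltage, compartment, species)."""

    rows: pd.DataFrame  # columns: voltage_mV, compartment, species, mean, sd, n_replicates

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()

    def pivot(self) -> pd.DataFrame:
        """Layout with one row per voltage and HC1/HC2/GJC x species columns."""
        wide = self.rows.pivot_table(
            index="voltage_mV",
            columns=["compartment", "species"],
            values=["mean", "sd"],
            aggfunc="first",
        )
        return wide


def _station_codes(z: np.ndarray, comp: CompartmentSpec) -> np.ndarray:
    """Confirmed station per sample (-1 while inside a buffer band)."""
    h = comp.hysteresis
    b = np.array([comp.z_cyt1, comp.z_mid, comp.z_cyt2])
    out = np.full(z.shape, -1, dtype=int)
    out[z < b[0] - h] = 0
    out[(z > b[0] + h) & (z < b[1] - h)] = 1
    out[(z > b[1] + h) & (z < b[2] - h)] = 2
    out[z > b[2] + h] = 3
    return out


def _confirmed_sequence(z: np.ndarray, times: np.ndarray, comp: CompartmentSpec):
    """Compressed sequence of confirmed stations with confirmation times.

    A jump over more than one station between consecutive samples is
    expanded into the intermediate stations at linearly interpolated
    times, so traversals are never lost to coarse sampling.
    """
    codes = _station_codes(z, comp)
    seq: list[int] = []
    ts: list[float] = []
    prev_t = None
    for c, t in zip(codes, times):
        if c < 0:
            continue
        if not seq:
            seq.append(int(c))
            ts.append(float(t))
        elif c != seq[-1]:
            step = 1 if c > seq[-1] else -1
            missing = list(range(seq[-1] + step, c, step))
            base_t = prev_t if prev_t is not None else ts[-1]
            k = len(missing) + 1
            for j, m in enumerate(missing, start=1):
                seq.append(m)
                ts.append(base_t + (t - base_t) * j / k)
            seq.append(int(c))
            ts.append(float(t))
        prev_t = float(t)
    return seq, ts


_HC_PATTERNS = {
    (0, 1, 2): ("HC1", "forward"),
    (2, 1, 0): ("HC1", "backward"),
    (1, 2, 3): ("HC2", "forward"),
    (3, 2, 1): ("HC2", "backward"),
}


def _events_from_sequence(seq, ts, ion_id: int, species: str) -> list[CrossingEvent]:
    events = []
    for i in range(len(seq) - 2):
        key = tuple(seq[i : i + 3])
        if key in _HC_PATTERNS:
            kind, direction = _HC_PATTERNS[key]
            events.append(
                CrossingEvent(ion_id, species, kind, direction, ts[i + 1], ts[i + 2])
            )
    for i in range(len(seq) - 3):
        quad = tuple(seq[i : i + 4])
        if quad == (0, 1, 2, 3):
            events.append(CrossingEvent(ion_id, species, "GJC", "forward", ts[i + 1], ts[i + 3]))
        elif quad == (3, 2, 1, 0):
            events.append(CrossingEvent(ion_id, species, "GJC", "backward", ts[i + 1], ts[i + 3]))
    return events


def detect_events(
    traj: Trajectory,
    comp: CompartmentSpec,
    species: str,
    axis: AxisFrame | None = None,
) -> list[CrossingEvent]:
    """Detect all hemichannel and full-GJC crossing events for one
    species.  Both directions count; filter on ``direction`` downstream
    if needed."""
    width = min(comp.z_mid - comp.z_cyt1, comp.z_cyt2 - comp.z_mid)
    if 2 * comp.hysteresis >= width:
        raise ValueError(
            f"hysteresis band (2x{comp.hysteresis} A) swallows a compartment "
            f"of width {width} A"
        )
    z = unwrapped_z(traj, species, axis=axis)
    times = np.array([f.time for f in traj.frames])
    events: list[CrossingEvent] = []
    for ion in range(z.shape[1]):
        seq, ts = _confirmed_sequence(z[:, ion], times, comp)
        events.extend(_events_from_sequence(seq, ts, ion, species))
    events.sort(key=lambda e: (e.t_enter, e.ion_id, e.kind))
    return events


def events_to_frame(events: list[CrossingEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ion_id": e.ion_id,
                "species": e.species,
                "kind": e.kind,
                "direction": e.direction,
                "t_enter_ps": e.t_enter,
                "t_exit_ps": e.t_exit,
            }
            for e in events
        ],
        columns=["ion_id", "species", "kind", "direction", "t_enter_ps", "t_exit_ps"],
    )


def summarize_events(
    events_per_replicate: list[list[CrossingEvent]],
    metas: list[SimulationMeta],
) -> PermeationTable:
    """Mean and sample SD of per-replicate event counts, grouped by the
    applied voltage recorded in each replicate's metadata."""
    if len(events_per_replicate) != len(metas):
        raise ValueError(
            f"{len(events_per_replicate)} event lists but {len(metas)} metadata records"
        )
    records = []
    for events, meta in zip(events_per_replicate, metas):
        counts: dict[tuple, int] = {}
        for e in events:
            counts[(e.kind, e.species)] = counts.get((e.kind, e.species), 0) + 1
        species_seen = {e.species for e in events} | set(meta.species_charges)
        for kind in ("HC1", "HC2", "GJC"):
            for sp in sorted(species_seen):
                records.append(
                    {
                        "voltage_mV": meta.applied_voltage,
                        "replicate_id": meta.replicate_id,
                        "compartment": kind,
                        "species": sp,
                        "count": counts.get((kind, sp), 0),
                    }
                )
    df = pd.DataFrame(records)
    grouped = (
        df.groupby(["voltage_mV", "compartment", "species"])["count"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"std": "sd", "count": "n_replicates"})
    )
    grouped["sd"] = grouped["sd"].fillna(0.0)  # single replicate -> sd 0, n=1
    return PermeationTable(rows=grouped)
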