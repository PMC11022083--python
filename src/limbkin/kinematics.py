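"""Segment kinematics and block statistics.

This module re-implements the analysis stage of the pipeline: within each
triggered event the user (or, headless, the defaults) selects a segment;
acceleration over the segment is integrated to velocity and displacement
by the cumulative trapezoid rule with v(start) = s(start) = 0; minima,
maxima and means are reported for all three quantities on the x, y and z
components and on the per-sample vector magnitude. Per-event peak
acceleration, its per-block mean ± SD and the percent change of the last
block's mean relative to the first are the quantities used to track motor
practice across a session.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .conditioning import UncalibratedDataError, magnitude
from .model import Block, Event, Recording

COMPONENTS = ("x", "y", "z", "abs")
_QUANTITIES = ("acceleration", "velocity", "displacement")


class SelectionError(ValueError):
    """A segment selection does not fit its event."""


@dataclass(frozen=True)
class SegmentSelection:
    """Half-open sample-index window [start_idx, end_idx) inside one event."""

    block_id: int
    event_id: int
    start_idx: int
    end_idx: int

    def validate(self, event: Event) -> None:
        if not 0 <= self.start_idx < self.end_idx <= event.n_samples:
            raise SelectionError(
                f"selection [{self.start_idx}, {self.end_idx}) invalid for event "
                f"(block {event.block_id}, event {event.event_id}) of "
                f"{event.n_samples} samples"
            )


@dataclass
class SegmentAnalysis:
    """Kinematic series and summary statistics over one selected segment.

    ``acceleration`` (m/s²), ``velocity`` (m/s) and ``displacement`` (m)
    are DataFrames with one row per sample and columns x, y, z, abs (the
    per-sample vector magnitude). ``summary`` holds min/max/mean for each
    of the 12 quantity × component combinations, indexed by
    (quantity, component).
    """

    selection: SegmentSelection
    acceleration: pd.DataFrame
    velocity: pd.DataFrame
    displacement: pd.DataFrame
    summary: pd.DataFrame


@dataclass
class BlockStats:
    """Per-block summary of event peak accelerations (m/s²).

    ``sd_peak`` is the sample standard deviation (n−1 denominator); it is
    ``None`` for blocks with fewer than two events.
    """

    block_id: int
    event_peaks: list[float]
    mean_peak: float
    sd_peak: float | None

    @property
    def n_events(self) -> int:
        return len(self.event_peaks)


def _with_abs(vec: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x": vec[:, 0],
            "y": vec[:, 1],
            "z": vec[:, 2],
            "abs": magnitude(vec),
        }
    )


def analyze_segment(event: Event, sel: SegmentSelection, dt: float) -> SegmentAnalysis:
    """Integrate a selected segment to velocity and displacement.

    ``dt`` is the sample period (1 / sampling rate) in seconds. Velocity
    is the cumulative trapezoidal integral of acceleration starting from
    v = 0 at the segment start; displacement integrates velocity from
    s = 0 likewise — the selected segment is assumed to begin at rest. The
    abs column of each quantity is the per-sample magnitude of its vector
    components.
    """
    sel.validate(event)
    if dt <= 0:
        raise SelectionError(f"dt must be positive, got {dt}")
    a = event.accel[sel.start_idx : sel.end_idx]
    v = cumulative_trapezoid(a, dx=dt, axis=0, initial=0.0)
    s = cumulative_trapezoid(v, dx=dt, axis=0, initial=0.0)
    frames = {
        "acceleration": _with_abs(a),
        "velocity": _with_abs(v),
        "displacement": _with_abs(s),
    }
    rows = []
    for quantity in _QUANTITIES:
        df = frames[quantity]
        for comp in COMPONENTS:
            col = df[comp]
            rows.append(
                {
                    "quantity": quantity,
                    "component": comp,
                    "min": col.min(),
                    "max": col.max(),
                    "mean": col.mean(),
                }
            )
    summary = pd.DataFrame(rows).set_index(["quantity", "component"])
    return SegmentAnalysis(
        selection=sel,
        acceleration=frames["acceleration"],
        velocity=frames["velocity"],
        displacement=frames["displacement"],
        summary=summary,
    )


def event_peak(
    event: Event,
    component: str = "abs",
    selection: SegmentSelection | None = None,
) -> float:
    """Peak acceleration of one event, in m/s².

    The default component is the per-sample vector magnitude ("abs"), the
    only rotation-invariant choice; an axis name returns the (signed)
    maximum of that axis instead. The signal is assumed to be
    offset-calibrated already. An optional selection restricts the peak
    search to a sub-window.
    """
    if event.n_samples == 0:
        raise SelectionError("cannot take the peak of an empty event")
    if component not in COMPONENTS:
        raise SelectionError(f"component must be one of {COMPONENTS}")
    a = event.accel
    if selection is not None:
        selection.validate(event)
        a = a[selection.start_idx : selection.end_idx]
    if component == "abs":
        return float(magnitude(a).max())
    return float(a[:, {"x": 0, "y": 1, "z": 2}[component]].max())


def block_stats(
    block: Block,
    component: str = "abs",
    selections: dict[int, SegmentSelection] | None = None,
) -> BlockStats:
    """Mean and sample SD (n−1) of the event peak accelerations in a block."""
    if block.n_events == 0:
        raise SelectionError(f"block {block.block_id} contains no events")
    peaks = [
        event_peak(e, component, (selections or {}).get(e.event_id))
        for e in block.events
    ]
    arr = np.asarray(peaks)
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
    return BlockStats(
        block_id=block.block_id,
        event_peaks=peaks,
        mean_peak=float(arr.mean()),
        sd_peak=sd,
    )


def percent_change(first: BlockStats, last: BlockStats) -> float:
    """Change of the last block's mean peak relative to the first, in percent.

    ``(last.mean_peak − first.mean_peak) / first.mean_peak × 100`` — the
    session-level index of motor practice.
    """
    if first.mean_peak <= 0:
        raise ValueError(
            f"baseline mean peak must be positive, got {first.mean_peak:g}"
        )
    return (last.mean_peak - first.mean_peak) / first.mean_peak * 100.0


def peaks_by_block(
    rec: Recording,
    component: str = "abs",
    selections: dict[tuple[int, int], SegmentSelection] | None = None,
    force: bool = False,
) -> list[BlockStats]:
    """Per-block peak statistics for a whole recording.

    Refuses to run on a recording whose static (offset + gravity) level
    has not been removed — otherwise the peaks would measure sensor
    orientation, not movement — unless ``force=True``.
    """
    if not rec.meta.calibrated and not force:
        raise UncalibratedDataError(
            "recording is not offset-calibrated; run "
            "limbkin.conditioning.calibrate_recording first or pass force=True"
        )
    stats = []
    for block in rec.blocks:
        per_block = None
        if selections:
            per_block = {
                eid: sel
                for (bid, eid), sel in selections.items()
                if bid == block.block_id
            }
        stats.append(block_stats(block, component, per_block))
    return stats


def export_stats(stats: list[BlockStats], path: str | Path) -> tuple[Path, Path]:
    """Write block summaries and the per-event peak table as TSV.

    ``<path>`` receives one row per block (block_id, n_events, mean_peak,
    sd_peak); a companion ``<stem>.events.tsv`` receives one row per event
    (block_id, event_id, peak). Values are written to 6 decimals.
    """
    path = Path(path)
    events_path = path.with_name(path.stem + ".events.tsv")
    summary = pd.DataFrame(
        [
            {
                "block_id": s.block_id,
                "n_events": s.n_events,
                "mean_peak": s.mean_peak,
                "sd_peak": np.nan if s.sd_peak is None else s.sd_peak,
            }
            for s in stats
        ],
        columns=["block_id", "n_events", "mean_peak", "sd_peak"],
    )
    summary.to_csv(path, sep="\t", index=False, float_format="%.6f")
    events = pd.DataFrame(
        [
            {"block_id": s.block_id, "event_id": i, "peak": p}
            for s in stats
            for i, p in enumerate(s.event_peaks)
        ],
        columns=["block_id", "event_id", "peak"],
    )
    events.to_csv(events_path, sep="\t", index=False, float_format="%.6f")
    return path, events_path
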