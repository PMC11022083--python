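"""Core domain types for limb-acceleration recordings.

The recording hierarchy mirrors how triggered accelerometer experiments are
organised in the field:

* **sample** — one time point of 3-axis acceleration (plus optional raw
  sensor counts and die temperature),
* **event** — the fixed-length window recorded after one trigger (one beep
  or one external pulse; 1 s in the reference protocol),
* **block** — a session of consecutive events, separated from the next
  block by a pause.

Acceleration is always stored in m/s²; the gravitational constant is fixed
at ``G0 = 9.81`` m/s² throughout the package. Raw integer sensor counts, if
present, are kept alongside, never converted in place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Iterator

import numpy as np

#: Gravitational acceleration used for all unit conversions, m/s².
G0 = 9.81

_AXES = ("x", "y", "z")
_MODES = ("free_running", "acoustic", "external_trigger")
_EDGES = ("rising", "falling")
_MARKERS = ("", "break", "delay")


class ValidationError(ValueError):
    """A recording violates a structural invariant."""


class ConfigError(ValueError):
    """A hardware or protocol configuration is inconsistent."""


@dataclass(frozen=True)
class Sample:
    """One time point: IDs, time since recording start, and acceleration.

    ``raw`` (integer sensor counts) and ``temperature`` (°C) are optional
    and absent — not zero — when the source did not record them.
    """

    sample_id: int
    block_id: int
    event_id: int
    t: float
    a: tuple[float, float, float]
    raw: tuple[int, int, int] | None = None
    temperature: float | None = None


@dataclass(frozen=True)
class HardwareConfig:
    """Sensor/controller settings.

    Parameters
    ----------
    range_g : int
        Full-scale acceleration range in g; the sensor supports 2, 4 or 8.
    sampling_rate_hz : float
        Sample rate, 4 Hz to 4 kHz.
    highpass_enabled, highpass_cutoff_hz :
        Optional first-order high-pass applied by the conditioning stage.
    beep_duration_ms : float
        Duration of the cue beep (metadata only; no audio is modelled).
    trigger_edge : str
        ``"rising"`` or ``"falling"`` edge on the external trigger input.
    """

    range_g: int = 8
    sampling_rate_hz: float = 1000.0
    highpass_enabled: bool = False
    highpass_cutoff_hz: float = 0.1
    beep_duration_ms: float = 50.0
    trigger_edge: str = "rising"

    def __post_init__(self) -> None:
        if self.range_g not in (2, 4, 8):
            raise ConfigError(f"range_g must be 2, 4 or 8, got {self.range_g}")
        if not 4.0 <= self.sampling_rate_hz <= 4000.0:
            raise ConfigError(
                f"sampling_rate_hz must lie in [4, 4000], got {self.sampling_rate_hz}"
            )
        if self.trigger_edge not in _EDGES:
            raise ConfigError(f"trigger_edge must be one of {_EDGES}")
        if self.highpass_enabled and self.highpass_cutoff_hz <= 0:
            raise ConfigError("highpass_cutoff_hz must be positive when enabled")


@dataclass(frozen=True)
class ProtocolConfig:
    """Acquisition-protocol settings for the three recording modes.

    ``stim_rate_mHz`` is the acoustic stimulation (beep) rate in millihertz
    — 500 mHz is one beep every 2 s. ``event_samples`` samples are recorded
    after every trigger; events must not overlap, i.e.
    ``event_samples / sampling_rate_hz <= 1000 / stim_rate_mHz``.
    """

    mode: str = "acoustic"
    stim_rate_mHz: float = 500.0
    block_duration_s: float = 60.0
    pause_s: float = 60.0
    repetitions: int = 6
    event_samples: int = 1000
    sampling_rate_hz: float = 1000.0
    trigger_edge: str = "rising"
    beep_on_trigger: bool = True

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ConfigError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.event_samples < 1:
            raise ConfigError("event_samples must be >= 1")
        if self.repetitions < 1:
            raise ConfigError("repetitions must be >= 1")
        if self.sampling_rate_hz <= 0:
            raise ConfigError("sampling_rate_hz must be positive")
        if self.trigger_edge not in _EDGES:
            raise ConfigError(f"trigger_edge must be one of {_EDGES}")
        if self.mode == "acoustic":
            if self.stim_rate_mHz <= 0:
                raise ConfigError("stim_rate_mHz must be > 0 in acoustic mode")
            if self.pause_s < 0:
                raise ConfigError("pause_s must be >= 0")
            period_s = 1000.0 / self.stim_rate_mHz
            if self.event_samples / self.sampling_rate_hz > period_s * (1 + 1e-12):
                raise ConfigError(
                    "events overlap: event duration "
                    f"{self.event_samples / self.sampling_rate_hz:g} s exceeds the "
                    f"inter-stimulus interval {period_s:g} s"
                )

    @property
    def event_duration_s(self) -> float:
        return self.event_samples / self.sampling_rate_hz


class Event:
    """One triggered recording window.

    Samples are held column-wise as numpy arrays for efficiency; the
    row-wise :class:`Sample` view is available via :meth:`samples`.

    Parameters
    ----------
    event_id, block_id : int
        0-based IDs; ``event_id`` is contiguous within its block.
    sample_ids : ndarray of int
        Globally increasing sample IDs.
    t : ndarray
        Seconds since recording start, one per sample.
    accel : ndarray, shape (n, 3)
        Acceleration in m/s², axes x, y, z.
    raw : ndarray of int, shape (n, 3), optional
        Raw sensor counts.
    temperature : ndarray, shape (n,), optional
        Sensor die temperature, °C.
    trigger_time : datetime, optional
        Wall clock of the trigger; by convention equal to the wall-clock
        stamp of the event's first sample.
    """

    def __init__(
        self,
        event_id: int,
        block_id: int,
        sample_ids: np.ndarray,
        t: np.ndarray,
        accel: np.ndarray,
        raw: np.ndarray | None = None,
        temperature: np.ndarray | None = None,
        trigger_time: datetime | None = None,
    ) -> None:
        self.event_id = int(event_id)
        self.block_id = int(block_id)
        self.sample_ids = np.asarray(sample_ids, dtype=np.int64)
        self.t = np.asarray(t, dtype=np.float64)
        self.accel = np.asarray(accel, dtype=np.float64)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValidationError(
                f"event {event_id}: accel must have shape (n, 3), got {self.accel.shape}"
            )
        n = self.accel.shape[0]
        if self.sample_ids.shape != (n,) or self.t.shape != (n,):
            raise ValidationError(f"event {event_id}: sample_ids/t/accel lengths differ")
        self.raw = None if raw is None else np.asarray(raw, dtype=np.int64)
        if self.raw is not None and self.raw.shape != (n, 3):
            raise ValidationError(f"event {event_id}: raw must have shape (n, 3)")
        self.temperature = (
            None if temperature is None else np.asarray(temperature, dtype=np.float64)
        )
        if self.temperature is not None and self.temperature.shape != (n,):
            raise ValidationError(f"event {event_id}: temperature must have shape (n,)")
        self.trigger_time = trigger_time

    @property
    def n_samples(self) -> int:
        return self.accel.shape[0]

    def samples(self) -> Iterator[Sample]:
        for i in range(self.n_samples):
            yield Sample(
                sample_id=int(self.sample_ids[i]),
                block_id=self.block_id,
                event_id=self.event_id,
                t=float(self.t[i]),
                a=tuple(float(v) for v in self.accel[i]),
                raw=None if self.raw is None else tuple(int(v) for v in self.raw[i]),
                temperature=None if self.temperature is None else float(self.temperature[i]),
            )

    def with_accel(self, accel: np.ndarray) -> "Event":
        return Event(
            self.event_id,
            self.block_id,
            self.sample_ids,
            self.t,
            accel,
            raw=self.raw,
            temperature=self.temperature,
            trigger_time=self.trigger_time,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Event):
            return NotImplemented

        def _opt_eq(a, b):
            if a is None or b is None:
                return a is None and b is None
            return np.array_equal(a, b)

        return (
            self.event_id == other.event_id
            and self.block_id == other.block_id
            and np.array_equal(self.sample_ids, other.sample_ids)
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.accel, other.accel)
            and _opt_eq(self.raw, other.raw)
            and _opt_eq(self.temperature, other.temperature)
            and self.trigger_time == other.trigger_time
        )

    def __repr__(self) -> str:
        return (
            f"Event(block_id={self.block_id}, event_id={self.event_id}, "
            f"n_samples={self.n_samples})"
        )


@dataclass
class Block:
    """One session of consecutive events."""

    block_id: int
    events: list[Event] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass
class RecordingMeta:
    """Subject, hardware and protocol metadata attached to a recording.

    ``calibrated`` records whether the static (offset + gravity) component
    has been removed from the acceleration channels, which downstream peak
    analysis requires.
    """

    subject: dict[str, str] = field(default_factory=dict)
    n_blocks: int = 0
    n_events: int = 0
    hardware: HardwareConfig | None = None
    protocol: ProtocolConfig | None = None
    created: datetime | None = None
    calibrated: bool = False


class Recording:
    """Ordered blocks of events plus metadata and per-sample wall clock.

    ``timestamps`` is one ``datetime64[ms]`` per sample; ``markers`` is a
    parallel list of ``""``, ``"break"`` (first sample after an inter-block
    pause) or ``"delay"``, so that breaks and trigger delays remain visible
    in the stored data.
    """

    def __init__(
        self,
        blocks: list[Block],
        meta: RecordingMeta,
        timestamps: np.ndarray | None = None,
        markers: list[str] | None = None,
    ) -> None:
        self.blocks = blocks
        self.meta = meta
        self.timestamps = (
            None if timestamps is None else np.asarray(timestamps, dtype="datetime64[ms]")
        )
        self.markers = markers

    # -- aggregate views -------------------------------------------------
    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_events(self) -> int:
        return sum(b.n_events for b in self.blocks)

    @property
    def n_samples(self) -> int:
        return sum(e.n_samples for b in self.blocks for e in b.events)

    def iter_events(self) -> Iterator[Event]:
        for block in self.blocks:
            yield from block.events

    def map_accel(self, fn) -> "Recording":
        """Return a copy with ``fn(event) -> accel`` applied to every event."""
        new_blocks = [
            Block(b.block_id, [e.with_accel(fn(e)) for e in b.events]) for b in self.blocks
        ]
        return Recording(
            new_blocks, replace(self.meta), timestamps=self.timestamps, markers=self.markers
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented

        def _ts_eq(a, b):
            if a is None or b is None:
                return a is None and b is None
            return np.array_equal(a, b)

        return (
            [b.block_id for b in self.blocks] == [b.block_id for b in other.blocks]
            and all(
                sb.events == ob.events for sb, ob in zip(self.blocks, other.blocks)
            )
            and self.meta == other.meta
            and _ts_eq(self.timestamps, other.timestamps)
            and (self.markers or None) == (other.markers or None)
        )

    def __repr__(self) -> str:
        return (
            f"Recording(n_blocks={self.n_blocks}, n_events={self.n_events}, "
            f"n_samples={self.n_samples})"
        )


def _events_per_block_expected(protocol: ProtocolConfig) -> int | None:
    if protocol.mode != "acoustic":
        return None
    return math.floor(protocol.block_duration_s * protocol.stim_rate_mHz / 1000.0 + 1e-9)


def validate_recording(rec: Recording) -> list[str]:
    """Check every structural invariant; return all violations found.

    An empty list means the recording is valid. This never raises on
    content problems — it is the single source of truth the reader and
    writer both consult.
    """
    problems: list[str] = []
    expected_sid = 0
    prev_block = -1
    for block in rec.blocks:
        if block.block_id != prev_block + 1:
            problems.append(
                f"block_id {block.block_id} breaks 0-based contiguity "
                f"(expected {prev_block + 1})"
            )
        prev_block = block.block_id
        prev_event = -1
        for event in block.events:
            label = f"event (block {block.block_id}, event {event.event_id})"
            if event.block_id != block.block_id:
                problems.append(f"{label}: block_id mismatch with enclosing block")
            if event.event_id != prev_event + 1:
                problems.append(
                    f"{label}: event_id breaks 0-based contiguity within block "
                    f"(expected {prev_event + 1})"
                )
            prev_event = event.event_id
            if event.n_samples == 0:
                problems.append(f"{label}: contains no samples")
            sids = event.sample_ids
            if sids.size and (
                sids[0] != expected_sid or not np.array_equal(sids, np.arange(sids[0], sids[0] + sids.size))
            ):
                problems.append(
                    f"{label}: sample_ids not contiguous from {expected_sid} "
                    f"(first offending sample_id {int(sids[0])})"
                )
            expected_sid += sids.size
            if not np.all(np.isfinite(event.t)):
                problems.append(f"{label}: non-finite time values")

    proto = rec.meta.protocol
    if proto is not None and proto.mode != "free_running":
        for block in rec.blocks:
            for event in block.events:
                if event.n_samples != proto.event_samples:
                    problems.append(
                        f"event (block {block.block_id}, event {event.event_id}): "
                        f"{event.n_samples} samples, protocol requires {proto.event_samples}"
                    )
        expected_epb = _events_per_block_expected(proto)
        if expected_epb is not None:
            for block in rec.blocks:
                if block.n_events != expected_epb:
                    problems.append(
                        f"block {block.block_id}: {block.n_events} events, "
                        f"protocol requires {expected_epb} per block"
                    )

    if rec.meta.n_blocks != rec.n_blocks:
        problems.append(
            f"meta.n_blocks={rec.meta.n_blocks} but recording has {rec.n_blocks} blocks"
        )
    if rec.meta.n_events != rec.n_events:
        problems.append(
            f"meta.n_events={rec.meta.n_events} but recording has {rec.n_events} events"
        )

    n_samples = rec.n_samples
    if rec.timestamps is not None and rec.timestamps.shape != (n_samples,):
        problems.append(
            f"timestamp count {rec.timestamps.shape[0]} != sample count {n_samples}"
        )
    if rec.markers is not None:
        if len(rec.markers) != n_samples:
            problems.append(
                f"marker count {len(rec.markers)} != sample count {n_samples}"
            )
        bad = {m for m in rec.markers} - set(_MARKERS)
        if bad:
            problems.append(f"unknown timestamp markers: {sorted(bad)}")
    if (rec.timestamps is None) != (rec.markers is None):
        problems.append("timestamps and markers must be provided together")
    return problems
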