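"""Stimulation-protocol scheduling and simulated acquisition.

Three acquisition modes are supported, mirroring how triggered
accelerometer experiments are run:

* **free running** — continuous recording for a fixed duration,
* **acoustic stimulation** — a beep cues the subject at a fixed rate
  (given in millihertz) and simultaneously triggers a fixed-length event;
  events are grouped into blocks separated by pauses,
* **external trigger** — an external device (e.g. a magnetic stimulator)
  supplies the trigger times.

No hardware is involved here: a *source* callable stands in for the
sensor. It receives the sample times of one event plus the event's IDs and
a seeded random generator, and returns an ``(n, 3)`` acceleration array in
m/s². Schedules depend only on the configuration; only the sample noise
produced by the source depends on the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime
from typing import Callable, Sequence

import numpy as np

from .model import (
    Block,
    ConfigError,
    Event,
    ProtocolConfig,
    Recording,
    RecordingMeta,
)

#: Signal source signature: (times_s, block_id, event_id, rng) -> (n, 3) m/s².
Source = Callable[[np.ndarray, int, int, np.random.Generator], np.ndarray]

#: Default wall-clock origin for simulated recordings (keeps output
#: byte-identical across runs with the same seed).
DEFAULT_START = datetime(2024, 1, 1, 12, 0, 0)


@dataclass(frozen=True)
class TriggerSchedule:
    """Ordered trigger plan: one ``(block_id, event_id, trigger_time_s)`` per event."""

    entries: tuple[tuple[int, int, float], ...]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def times(self) -> np.ndarray:
        return np.array([t for _, _, t in self.entries])


def events_per_block(cfg: ProtocolConfig) -> int:
    """Number of triggers that fit in one block of the acoustic protocol.

    ``floor(block_duration_s * stim_rate_mHz / 1000)``: the first beep
    fires at the block start and subsequent beeps every
    ``1000 / stim_rate_mHz`` seconds, so this is the count of beep onsets
    inside the block.
    """
    if cfg.mode != "acoustic":
        raise ConfigError(f"events_per_block requires acoustic mode, got {cfg.mode!r}")
    return math.floor(cfg.block_duration_s * cfg.stim_rate_mHz / 1000.0 + 1e-9)


def build_schedule(cfg: ProtocolConfig) -> TriggerSchedule:
    """Lay out every trigger of an acoustic-stimulation protocol.

    Block ``b`` starts at ``b * (block_duration_s + pause_s)`` seconds; the
    first trigger of a block fires at the block start and triggers within a
    block are spaced ``1000 / stim_rate_mHz`` s apart. With a single
    repetition no pause appears in the schedule.
    """
    n_per_block = events_per_block(cfg)
    period = 1000.0 / cfg.stim_rate_mHz
    entries = []
    for b in range(cfg.repetitions):
        block_start = b * (cfg.block_duration_s + cfg.pause_s)
        for e in range(n_per_block):
            entries.append((b, e, block_start + e * period))
    return TriggerSchedule(entries=tuple(entries))


def _silent(times: np.ndarray, block_id: int, event_id: int, rng) -> np.ndarray:
    return np.zeros((times.size, 3))


def _record_events(
    cfg: ProtocolConfig,
    schedule: Sequence[tuple[int, int, float]],
    source: Source,
    seed: int,
    start: datetime,
) -> Recording:
    rng = np.random.default_rng(seed)
    fs = cfg.sampling_rate_hz
    rel = np.arange(cfg.event_samples) / fs
    blocks: list[Block] = []
    timestamps: list[np.ndarray] = []
    markers: list[str] = []
    sid = 0
    cur: Block | None = None
    for bid, eid, t0 in schedule:
        times = t0 + rel
        try:
            accel = np.asarray(source(times, bid, eid, rng), dtype=np.float64)
        except Exception as exc:  # pragma: no cover - pass-through with context
            raise RuntimeError(
                f"signal source failed for block {bid}, event {eid}: {exc}"
            ) from exc
        if accel.shape != (cfg.event_samples, 3):
            raise ConfigError(
                f"source returned shape {accel.shape} for block {bid}, event {eid}; "
                f"expected ({cfg.event_samples}, 3)"
            )
        if cur is None or cur.block_id != bid:
            cur = Block(block_id=bid)
            blocks.append(cur)
            markers.extend(["break"] + [""] * (cfg.event_samples - 1) if bid else [""] * cfg.event_samples)
        else:
            markers.extend([""] * cfg.event_samples)
        stamps = (
            np.datetime64(start, "ms")
            + (np.round((t0 + rel) * 1000)).astype(np.int64).astype("timedelta64[ms]")
        )
        timestamps.append(stamps)
        cur.events.append(
            Event(
                event_id=eid,
                block_id=bid,
                sample_ids=np.arange(sid, sid + cfg.event_samples),
                t=times,
                accel=accel,
                trigger_time=stamps[0].astype("datetime64[ms]").astype(datetime),
            )
        )
        sid += cfg.event_samples
    ts = np.concatenate(timestamps) if timestamps else None
    meta = RecordingMeta(
        n_blocks=len(blocks),
        n_events=sum(b.n_events for b in blocks),
        protocol=cfg,
        created=start,
    )
    return Recording(blocks, meta, timestamps=ts, markers=markers if ts is not None else None)


def run_protocol(
    cfg: ProtocolConfig,
    source: Source = _silent,
    seed: int = 0,
    start: datetime = DEFAULT_START,
) -> Recording:
    """Simulate a full acquisition run under ``cfg``.

    Acoustic mode records one event per scheduled beep; free-running mode
    records the whole ``block_duration_s`` as a single event. The result is
    deterministic for a given seed.
    """
    if cfg.mode == "acoustic":
        schedule = build_schedule(cfg).entries
        return _record_events(cfg, schedule, source, seed, start)
    if cfg.mode == "free_running":
        n = int(round(cfg.block_duration_s * cfg.sampling_rate_hz))
        free_cfg = ProtocolConfig(
            mode="free_running",
            stim_rate_mHz=cfg.stim_rate_mHz,
            block_duration_s=cfg.block_duration_s,
            pause_s=cfg.pause_s,
            repetitions=1,
            event_samples=max(n, 1),
            sampling_rate_hz=cfg.sampling_rate_hz,
            trigger_edge=cfg.trigger_edge,
            beep_on_trigger=False,
        )
        return _record_events(free_cfg, [(0, 0, 0.0)], source, seed, start)
    raise ConfigError(
        f"run_protocol handles acoustic/free_running modes; use "
        f"external_trigger_run for mode {cfg.mode!r}"
    )


def external_trigger_run(
    cfg: ProtocolConfig,
    trigger_times: Sequence[float],
    source: Source = _silent,
    seed: int = 0,
    start: datetime = DEFAULT_START,
) -> Recording:
    """Simulate external-trigger acquisition: one event per trigger edge.

    ``trigger_times`` (seconds) must be sorted and spaced at least one
    event duration apart; after each trigger exactly ``cfg.event_samples``
    samples are recorded.
    """
    times = list(trigger_times)
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ConfigError("trigger_times must be strictly increasing")
    dur = cfg.event_samples / cfg.sampling_rate_hz
    for a, b in zip(times, times[1:]):
        if b - a < dur * (1 - 1e-12):
            raise ConfigError(
                f"triggers at {a:g} s and {b:g} s overlap: events last {dur:g} s"
            )
    ext_cfg = ProtocolConfig(
        mode="external_trigger",
        stim_rate_mHz=cfg.stim_rate_mHz,
        block_duration_s=cfg.block_duration_s,
        pause_s=cfg.pause_s,
        repetitions=cfg.repetitions,
        event_samples=cfg.event_samples,
        sampling_rate_hz=cfg.sampling_rate_hz,
        trigger_edge=cfg.trigger_edge,
        beep_on_trigger=cfg.beep_on_trigger,
    )
    schedule = [(0, i, t) for i, t in enumerate(times)]
    return _record_events(ext_cfg, schedule, source, seed, start)
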