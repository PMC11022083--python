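"""Synthetic sensor signals: gravity under rotation, thumb flicks, learning runs.

Every other module is testable without hardware through three generators:

* :func:`static_signal` — a resting sensor tilted through a sequence of
  orientations, reading the projection of gravity (9.81 m/s²) onto its
  axes plus white noise and per-axis offsets; the noiseless magnitude is
  exactly 1 g at all times.
* :func:`flick_signal` — a ballistic thumb flick: a smooth biphasic
  (accelerate-then-brake) pulse along a fixed direction, silent before an
  onset delay that models reaction time. The profile is the derivative of
  a Gaussian, truncated at ±3σ, so the movement ends with zero net
  velocity but non-zero displacement — the thumb lands and stays in the
  bent position.
* :func:`learning_experiment` — a full multi-block protocol whose
  per-event true peaks follow a programmed per-block trend with
  multiplicative event-to-event variability, emulating across-block
  changes in peak acceleration during motor practice.

Orientations are single-plane tilts (an axis vertical, or part-way
between two axes), which covers every static validation case without full
quaternion machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ConfigError, G0, Recording
from .protocol import DEFAULT_START, ProtocolConfig, Source, run_protocol

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class TiltStep:
    """Hold the sensor tilted ``angle_deg`` from ``axis_from`` toward ``axis_to``.

    At 0° gravity lies fully on ``axis_from``; at 90° fully on
    ``axis_to``; at 45° both read 9.81/√2 ≈ 6.94 m/s².
    """

    axis_from: str
    axis_to: str
    angle_deg: float
    hold_s: float

    def __post_init__(self) -> None:
        if self.axis_from not in _AXIS_INDEX or self.axis_to not in _AXIS_INDEX:
            raise ConfigError("tilt axes must be x, y or z")
        if self.axis_from == self.axis_to:
            raise ConfigError("tilt axes must differ")
        if not 0 <= self.angle_deg < 360:
            raise ConfigError(f"angle must lie in [0, 360), got {self.angle_deg}")
        if self.hold_s <= 0:
            raise ConfigError("hold duration must be positive")

    def gravity_vector(self) -> np.ndarray:
        g = np.zeros(3)
        theta = np.deg2rad(self.angle_deg)
        g[_AXIS_INDEX[self.axis_from]] = G0 * np.cos(theta)
        g[_AXIS_INDEX[self.axis_to]] = G0 * np.sin(theta)
        return g


@dataclass(frozen=True)
class Orientation:
    """A sequence of tilt-and-hold steps, e.g. each axis vertical in turn."""

    steps: tuple[TiltStep, ...]

    @property
    def total_s(self) -> float:
        return sum(s.hold_s for s in self.steps)

    @staticmethod
    def axis_vertical(axis: str, hold_s: float = 1.0) -> "Orientation":
        other = "x" if axis != "x" else "y"
        return Orientation((TiltStep(axis, other, 0.0, hold_s),))


@dataclass(frozen=True)
class NoiseModel:
    """Additive white measurement noise and constant per-axis offsets."""

    sd: tuple[float, float, float] = (0.0, 0.0, 0.0)
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sd):
            raise ConfigError("noise SD must be >= 0")

    def sample(self, n: int, rng: np.random.Generator | None = None) -> np.ndarray:
        rng = rng if rng is not None else np.random.default_rng(self.seed)
        return rng.normal(0.0, self.sd, size=(n, 3)) + np.asarray(self.offset)


#: Default sensor noise: 0.02 m/s² SD per axis, matching a low-noise MEMS
#: accelerometer sampled at 1 kHz. Configurable, not a datasheet value.
DEFAULT_NOISE = NoiseModel(sd=(0.02, 0.02, 0.02))
QUIET = NoiseModel()


@dataclass(frozen=True)
class FlickModel:
    """Parameters of one ballistic thumb flick.

    ``peak`` is the programmed peak acceleration magnitude (m/s²),
    ``duration`` the full movement duration (the ±3σ support of the
    profile) and ``onset_delay`` the reaction time between the trigger and
    movement onset.
    """

    peak: float = 5.0
    duration: float = 0.3
    onset_delay: float = 0.2

    def __post_init__(self) -> None:
        if self.peak < 0:
            raise ConfigError("peak must be >= 0")
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        if self.onset_delay < 0:
            raise ConfigError("onset_delay must be >= 0")

    def profile(self, t: np.ndarray) -> np.ndarray:
        """Scalar biphasic acceleration at times ``t`` (s after the trigger).

        Derivative-of-Gaussian pulse: positive (accelerating) lobe peaking
        at ``peak``, then a mirror-image braking lobe; zero outside
        ``[onset_delay, onset_delay + duration]``. The two lobes cancel
        exactly, so the time integral (final velocity) is zero.
        """
        sigma = self.duration / 6.0
        tc = self.onset_delay + self.duration / 2.0
        u = (t - tc) / sigma
        out = self.peak * (-u) * np.exp((1.0 - u * u) / 2.0)
        out[np.abs(u) > 3.0] = 0.0
        return out


def static_signal(
    ori: Orientation, fs: float, noise: NoiseModel = QUIET
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a resting sensor stepped through the given orientations.

    Returns ``(t, accel)`` with one gravity-projection segment per tilt
    step; the noiseless magnitude is 9.81 m/s² at every sample.
    """
    if not ori.steps:
        raise ConfigError("orientation holds no tilt steps")
    segments = []
    for step in ori.steps:
        n = int(round(step.hold_s * fs))
        segments.append(np.tile(step.gravity_vector(), (max(n, 1), 1)))
    clean = np.concatenate(segments)
    t = np.arange(clean.shape[0]) / fs
    return t, clean + noise.sample(clean.shape[0])


def flick_signal(
    model: FlickModel,
    fs: float,
    noise: NoiseModel = QUIET,
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0),
    event_duration_s: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one triggered event containing a single flick.

    The biphasic pulse acts along the unit ``direction``; before
    ``onset_delay`` the signal is silent. Returns ``(t, accel)`` of
    event length; the noiseless peak magnitude equals ``model.peak``
    within one sample of discretisation.
    """
    if model.onset_delay + model.duration > event_duration_s:
        raise ConfigError(
            f"flick (onset {model.onset_delay:g} s + duration {model.duration:g} s) "
            f"does not fit the {event_duration_s:g} s event window"
        )
    d = np.asarray(direction, dtype=np.float64)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ConfigError("direction must be a non-zero vector")
    d = d / norm
    n = int(round(event_duration_s * fs))
    t = np.arange(n) / fs
    accel = model.profile(t)[:, None] * d[None, :]
    return t, accel + noise.sample(n, rng)


@dataclass(frozen=True)
class LearningConfig:
    """Ground truth of a synthetic motor-practice experiment.

    Each event's true peak is
    ``base_peak × block_trend[block] × (1 + N(0, event_cv))``. The
    reference session uses six blocks of 30 one-second events at 1 kHz
    with 60 s breaks, gravity resting on ``gravity_axis``.
    """

    base_peak: float = 4.0
    block_trend: tuple[float, ...] = (1.0, 1.105, 1.21, 1.315, 1.42, 1.525)
    event_cv: float = 0.05
    direction: tuple[float, float, float] = (0.6, 0.64, 0.48)
    gravity_axis: str | None = "z"
    flick: FlickModel = field(default_factory=FlickModel)


def reference_protocol() -> ProtocolConfig:
    """The reference acoustic session: 6 blocks × 30 events × 1000 samples.

    One beep every 2 s (500 mHz) for 60 s per block, 60 s breaks, 1 kHz
    sampling — thirty one-second events per block.
    """
    return ProtocolConfig(
        mode="acoustic",
        stim_rate_mHz=500.0,
        block_duration_s=60.0,
        pause_s=60.0,
        repetitions=6,
        event_samples=1000,
        sampling_rate_hz=1000.0,
    )


def learning_experiment(
    cfg: ProtocolConfig | None = None,
    learning: LearningConfig | None = None,
    noise: NoiseModel = DEFAULT_NOISE,
    seed: int = 0,
) -> Recording:
    """Simulate a full multi-block session with a programmed peak trend.

    Returns a standard :class:`~limbkin.model.Recording` (uncalibrated:
    the gravity projection and the noise offsets are still in the data,
    as they would be off the sensor). Deterministic per seed: with
    ``event_cv = 0`` and a flat trend every event's true peak equals
    ``base_peak`` exactly.
    """
    cfg = cfg if cfg is not None else reference_protocol()
    learning = learning if learning is not None else LearningConfig()
    if len(learning.block_trend) != cfg.repetitions:
        raise ConfigError(
            f"block_trend has {len(learning.block_trend)} entries for "
            f"{cfg.repetitions} blocks"
        )
    static = np.zeros(3)
    if learning.gravity_axis is not None:
        static[_AXIS_INDEX[learning.gravity_axis]] = G0
    static = static + np.asarray(noise.offset)

    def source(times: np.ndarray, block_id: int, event_id: int, rng) -> np.ndarray:
        true_peak = learning.base_peak * learning.block_trend[block_id]
        if learning.event_cv > 0:
            true_peak *= max(1.0 + rng.normal(0.0, learning.event_cv), 0.0)
        model = FlickModel(
            peak=true_peak,
            duration=learning.flick.duration,
            onset_delay=learning.flick.onset_delay,
        )
        _, accel = flick_signal(
            model,
            cfg.sampling_rate_hz,
            noise=NoiseModel(sd=noise.sd),
            direction=learning.direction,
            event_duration_s=cfg.event_duration_s,
            rng=rng,
        )
        return accel + static

    return run_protocol(cfg, source, seed=seed, start=DEFAULT_START)


def random_recording(
    rng: np.random.Generator,
    n_blocks: int | None = None,
    with_raw: bool | None = None,
    with_temp: bool | None = None,
    with_timestamps: bool | None = None,
    fs: float = 100.0,
) -> Recording:
    """Generate a structurally valid recording with random content.

    Blocks, events-per-block and event lengths are drawn at random (small,
    a few dozen samples per event); optional raw-count and temperature
    channels and the wall-clock timestamp table are included at random
    unless pinned by the keyword arguments. Used to exercise the file
    format: any recording produced here satisfies every invariant, so
    write→read must reproduce it exactly.
    """
    from datetime import datetime

    from .model import Block, Event, HardwareConfig, RecordingMeta

    n_blocks = int(rng.integers(1, 4)) if n_blocks is None else n_blocks
    with_raw = bool(rng.integers(0, 2)) if with_raw is None else with_raw
    with_temp = bool(rng.integers(0, 2)) if with_temp is None else with_temp
    with_timestamps = (
        bool(rng.integers(0, 2)) if with_timestamps is None else with_timestamps
    )
    start = datetime(2024, 3, 1, 9, 30, 0)
    sid = 0
    t_cursor = 0.0
    blocks: list[Block] = []
    stamps: list[np.ndarray] = []
    markers: list[str] = []
    for b in range(n_blocks):
        block = Block(block_id=b)
        for e in range(int(rng.integers(1, 4))):
            n = int(rng.integers(2, 30))
            t = t_cursor + np.arange(n) / fs
            wall = np.datetime64(start, "ms") + (
                np.round(t * 1000).astype(np.int64).astype("timedelta64[ms]")
            )
            block.events.append(
                Event(
                    event_id=e,
                    block_id=b,
                    sample_ids=np.arange(sid, sid + n),
                    t=t,
                    accel=rng.normal(0, 3, size=(n, 3)),
                    raw=rng.integers(-(2**15), 2**15, size=(n, 3)) if with_raw else None,
                    temperature=20 + rng.normal(0, 0.5, size=n) if with_temp else None,
                    trigger_time=(
                        wall[0].astype("datetime64[ms]").astype(datetime)
                        if with_timestamps
                        else None
                    ),
                )
            )
            stamps.append(wall)
            markers.extend((["break"] if b > 0 and e == 0 else [""]) + [""] * (n - 1))
            sid += n
            t_cursor = t[-1] + 1.0 / fs
        t_cursor += 5.0  # inter-block pause
        blocks.append(block)
    meta = RecordingMeta(
        subject={"id": f"S{int(rng.integers(1, 99)):02d}", "hand": "right"},
        n_blocks=n_blocks,
        n_events=sum(b.n_events for b in blocks),
        hardware=HardwareConfig(sampling_rate_hz=fs),
        created=start,
    )
    return Recording(
        blocks,
        meta,
        timestamps=np.concatenate(stamps) if with_timestamps else None,
        markers=markers if with_timestamps else None,
    )


def static_source(
    ori: Orientation | None = None,
    noise: NoiseModel = QUIET,
    gravity_axis: str = "z",
) -> Source:
    """A protocol-engine source producing resting-sensor gravity readings."""
    g = (
        ori.steps[0].gravity_vector()
        if ori is not None
        else Orientation.axis_vertical(gravity_axis).steps[0].gravity_vector()
    )
    offset = np.asarray(noise.offset)

    def source(times: np.ndarray, block_id: int, event_id: int, rng) -> np.ndarray:
        clean = np.tile(g + offset, (times.size, 1))
        return clean + rng.normal(0.0, noise.sd, size=(times.size, 3))

    return source
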