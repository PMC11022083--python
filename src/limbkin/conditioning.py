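"""Signal conditioning: offset calibration, high-pass filtering, magnitude.

MEMS accelerometers exhibit per-axis constant bias, and a static sensor
additionally reads the projection of gravity onto its axes. Before peak
analysis this static component must be removed, otherwise the "peak"
measures orientation rather than movement. Two routes are provided:

* :func:`estimate_offset` / :func:`apply_offset` — classic automatic
  offset calibration from a dedicated static window (≥ 0.5 s). With
  ``gravity_axis`` named, 1 g is preserved on that axis (orientation is
  kept); with ``gravity_axis=None`` the full static level, gravity
  included, is removed.
* :func:`calibrate_recording` — per-event baseline subtraction over the
  pre-onset window of each triggered event, the practical choice for
  protocol recordings whose events contain no 0.5 s static stretch.

A first-order recursive high-pass (:func:`highpass`) offers a third,
drift-tolerant route.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .model import G0, Recording


class CalibrationError(ValueError):
    """Calibration preconditions not met."""


class UncalibratedDataError(ValueError):
    """Peak analysis was requested on data whose static level was not removed."""


_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class OffsetEstimate:
    """Per-axis constant bias estimated from a static window.

    ``gravity_axis`` records on which axis 1 g was preserved (``None`` if
    the full static level was taken as offset); ``window`` is the
    half-open sample-index range used.
    """

    offset: tuple[float, float, float]
    gravity_axis: str | None
    window: tuple[int, int]


def estimate_offset(
    series: np.ndarray,
    sampling_rate_hz: float,
    gravity_axis: str | None = None,
    window: tuple[int, int] | None = None,
) -> OffsetEstimate:
    """Estimate per-axis offsets from a static acceleration series.

    Parameters
    ----------
    series : ndarray, shape (n, 3)
        Acceleration in m/s² from a sensor held static (caller-asserted).
    sampling_rate_hz : float
        Sample rate; the window must cover at least 0.5 s.
    gravity_axis : {"x", "y", "z", None}
        Axis on which 1 g (9.81 m/s²) is preserved; with ``None`` the
        per-axis means themselves are the offsets, so applying the
        estimate zeroes all axes — gravity included.
    window : (start, end), optional
        Half-open index range to use; defaults to the whole series.

    After :func:`apply_offset` with the returned estimate, the per-axis
    means over the calibration window are 0 (or ±9.81 on the gravity
    axis), within noise.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 2 or series.shape[1] != 3:
        raise CalibrationError(f"series must have shape (n, 3), got {series.shape}")
    if window is None:
        window = (0, series.shape[0])
    start, end = window
    if not 0 <= start < end <= series.shape[0]:
        raise CalibrationError(f"invalid calibration window {window}")
    n = end - start
    min_n = 0.5 * sampling_rate_hz
    if n < min_n:
        raise CalibrationError(
            f"calibration window of {n} samples is shorter than 0.5 s "
            f"({min_n:g} samples at {sampling_rate_hz:g} Hz)"
        )
    offset = series[start:end].mean(axis=0)
    if gravity_axis is not None:
        if gravity_axis not in _AXIS_INDEX:
            raise CalibrationError(f"gravity_axis must be x, y, z or None")
        i = _AXIS_INDEX[gravity_axis]
        # preserve 1 g with the observed sign on the gravity axis
        offset[i] -= np.sign(offset[i]) * G0 if offset[i] != 0 else G0
    return OffsetEstimate(
        offset=tuple(float(v) for v in offset),
        gravity_axis=gravity_axis,
        window=(int(start), int(end)),
    )


def apply_offset(series: np.ndarray, est: OffsetEstimate) -> np.ndarray:
    """Subtract the estimated per-axis offsets from an (n, 3) series."""
    return np.asarray(series, dtype=np.float64) - np.asarray(est.offset)


def highpass(
    series: np.ndarray, cutoff_hz: float, sampling_rate_hz: float
) -> np.ndarray:
    """First-order recursive high-pass filter, applied per axis.

    Discretised RC high-pass: ``y[i] = a * (y[i-1] + x[i] - x[i-1])`` with
    ``a = 1 / (1 + 2*pi*fc*dt)``. A constant (DC) input decays to zero with
    time constant ``1 / (2*pi*fc)``; components well above the cutoff pass
    essentially unchanged. Output length equals input length.
    """
    if not 0 < cutoff_hz < sampling_rate_hz / 2:
        raise CalibrationError(
            f"cutoff_hz must lie in (0, {sampling_rate_hz / 2:g}), got {cutoff_hz}"
        )
    x = np.asarray(series, dtype=np.float64)
    a = 1.0 / (1.0 + 2.0 * np.pi * cutoff_hz / sampling_rate_hz)
    return signal.lfilter([a, -a], [1.0, -a], x, axis=0)


def magnitude(series: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm sqrt(ax² + ay² + az²) of an (n, 3) series."""
    return np.linalg.norm(np.asarray(series, dtype=np.float64), axis=-1)


def clip_to_range(series: np.ndarray, range_g: int) -> tuple[np.ndarray, np.ndarray]:
    """Saturate values beyond the sensor's full scale of ``±range_g × 9.81``.

    Returns the clipped series and a boolean mask flagging saturated
    samples (any axis). Saturated samples are kept, never dropped.
    """
    limit = range_g * G0
    x = np.asarray(series, dtype=np.float64)
    mask = np.any(np.abs(x) > limit, axis=-1)
    return np.clip(x, -limit, limit), mask


def calibrate_recording(
    rec: Recording,
    baseline_s: float = 0.15,
    estimate: OffsetEstimate | None = None,
) -> Recording:
    """Remove the static (offset + gravity) level from every event.

    With ``estimate`` given, that global offset estimate — typically from
    a dedicated static recording via :func:`estimate_offset` with
    ``gravity_axis=None`` — is subtracted from all events. Otherwise each
    event's per-axis mean over its first ``baseline_s`` seconds (the
    pre-onset window, before the subject reacts to the cue) is subtracted,
    which removes sensor bias and the gravity projection in one step.

    Returns a new :class:`~limbkin.model.Recording` whose metadata carries
    ``calibrated=True``; the input is unchanged.
    """
    if estimate is not None:
        if estimate.gravity_axis is not None:
            raise CalibrationError(
                "a gravity-preserving estimate leaves 1 g in the data; "
                "movement calibration requires gravity_axis=None"
            )
        calibrated = rec.map_accel(lambda e: apply_offset(e.accel, estimate))
    else:
        fs = (
            rec.meta.protocol.sampling_rate_hz
            if rec.meta.protocol is not None
            else rec.meta.hardware.sampling_rate_hz
            if rec.meta.hardware is not None
            else None
        )
        if fs is None:
            raise CalibrationError(
                "recording carries no sampling rate; pass an explicit estimate"
            )
        n_base = int(round(baseline_s * fs))
        if n_base < 1:
            raise CalibrationError(
                f"baseline window of {baseline_s:g} s holds no samples at {fs:g} Hz"
            )
        for event in rec.iter_events():
            if event.n_samples <= n_base:
                raise CalibrationError(
                    f"event (block {event.block_id}, event {event.event_id}) has "
                    f"{event.n_samples} samples, too short for a {n_base}-sample baseline"
                )
        calibrated = rec.map_accel(
            lambda e: e.accel - e.accel[:n_base].mean(axis=0)
        )
    calibrated.meta = replace(calibrated.meta, calibrated=True)
    return calibrated
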