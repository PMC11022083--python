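# Methods

This note documents the models, conventions and numerical choices behind
`limbkin`, and what the synthetic-data tests do and do not establish about
real sensor data.

## Recording model and file dialect

A recording is a strict hierarchy: blocks contain events, events contain
samples. IDs are 0-based and contiguous per scope — sample IDs globally,
event IDs within their block, block IDs across the recording — which makes
every structural check decidable and lets `validate_recording` enumerate
all violations rather than failing on the first. Acceleration is stored in
m/s² with the gravitational constant fixed at g₀ = 9.81 m/s² everywhere
(offset calibration, clipping, synthetic gravity), so that a vertical axis
reads exactly 9.81 and a 45° tilt reads 9.81/√2 ≈ 6.94 per involved
component. Raw sensor counts and temperature are optional channels that
are either present for every sample or absent from the recording; absence
round-trips as absence, never as zeros.

The on-disk dialect is a deliberate design, not a reverse-engineered
match of any acquisition program's files (whose exact layout is not
public): tab-separated data and timestamp tables with one-line headers and
`#` comments, and a flat `key=value` metadata file. Floats are written
with Python's shortest round-tripping repr and parsed with pandas'
`float_precision="round_trip"`, giving a bit-exact write→read identity —
the property the round-trip tests assert for randomly generated
recordings. Wall-clock timestamps are ISO-8601 at millisecond precision; a
marker column (`break`, `delay`) keeps inter-block pauses and trigger
delays visible in the stored data. By convention an event's trigger time
equals the wall-clock stamp of its first sample.

## Protocol scheduling

In acoustic mode the stimulation rate is given in millihertz. Events per
block is `floor(block_duration_s × stim_rate_mHz / 1000)` (with a 1e-9
relative guard against floating-point shortfall); the first beep of each
block fires at the block start, block *b* starting at
`b × (block_duration_s + pause_s)`. The phase and rounding rule are our
choice — only rate, duration, pause and repetitions are user-facing — and
`floor` plus start-of-block phase guarantees every event fits inside its
block. Events must not overlap: configuration requires
`event_samples / sampling_rate_hz ≤ 1000 / stim_rate_mHz`.

The reference session used throughout (six blocks × thirty 1 s events of
1000 samples at 1 kHz, 60 s breaks) fixes the beep rate at 500 mHz with
60 s blocks. Only the counts and the break length are given quantities;
the 500 mHz / 60 s pair is the assumption consistent with them, and it is
configurable.

Trigger-edge selection and the cue beep are carried as metadata only; no
voltages or audio are modelled — timing is what matters downstream.
Schedules depend only on the configuration; the seed affects nothing but
the sample noise produced by the signal source.

## Signal conditioning

Offset calibration estimates per-axis constant bias as the mean over a
static window of at least 0.5 s. Whether the gravity reading should
survive calibration is genuinely ambiguous for a wearable (the sensor's
orientation during calibration may or may not match the experiment), so it
is an explicit parameter: with `gravity_axis=None` (the default) the full
static level — gravity included — is treated as offset and removed; with
an axis named, 1 g with the observed sign is preserved on that axis.

Protocol recordings contain only the 1 s post-trigger windows, and with a
realistic reaction time (~0.2 s) no 0.5 s static stretch exists inside an
event. `calibrate_recording` therefore defaults to per-event baseline
subtraction: the per-axis mean over each event's first 0.15 s (pre-onset,
sensor at rest) is subtracted, removing bias and the gravity projection in
one step. At 1 kHz the 150-sample baseline leaves a residual of
σ/√150 ≈ 0.0016 m/s² at the default noise level — negligible against
multi-m/s² movement peaks. Peak analysis refuses uncalibrated recordings
(a `calibrated` flag travels in the metadata) unless forced, because peaks
of uncalibrated data measure orientation, not movement.

The optional high-pass is the first-order recursive RC filter
`y[i] = a (y[i-1] + x[i] − x[i-1])`, `a = 1/(1 + 2π f_c/f_s)`, default
cutoff 0.1 Hz — the simplest defensible drift-removal for a MEMS
accelerometer; no filter order or cutoff is prescribed by the hardware.
Values beyond the configured full scale (±range_g × 9.81, range 2/4/8 g)
are saturated and flagged, never dropped.

## Kinematics and statistics

Velocity and displacement are cumulative trapezoidal integrals
(`scipy.integrate.cumulative_trapezoid`) over the user-selected segment,
with v = 0 and s = 0 at the segment start and no detrending or drift
correction inside the segment. The segment is assumed to begin at rest —
that is what makes v₀ = 0 defensible, and it matches how an analyst
places the start marker just before movement onset. Segment indices are
half-open `[start, end)`, 0-based. Trapezoid integration is exact for
polynomial accelerations up to degree 1 and O(dt²) for smooth signals;
the tests check both against closed forms and against an independent
10×-oversampled integrator.

"Peak acceleration" defaults to the maximum of the per-sample vector
magnitude — the only rotation-invariant choice; axis-specific (signed)
maxima are available via the component parameter. Block dispersion uses
the sample standard deviation (n−1), the standard convention for error
bars over repeated trials; it is reported absent for single-event blocks.
Percent change is `(m_last − m_first)/m_first × 100` and requires a
positive baseline. No significance testing is provided: the session-level
quantity of interest is the descriptive percent change.

## Synthetic sensor

Orientations are single-plane tilts (`TiltStep`: rotate from one axis
toward another by a given angle and hold), which covers axis-vertical and
45° validation cases without quaternion machinery; the noiseless static
signal has magnitude g₀ at every sample by construction.

The flick profile is the derivative of a Gaussian, truncated at ±3σ with
σ = duration/6: a smooth accelerate-then-brake pulse whose positive lobe
peaks at the programmed value, whose lobes cancel exactly (zero net
velocity — the thumb lands and stays), and whose displacement is
monotone. Defaults: peak 5 m/s², duration 0.3 s, onset delay 0.2 s
(reaction time) — a plausible ballistic thumb flick; the real movement's
waveform is not quantified anywhere, so the profile is an assumption, and
peak recovery is asserted only up to one-sample discretisation error.

Measurement noise is white and Gaussian, default SD 0.02 m/s² per axis at
1 kHz with configurable constant offsets. That emulates a low-noise MEMS
part qualitatively; it deliberately omits 1/f drift, temperature
dependence, cross-axis coupling and quantisation, so passing tests show
pipeline correctness, not robustness to every real-sensor artefact.

The learning generator draws each event's true peak as
`base_peak × trend[block] × (1 + N(0, cv))` (negative draws floored at
zero), applies it to the flick profile along a fixed direction, adds the
gravity projection and noise, and runs it through the standard protocol
engine — so synthetic sessions exercise the identical code path as any
other recording. The default session programmes a linear trend to +52.5 %
last-vs-first at cv = 0.05 with 30 events per block; the ratio of two
block means then has a sampling SD of ≈ √2·cv/√30·152.5 ≈ 2 percentage
points, and the end-to-end test accepts recovery within ±3.9 points of
the programmed value at a fixed seed.

## Problem sizes and determinism

The default test and acceptance runs use the reference session (180
events, 180 000 samples, ≈ 15 MB of text when written) plus 100 small
random recordings for round-trip checks; these sizes keep a full run in
the tens of seconds while still exercising the full-scale protocol.
Every stochastic path takes an explicit seed (`numpy.random.default_rng`),
simulated wall clocks start from a fixed origin, and property tests run
derandomised, so identical inputs give byte-identical outputs.

## Known limitations

* No device I/O: the package simulates and analyses; it does not talk to
  hardware, and the text dialect is its own, not the original programs'.
* Per-event baseline calibration assumes the pre-onset window is truly
  static; anticipatory movement would bias it.
* The integration stage accumulates sensor error quadratically in time;
  segments should stay short (sub-second), as in the intended use.
* The flick profile and noise model are stated idealisations (above).
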