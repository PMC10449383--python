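# Methods

This note documents the models, conventions and parameter choices behind
`photothreat`, and what the synthetic-data validation does and does not
establish about real recordings.

## Signal chain

The processing order is fixed: local-average downsampling of both channels
to the analysis rate, polynomial baseline fit to the downsampled calcium
channel, ΔF/F, isosbestic screening.

**Downsampling.** The output sample *j* is the mean of input samples in
bin *j* of width `round(fs_in/fs_out)`; a trailing partial bin is dropped.
The nominal 11 kHz → 120 Hz ratio is non-integer (91.67), so the bin width
is the nearest integer and the effective output rate `fs_in/width` is
recorded on the trace (92 samples → 119.57 Hz at 11 kHz; 8 samples →
125 Hz at the 1 kHz desk scale used in tests and examples). All
sample-count tolerances in the package are expressed at the effective
rate.

**Baseline fit.** A first-order polynomial is fitted by least squares to
the calcium channel itself, over the whole recording, not per trial and
not to the isosbestic channel — the isosbestic channel enters only the
discard rule. A first-order fit removes the locally near-linear portion of
photobleaching; it is not a model of the bleaching process. ΔF/F is the
ratio `(F − F̂)/F̂`, so the readout is invariant to detector gain (any
k·F gives identical output) and a fitted baseline that touches zero makes
the trace unusable and raises an error rather than producing infinities.

**Isosbestic screen.** "Sudden change" is operationalized as the robust
z-score of the channel's first differences: z = (d − median(d)) /
(1.4826·MAD(d)), flagging |z| > 5 (config-exposed). The robust scale
prevents a single large step from masking itself; slow drifts have
near-constant differences and pass. With tens of thousands of differences
per session, the 5-z threshold carries a small per-session false-alarm
probability (of order a few percent for a multi-minute session); since
exclusion is per trial, a false flag costs at most the trials whose
windows cover it. QC is computed session-wide and re-evaluated per aligned
trial window: a single artifact drops only the trials it touches.

## Trial metrics

**Alignment and standardization.** Trials are aligned to event onsets by
nearest sample; a looming trial of five expansions contributes one row,
aligned to the first expansion. Windows are half-open
`[−baseline, response)` with defaults loom 2/2 s, CS 1.5/2 s, US
0.5/0.5 s. Each trial is standardized against its own baseline using the
population SD (divisor *n*; fixed so hand-computable examples are
reproducible). A zero-SD baseline marks the trial invalid — it never
propagates NaN into group summaries. For the US window, the 0.5 s
preceding the shock is integrated into the AUC along with the 0.5 s
following it, and the z-baseline is the window's own pre-onset segment.

**Peak-filtered AUC.** On the z-scored trace over the response window,
maximal runs of consecutive samples with z > 0 are enumerated (baseline =
0 in z units, the implicit baseline of a standardized trace). A region
whose peak height is strictly below 10% of the window's (max − min) range
is discarded — heights exactly at the threshold are retained. Retained
regions contribute trapezoidal area over their samples; negative
deflections never contribute; an empty retained set gives AUC 0.
Trapezoid terms are accumulated with `math.fsum`, so the result is the
correctly rounded sum and independent of accumulation order — this makes
"exact" agreement with an independently ordered reference implementation
well defined.

**Time-to-peak.** The onset-relative time of the maximal z sample in the
response window, ties to the earliest sample. This is a per-sample argmax
with no smoothing. Consequence: for a kernel that is nearly flat around
its peak (the difference-of-exponentials GCaMP kernel drops only ~4×10⁻⁴
of its height over one 8 ms sample), per-sample noise comparable to that
drop moves the argmax by several samples. Latency is therefore recovered
to within one sample only when noise is well below amplitude × peak
curvature; at a raw noise SD of 0.01 against amplitudes of 0.01–0.1 the
argmax wanders by a few tens of milliseconds. This is a property of the
estimator, not an implementation artifact, and the validation reports it
honestly (see `time_to_peak_within_one_sample_fraction` in the acceptance
output).

## Behavior scoring

Freezing bouts are maximal runs of motion below threshold lasting ≥ 1 s;
sub-second immobility is never a bout. Motion defaults to per-frame
centroid displacement (cm/s) when positions are available, otherwise the
recorded motion index; the immobility threshold (default 1 cm/s) is
config-exposed since upstream video trackers differ. Freezing percentage
clips bouts to the scoring window. Escape detection smooths speed with a
0.25 s moving average to suppress single-frame jitter, references the mean
speed over the 30 s pre-loom window (the averaging span is a package
choice), and counts maximal supra-threshold runs; a zero reference speed
makes the metric not-evaluable rather than infinite. Rearing and tail
rattling are manual annotations passed through, never detected. Line
crosses are sign changes of position against grid lines, with frames
exactly on a line adopting the previous side.

## Synthetic sessions

The generator exists to provide ground truth, emulating: multiplicative
exponential photobleaching (default amplitude 0.05, τ 3000 s — long
relative to a session, so the trend is locally near-linear, matching the
first-order detrend; shorter τ is a deliberate stress-test knob);
event-locked transients with kernel `(1−e^(−t/τr))·e^(−t/τd)`
peak-normalized to the amplitude, defaults τr = 0.1 s, τd = 1.0 s and
amplitude 0.05 ΔF/F — placeholders with GCaMP7s-like kinetics, since real
sessions do not pin these numerically; white Gaussian sensor noise
(default SD 0.005 fluorescence units against F₀ = 1); an isosbestic
channel with its own bleaching trend and optional additive steps (default
0.05·F₀) at chosen times. The desk-scale sampling rate is 1 kHz (11 kHz is
supported but adds nothing at a 120 Hz analysis rate except runtime).

Protocol schedules place a 30 s lead-in, then trials: five loom onsets
2.5 s apart per trial, or a 20 s CS whose final 2 s coincide with the US;
inter-trial intervals are uniform on 35–120 s, quantized to a 1/1024 s
grid. The grid is exact in binary floating point, so within-trial spacings
remain exactly 2.5 s after accumulating trial start times; sub-ms
quantization is far below any behavioral or analysis timescale.

Behavior tracks are heading-diffusion random walks at a scripted speed
(default 6 cm/s) in the 37 × 40 cm arena, with speed set to 0 inside
freezing bouts and to multiplier × baseline inside escape windows. Walls
reflect the heading *before* the step is taken, so every emitted
displacement has exactly the scripted length and scripted scores are
recoverable exactly from the emitted track. Rearing annotations snap to
the frame grid so file round-trips are lossless.

What the generator does not emulate: hemodynamic or motion artifacts in
the calcium channel, sensor nonlinearity and saturation, habituation or
learning across trials, pose-level behavior (rearing is annotation-only),
and tracking dropouts. Passing tests therefore establish the correctness
of the quantification chain under the stated signal model — not the
robustness of the chain to every artifact of real recordings.

## Numerical conventions

Times are float64 seconds from recording start; intervals are half-open
`[onset, offset)`; an event exactly at a window edge belongs to the later
window. Baseline SD uses divisor *n*. Downsampled bin times are the mean
of the bin's sample times. Polynomial coefficients are stored in ascending
order. All generators take a single integer seed; sub-streams are derived
deterministically, and identical seeds give bit-identical outputs, which
the CLI manifests (SHA-256 digests of inputs and outputs) make checkable.

## Validation scale

The test suite and acceptance script run entirely on synthetic sessions of
20–200 s at 1 kHz, 50–100-trial batches for statistical checks, 200 random
traces for the AUC reference comparison, and 200–1000 schedules for
protocol timing — sizes chosen to make the statistical assertions sharp
(CLT bands of ±3·SE) while keeping a full run in seconds.
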