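# Methods

This note documents the models and conventions behind `tremorkit`: what
each stage computes, the parameters that matter and their defaults, what
the synthetic-data generator does and does not emulate, and the places
where the design was genuinely open and a choice had to be made.

## Signal model

The pipeline treats a wrist-accelerometry session as episodic triaxial
recordings around a drug-injection event (time zero). The tremor of
interest is a narrowband oscillation with

- a peak frequency in the 10–14 Hz range at onset,
- an onset 20–30 minutes post-injection (intramuscular wash-in),
- a slow, approximately linear downward frequency drift on the order of
  −0.5 to −1.5 Hz/hour (−0.009 to −0.024 Hz/min),
- pronounced amplitude intermittency on a seconds timescale.

Everything else on the sensor — postural sway, voluntary movement,
sensor noise — is "background", plus occasional brief jerks that leak
power across the whole spectrum.

## Conditioning

Each channel of each segment is detrended (OLS line subtracted) and
high-pass filtered with a 6th-order Butterworth at 1 Hz, in that order.
The filter is causal single-pass by default: a zero-phase
forward–backward pass would square the magnitude response and double
the effective order. A `zero_phase` switch exists for users who prefer
phase fidelity. No padding is applied; the initial-condition transient
(well under 3 s at a 1 Hz cutoff) is negligible against segments of 60 s
or more. Streams longer than 120 s are split into 120-s chunks; a
trailing remainder is kept only if it can hold at least one 4-s Welch
window.

## Spectrogram and artifact rejection

The short-time Fourier transform uses non-overlapping Hamming windows
of `round(fs)` samples (nominally 1 s; at a non-integer rate such as
1017.3 samples/s the bin spacing is fs/nperseg ≈ 1.0003 Hz). Per-axis
magnitude-squared spectra are summed over the three axes, making every
downstream statistic independent of tremor orientation relative to the
sensor. Power carries no density scaling: the MAD rule and MPR are
invariant to the overall scale, so the convention is cosmetic but
fixed.

Artifact rejection pools the total (frequency-summed) power of every
1-s window across *all* segments of a session, computes the median and
the unscaled MAD, and excludes windows strictly outside median ±
3 MAD. Consequences worth knowing:

- With all windows equal, MAD = 0 and everything is kept (a deviation
  of zero is not *outside* the threshold).
- The rule is two-sided: unusually quiet windows are excluded too.
- Because the statistics are session-wide, the rule implicitly assumes
  that no single behavioral state (including the tremor itself)
  separates from the bulk of the session by more than 3 MAD of total
  power. A tremor that dominated total window power while active in
  only a minority of windows would be excluded as artifact. On a wrist
  sensor the broadband motion background carries most of the total
  power and the tremor is narrowband, so in practice the rule removes
  jerks, not tremor — the synthetic defaults (below) reproduce exactly
  this regime.

Kept windows are individually detrended and concatenated per axis
before PSD estimation, which bounds the discontinuities created by
removing windows.

## Motion power ratio and onset statistics

MPR of a window is the summed spectrogram power in the tremor band
divided by the power in the 17–21 Hz reference band. Bands are
half-open `[lo, hi)` on the frequency grid so adjacent bands never
double-count a bin; with the default 4-bin bands a flat spectrum gives
MPR ≈ 1. The tremor band defaults to automatic selection: each
post-baseline Welch PSD votes with its 8–16 Hz peak (rounded to 0.5 Hz)
provided the peak clears 3× the median in-range power and is not
saturated at the range boundary; the band is the modal vote ± 2 Hz.
With no qualifying peaks the band falls back to 10–14 Hz with a
warning. A secondary band (e.g. a coexisting low-frequency postural
mode) is reported when the session-average PSD has a second local
maximum at ≥ 25% of the primary peak, and onset statistics are then
computed for both bands.

The baseline is every window with midpoint time ≤ 900 s (pre-injection
included); MPR is normalized by the baseline median, so the normalized
baseline median is 1 by construction. Each segment's normalized MPR is
tested against 1 with the two-sided Wilcoxon signed-rank test (exact
null for n ≤ 25 without ties, normal approximation with tie correction
otherwise; zero differences discarded). The segment family is
controlled with Benjamini–Hochberg at FDR = 10⁻⁴ — deliberately
conservative, because MPR values are right-skewed and the signed-rank
test is a test of symmetry, so mild anti-conservatism at ordinary
alpha levels is expected. Onset is the earliest post-baseline segment
that is BH-rejected *and* above baseline (two-sided test, separate
direction flag); significant drops below baseline never count as onset.
Per-segment 95% CIs on the median are seeded percentile bootstrap
(1000 resamples by default; the CI method is a reporting aid and does
not enter onset detection).

## PSD estimation and drift

Welch PSDs use 4-s Hamming windows with 50% overlap and
`nfft = max(256, next power of two ≥ window length)`, so the bin
spacing is fs/nfft: 0.1506 Hz at 617 samples/s, 0.2441 Hz at 500,
0.2484 Hz at 1017.3. The three axis densities are summed. The 10–14 Hz
peak of each segment PSD is tracked over time and fit by OLS on
minutes, using only points after the 15-minute wash-in.

Outlier handling before the fit: (a) peaks sitting on the search-band
boundary are dropped as saturated; (b) one pass of residual screening
removes points with |residual| > 3 × the *normal-consistent*
(1.4826-scaled) MAD of the residuals, then refits. The scaled MAD
matters here: an unscaled 3-MAD cut equals only ≈ 2σ under Gaussian
tracking noise, trims ~4% of legitimate points per fit, deflates the
residual variance and drags the 95% slope-CI coverage down to ≈ 85%;
with the ≈ 3σ screen coverage is nominal (measured ≈ 94% over 200
replicates). The slope CI is the usual t-interval on the OLS slope.

A caveat measured on simulations: peaks from segments *after* the
15-minute cutoff but *before* actual tremor onset are pure noise, and
with short sessions they bias the fitted slope toward zero; with 90
minutes of post-onset data the effect is negligible. Nonlinear
(power-law/exponential) drift models are out of scope — the drift is
modeled linearly only.

## Reach-task dose response

Each task session contributes an attempted-reach count (engagement) and
a premature-reach count (impulsivity). Drug-naive (dose 0) sessions are
pooled and summarized with a 90% t-interval; dose sessions are averaged
per dose. The dose-response statistic is the Pearson correlation
between dose and the per-dose metric mean, with the two-sided p from
the exact t transform at n − 2 df. With four dose levels plus the
pooled naive point, n = 5 (df = 3) — chosen because the premature-reach
worked example (r = 0.9176 → p = 0.0280) is consistent only with
df = 3; a switch excludes the naive point. The premature metric is the
within-session fraction, averaged across sessions at a dose; a session
with zero attempts has an undefined fraction and is excluded with a
warning.

## Synthetic sessions

The generator (`tremorkit.synthetic`) emulates the statistical
structure the analysis assumes, with all randomness drawn from one
seeded generator (identical inputs + seed ⇒ bit-identical output):

- **Tremor**: a chirp whose instantaneous phase is the integral of
  `f(t) = f₀ + slope·(t − t_onset)` (no phase discontinuities),
  multiplied by a per-1-s-epoch Bernoulli(duty) gate smoothed with
  0.1-s raised-cosine ramps (the gate is aligned with the analysis
  windows), and by a slow stochastic envelope (low-pass noise,
  timescale 30 s, relative depth 0.3). The waveform is projected on the
  three axes with fixed unit-norm weights (0.7, 0.5, 0.5)/‖·‖ —
  configurable, and irrelevant to the axis-summed analysis.
- **Background**: white noise (SD 1, the amplitude unit) plus < 5 Hz
  low-pass-filtered noise at SD 0.5 mimicking postural drift. Units are
  arbitrary because the full analysis is scale-invariant; tremor
  amplitude is therefore expressed relative to the broadband noise SD.
- **Artifacts**: Poisson-scheduled broadband bursts (default 1/min,
  duration 0.2 s, amplitude 10× the broadband SD), each placed entirely
  within one 1-s window so the ground-truth window labels used by the
  recovery suites are unambiguous.
- **Schedule**: episodic, with two 2-min pre-injection recordings, one
  early post-injection recording inside the baseline window, then
  contiguous 1-min segments from 15 to 45 minutes post-injection at
  500 samples/s (`SessionPlan.regular`; every element configurable).

Default tremor amplitude is 1.5× the broadband SD with duty 0.8. This
calibration is deliberate: the tremor then dominates the tremor-band
power ratio (normalized MPR of active windows ≫ 1) without dominating
total window power, so it survives the session-level MAD rule — the
regime wrist recordings of a seated subject actually occupy. The
"strong tremor" scenario used by the recovery suites fixes amplitude
1.5 and duty 0.9 (a consistent tremor).

What the generator does **not** emulate: biomechanics (no limb model,
no EMG), pharmacokinetics beyond the onset/drift parameters, tremor
harmonics, behaviorally correlated background (movement bouts), or
recording dropouts. Passing recovery suites therefore demonstrate that
the statistics behave as designed under the assumed structure, not that
the pipeline is robust to every artifact of real recordings.

## Validation suites and problem sizes

`tremorkit.validation` re-runs the pipeline end to end on known ground
truth; the reproduction script and the test suite call the same code:

- onset recovery: 100 sessions, onsets uniform in 19–30 min, recovered
  within one segment duration (2 min);
- false onsets: 200 noise-only sessions at FDR 10⁻⁴;
- artifact rates: 5 sessions with ~5% transient windows at 10× SD;
- drift coverage: 200 replicates of a linear 30-point peak track with
  N(0, 0.1 Hz) tracking noise, slopes in −0.0241…−0.0089 Hz/min.

Sessions are 45 minutes of recording at 500 samples/s — large enough
that every segment test uses the normal-approximation regime (≈ 60
windows) while the full suites run in minutes on one core.

## Containers

Two session-container dialects: a CSV bundle (directory of tidy tables
with a JSON manifest; floats written as shortest round-trippable reprs
and read back with exact parsing, so round trips are bit-exact) and a
single HDF5 file whose group layout follows the Neurodata Without
Borders convention of `acquisition` / `processing` / `general` groups —
a structural mimic, not a certified NWB schema. All stored timestamps
are seconds relative to injection; minutes appear only in reports.

## Known limitations

- The MAD artifact rule and the signed-rank onset test inherit the
  caveats noted above (tremor-dominant minorities; symmetry vs median
  testing). Both follow the stated analysis conventions on purpose.
- Peak tracking reports grid frequencies (no interpolation); drift
  estimates inherit the bin quantization (≤ 0.25 Hz), which the linear
  fit averages out over tens of segments.
- No multitaper/wavelet alternatives, no resampling across subjects'
  native rates, and no physical (g-calibrated) amplitude reporting.
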