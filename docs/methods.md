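# Methods

`tapvoice` re-implements, as a tested pipeline, a smartphone-style dynamic
assessment of Parkinson disease (PD): fine-motor function from alternating
finger tapping and vocal function from sustained phonation and rapid
syllable repetition, each analysed over five equal time frames (TFs) within
a single short recording, with linear mixed models for the interaction of
time frame with group and with motor severity (UPDRS part III). Because no
participant-level data are available, everything is validated on a
synthetic cohort whose generating parameters are exported as ground truth.

## Tasks, features and time frames

Protocol per trial: 20 s alternating two-button tapping (per hand), 10 s
sustained vowels /a/ and /i/, 5 s /dadada/ (alternating motion rate) and
/pa-ta-ka/ (sequential motion rate). Each recording is split into five
equal, half-open frames [start, end), TF1..TF5 (4 s / 2 s / 1 s frames
respectively); the trial-end instant folds into TF5. Half-open frames are
the only non-overlapping reading of printed ranges such as "0 s–4 s,
4 s–8 s".

Tapping. Only taps alternating between the two buttons count: each retained
tap's side must differ from the previously *retained* tap's side (the first
tap is always kept). Intervals are computed between consecutive retained
taps, so an excluded same-side tap bridges its neighbours into one longer
interval (exposed as the `bridge_excluded` reading; the alternative would
leave gaps in the interval series). An interval belongs to the frame of its
*later* tap — causal and single-valued for boundary-spanning intervals.
Dysrhythmia per frame is the sample SD (n−1 denominator, the common
statistical-package default) of intervals in that frame; `mean_variability`
is the arithmetic mean of the five frame SDs, and `total_taps` counts
retained taps.

Voice. The acoustic measures are deliberately minimal, self-contained
re-implementations (an external extractor's CSV can be substituted):

* **Loudness** — framewise energy compressed to the 0.3 power,
  `(mean x^2)**0.3` over 25 ms windows at a 10 ms hop, a standard
  intensity-to-loudness compression: doubling amplitude multiplies loudness
  by `2**0.6`. Units are arbitrary; only within-trial dynamics matter.
* **f0 / voicing** — framewise normalised autocorrelation (40 ms window,
  10 ms hop, 75–500 Hz search); voiced when the peak reaches 0.45, with a
  sub-octave correction preferring the half lag when it is ≥ 0.85 of the
  best peak (guards against locking onto two-cycle periodicities).
* **Cycle marking** — the signal is zero-phase lowpassed to ~5.5 median f0;
  peaks are chained at the running period spacing, and each cycle boundary
  is the upward zero crossing preceding its peak, refined on a local cubic
  (errors of order nanoseconds on clean harmonic signals). Marking
  boundaries at fixed phase, rather than reading peak-to-peak spacing,
  avoids smearing cycle-to-cycle perturbations across neighbours. Cycle
  amplitude is the RMS over the cycle, integrated with fractional-sample
  boundaries on an 8x band-limited upsampling — exactly proportional to
  peak amplitude for a fixed cycle shape, and free of the picket-fence
  wobble a raw peak read-out has. Cycles inside the filter's edge
  transients (two nominal periods at each end) are dropped.
* **Jitter (local)** — mean |T_i − T_{i−1}| / mean T over a frame's cycles;
  **shimmer (local)** — the same functional on cycle amplitudes. Both need
  ≥ 2 cycles, else missing. Trial-level "mean jitter/shimmer" are means of
  the five frame values; their *variability* is the coefficient of
  variation (sample SD / mean) across the five frame values — the only
  within-trial series the design defines.
* **Syllable onsets** — upward crossings of a 20 ms moving-RMS envelope at
  0.2 x its 95th percentile, with an 80 ms refractory gap. Repeat count is
  the number of onsets; interval variability is the SD of inter-onset
  intervals, overall and per frame (frame of the later onset). The onset
  detector is a documented stand-in: how repeat counts were derived in the
  motivating protocol is unspecified.

## Statistical battery

All analyses consume one long table: subject x task x trial x frame x
feature. Group contrasts use pooled-variance two-sample t tests on
per-subject means (mean over hands/sessions/trials first; df = n_a + n_b −
2, i.e. 38 at 20 + 20). Within-group time courses use one-way
repeated-measures ANOVA across TF1..TF5 on per-subject frame means, with
paired post hoc tests of each frame against TF1, Holm-adjusted. The
interaction models are random-intercept linear mixed models (REML,
statsmodels `MixedLM`, Wald inference):

    value ~ 1 + tf + group + tf:group        (both groups)
    value ~ 1 + tf + updrs3 + tf:updrs3      (PD only)

with tf numeric 1..5 (the design reports a single time-frame slope; the
ANOVA treats frame as categorical), group coded control = 0 / PD = 1, and
UPDRS III uncentered (intercepts then refer to UPDRS = 0; centering is an
option, off by default). Random structure is a subject intercept only —
the subject-level df conventions printed alongside (n_subjects − 2 for the
group model, n_PD − 1 within PD) point to subject clustering without
random slopes. t tests use the residual df approximation; the subject-level
convention is emitted for comparability. A fixed-variance-ratio path
(`re_variance_ratio`) fits the profiled GLS closed form via
Sherman–Morrison; at ratio → 0 it reproduces OLS exactly, which pins down
the model's limiting behaviour. Severity association is summarised by
Pearson r (and r² from simple least squares) on pooled PD observations.
Multiple testing across features is *not* adjusted (each test at α = .05,
matching the design's per-test convention); Benjamini–Hochberg is available
as a flag.

## The synthetic cohort

`sample_cohort` draws 20 PD / 20 control profiles by default: PD UPDRS III
~ N(22.10, 10.64) truncated to [5, 60] and rounded; ages N(68.3, 6.3) (PD)
and N(33.55, 7.85) (controls); H&Y stages {1.5, 2, 2.5, 3} with weights
{.20, .25, .35, .20}; 85% / 50% female. Each subject contributes 2 sessions
x 2 hands of tapping and 2 sessions x 3 trials per vocal task.

Signal-level generators:

* **Tapping** — lognormal inter-tap intervals (mean 0.25 s controls /
  0.55 s PD — positive and right-skewed; ~80 vs ~36 alternating taps per
  20 s hand), with frame-k SD `tap_sigma0 + tap_tf_slope (k−1)`. For PD,
  `tap_sigma0 = 0.029 + 0.0029 u` and `tap_tf_slope = 0.005 + 0.00025 u`
  (u = UPDRS III), anchoring the TF1 level and TF1→TF5 progression of the
  group contrast; controls use 0.0238 and 0.0021 s/frame. 2% of events
  duplicate the previous side to exercise the alternation filter; the clean
  event list is exported.
* **Phonation** — cycle-by-cycle harmonic rendering (fixed per-vowel
  harmonic recipes standing in for two-resonance shaping; f0 150–220 Hz by
  sex) with phase reset at each boundary, so the true period and amplitude
  sequences are exact and exported. Per-frame jitter/shimmer targets are
  linear in frame with severity-coupled slopes; Gaussian period/amplitude
  scatter is calibrated so the *local* perturbation equals the target
  (sigma = target x sqrt(pi)/2). The loudness trajectory maps to the
  amplitude envelope through the inverse of the energy**0.3 compression.
  Additive noise at 30 dB SNR by default.
* **Syllable trains** — decaying voiced bursts (5 ms attack, 25 ms decay,
  120 ms length) at nominal inter-onset intervals set by the group repeat
  counts (~0.125 s controls, ~0.138 s PD), interval SD linear in frame and
  severity, floored at 90 ms; onsets within the last 30 ms are not emitted
  (a burst needs room to exist in the recording). True onsets exported.
  20 dB SNR by default.

Unit conventions adopted where the source scales are ambiguous: printed
DDK interval variability is read as units of 10 ms (divided by 100 for the
audio generator, which works in seconds); printed shimmer magnitudes are
consistent with a dB-type scale and are converted to relative perturbation
by x0.115 (the small-perturbation linearisation of 10^(dB/20)) for audio
targets, while `shimmer_local` itself is the relative ratio.

**Variance anchoring.** Printed group tables give means, SDs and t values
that are mutually consistent only if the SDs describe observation-level
spread (trials x frames pooled) while the t tests act on per-subject means.
The generator adopts that reading: for each feature the between-subject SD
comes from the implied subject-mean SD (Δ·sqrt(n/2)/t), and the
within-subject SD from the remainder of the printed total. For the
frame-resolved PD severity models, the residual SD is set so the simulated
interaction SE matches the printed coefficient SE
(sigma_e = SE x sqrt(N_obs x var(tf) x var(u)), in PD units; controls get a
proportional reduction). Group-mean trajectories come directly from the
printed model coefficients — reassuringly, those coefficients evaluated at
the mean UPDRS and mid-frame reproduce the printed PD group means.

**Scenarios.** `paper_like` uses the anchored severity couplings;
`null_interaction` zeroes both the severity main effect and the interaction
(the stronger reading — the generating distribution must be identical
across UPDRS conditional on frame — implies both), while keeping the
average-severity trajectory so levels are comparable. `custom` accepts
per-feature overrides.

**Feature-level fast path.** `simulate_feature_table` draws the long
feature table directly from the generating model (fixed effects + subject
intercept + Gaussian residual), bypassing audio/tap synthesis. Replication
studies — type-I error, CI coverage, sign recovery at hundreds of cohorts —
run on this path (a full signal-level cohort costs minutes; 500 of them are
out of reach of any sensible test budget). The signal-level paths are
validated separately by the estimator-recovery suites, so the combination
tests the whole chain without conflating the two error sources. Trial-level
aggregate features that the extraction pipeline derives from frame values
(mean variability, trial means) are derived the same way here; the
jitter/shimmer CV features are anchored draws of their own, not the CV of
the simulated frame values — a simplification the direction suite tolerates
because only group contrasts touch them.

**Seeding.** One master seed; every trial's RNG derives from
(seed, subject id, task, trial index) via CRC-hashed `SeedSequence`
entropy, so any trial regenerates bit-identically in isolation. Identical
configurations reproduce byte-identical CSV/WAV outputs (the run stamp
hashes the scientific configuration, not the output path).

## What passing tests do and do not show

The generator emulates the *statistical* structure of the study data —
directions and magnitudes of group contrasts, frame trends and severity
couplings — not human physiology. No tremor spectra, medication on/off
dynamics, formant detail, articulatory variation, recording-channel or
room effects are modelled, and cycle shapes are identical within a trial.
Estimator-recovery results therefore bound algorithmic error under clean,
stationary conditions, not performance on real smartphone audio. Two
contrasts reported as null in the motivating tables (/i/ mean shimmer,
/pa-ta-ka/ interval variability) are reproduced at their printed effect
sizes, which means their *direction* is close to a coin flip in any one
cohort by construction; the direction suite accordingly checks the
contrasts with reported significant differences, and loudness (elevated in
the PD group, opposite the impaired-performance pattern) is summarised but
not direction-checked. Within-PD severity couplings for tapping are taken
from the printed within-PD model, whose slope is shallower than the group
table's TF progression suggests — an inconsistency inherited from the
source, noted rather than resolved.

## Numerical choices and degenerate inputs

Tolerances and knobs (all exposed in config/arguments): voicing threshold
0.45, f0 search 75–500 Hz, 10 ms hop; onset threshold 0.2 of the 95th
envelope percentile, 80 ms refractory; period plausibility gate
[0.6, 1.6] x nominal period; random-effect variance floor 1e-8 with a
`singular` flag on boundary fits (the optimizer falls back from the default
BFGS to CG/Powell if standard errors come back non-finite). Frames with
< 2 intervals or cycles yield missing values; unvoiced trials yield missing
phonation features; an all-identical time course returns F = 0, p = 1;
constant UPDRS makes the severity terms inestimable and raises; empty
feature tables produce a "no data" report rather than a failure. Replicate
counts in the validation suites (30 acoustic, 50 onset, 100–500 cohorts)
were chosen to keep Monte-Carlo error a fraction of each tolerance band at
desk-scale runtimes.
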