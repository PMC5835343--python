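# Methods

This note documents the models, defaults, and numerical choices behind
`gamblerp`, and what its synthetic validation does and does not establish.

## Behavioural task model

The task is a repeated investment game: endowment 20 points per trial,
stakes {0, 4, 8, 12, 16, 20}, win probability 1/3, win multiplier 4, played
in 10 alternating blocks (HF/LF feedback) of 16 trials.  Which condition
opens the session is configurable (`first_block_condition`, default HF);
symmetry of the design makes the choice immaterial for every statistic the
package computes.

Simulated agents draw stakes from a per-condition categorical distribution
(default uniform → risk-neutral, RI ≈ 0, matching the near-zero group
medians the task typically yields) and response times from a log-normal,
the only RT summary available being medians: controls HF 1,083 / LF
1,032 ms, ADHD HF 1,544 / LF 1,274 ms.  The log-normal location is the log
median; the shape parameter (0.45 controls, 0.50 ADHD) was chosen once to
give realistic right-skewed RT spreads (IQR roughly 0.5–2× the median).
RTs are truncated at 20 s, twice the analysis discard limit, so the
generator produces the occasional trial the RT filter exists to remove.
Session clocks place trigger S (trial onset) and I (choice) rtms apart,
followed by a 4 s outcome display in HF (1 s determination message in LF)
and a 1 s inter-trial gap.

Randomness: one `numpy.random.SeedSequence([seed, participant, offset])`
stream per participant, so cohorts are reproducible independently of
simulation order.

### Behavioural endpoints

Total gains sum `points_after` over **all** trials, including trials later
discarded by the RT filter — points are earned regardless of how quickly
the choice was made; risk indexes and RT statistics use retained trials
only.  RT cleaning applies the hard 250 ms / 10 s thresholds first, then a
Local Outlier Factor screen on log RT (k = min(20, n−1), score threshold
1.5) — LOF being the robust-outlier method conventional for this purpose;
with fewer than eight survivors the density estimate is meaningless and
the stage is skipped with a warning.

## Synthetic EEG generator

Each component is a Gaussian bump: polarity-signed peak amplitude per
electrode, FWHM width, mean latency resolved per (group, condition, ROI),
and trial-to-trial latency jitter shared across electrodes within a trial.
Planted latencies reproduce the study's median latency table for N2, P3a
and P3b (both triggers, both ROIs, both groups and conditions); C1 (70 ms,
posterior), premotor build-up M (−150 ms), N500 (490 ms post-onset,
frontal), the N400-like wave (490 ms post-choice, central) and LPP (850 ms
post-choice, centroparietal) sit at their described latencies.  No
amplitude values are reported for any component, so amplitudes (2–6 µV,
tapered across the six midline sites per the described topographies) are
free generator parameters, and only latency — not amplitude — recovery is
treated as a validation target.  Mild group × condition amplitude scalings
are planted on N500 (larger under HF in ADHD) and the N400-like wave
(larger under LF in ADHD) to mirror the qualitative findings;
`add_frontal_interaction` plants stronger ROI-restricted interactions for
power studies.

**Width and jitter choices.**  Component FWHMs default to M 100, C1 30,
N2 40, P3a 44, P3b 60, N500/N400-like 100, LPP 150 ms, with latency jitter
15 ms SD for N2/P3a/P3b and 20 ms for the slower waves.  These are
deliberately at the narrow end of plausible ERP morphology: when
neighbouring bumps overlap appreciably, each one's rising edge displaces
the other's extremum (shift ≈ neighbour slope / own curvature), and with
broader defaults that systematic displacement reaches 10–40 ms — the
planted latencies would then be unrecoverable by *any* peak picker, making
parameter-recovery validation vacuous.  The chosen values keep systematic
displacement below ~4 ms while preserving realistic-looking grand
averages.  All widths, jitters, amplitudes and latencies are configurable
per template.

**Noise.**  Per-epoch additive noise: 1/f ("pink") background (8 µV SD),
amplitude-randomised 10 Hz alpha (3 µV), white sensor noise (2 µV), plus
artifacts at per-minute rates — frontally weighted 150 µV blinks (4/min,
250 ms) and 25 µV high-frequency muscle bursts (2/min, 100 ms).  At these
defaults an 80-epoch average carries ~0.9 µV residual noise against 2–6 µV
components, and a realistic minority of epochs trips the artifact rules.

Epoch stacks can be generated directly (fast path used by the simulation
studies) or a continuous recording can be synthesised and re-epoched; for
non-overlapping trials the two routes are statistically equivalent, and a
test verifies their averages agree on noiseless data.

**What the generator does not emulate:** volume conduction and realistic
channel covariance (noise is channel-independent), non-stationary drowsiness
or drift, saccade potentials, condition-dependent noise, overlapping-epoch
distortion beyond linear superposition, and any amplitude ground truth.
Passing recovery tests therefore show the pipeline is unbiased for
latencies under additive Gaussian-bump signals with 1/f-type noise — not
that it would be artifact-proof on arbitrary real recordings.

## File formats

Recordings round-trip as a raw little-endian float32 matrix (row = channel)
with a JSON sidecar (fs, channels, events) plus an events TSV, or as
16-bit EDF+ with an annotations channel (TAL-encoded `trigger/condition`
descriptions).  The EDF writer is a minimal purpose-built implementation
(1 s records, symmetric physical range, zero-padded final record); its
output is verified in tests against MNE's independent EDF reader, with
quantisation error bounded by one digital step.

## Preprocessing chain

Fixed order: band-pass → epoch → baseline → artifact screen → average.
The 0.1–30 Hz band-pass is a 2-pole Butterworth (nominal −12 dB/octave)
applied forward–backward (`sosfiltfilt`), which preserves component
latencies at the cost of doubling the effective roll-off; padding extends
5 time constants of the 0.1 Hz pole so its transient stays out of the
data.  Epochs use the half-open window [−500, +1000) ms with the trigger
at sample 512 (1,536 samples at 1,024 Hz), giving unambiguous sample
counts.  Baseline is the mean over [−500, 0).  The artifact screen is an
automated stand-in for interactive inspection and ICA ocular correction:
any-channel peak-to-peak > 100 µV or gradient > 50 µV/ms flags the epoch
with the violated rule; baseline correction precedes screening (the
reverse order is available by composing the functions the other way).
Averages require strictly more than 20 clean epochs per condition and
refuse otherwise.

## Peak detection and pooling

A component peak is the largest polarity-signed **local** extremum strictly
inside the search window (N2 [130, 230], P3a [200, 310], P3b [300, 430],
C1 [50, 110] ms; windows bracket every tabulated median with margin), ties
broken earliest.  Requiring a local extremum avoids mistaking slow-wave
ramps (e.g. the CNV slope) for peaks; if the window contains none, the
window-edge extremum is returned flagged `boundary` rather than dropped.
Detection runs on per-participant, per-electrode condition averages —
chosen over ROI-averaged waveforms because pooling then simply
concatenates per-electrode observations (three per participant per ROI
cell), which is switchable by averaging channels upstream.  Latency
detection is invariant to constant offsets by construction.

## Differential analysis

Difference waves are pointwise HF − LF per participant.  Group envelopes
are mean ± SEM with the sample SD (ddof = 1).  The band-separation
statistic integrates (trapezoid) the signed pointwise gap

    s(t) = max(0, lower_A − upper_B) − max(0, lower_B − upper_A)

over a window — zero wherever envelopes overlap, antisymmetric in the
groups, and bounded by the integrated distance between group means.
Windows default to ±50 ms half-width (component-comparable; not uniquely
determined by the analysis definition) around the trial-onset centers 80,
260, 490 ms and choice-locked centers −450, −140, +490, +850 ms.
Significance comes from a two-sided permutation test that reassigns
participants to pseudo-groups and re-derives both envelopes per
permutation (add-one p-value).  The per-electrode window-amplitude profile
integrates each participant's difference curve over the window and
reports the group mean with a seeded percentile bootstrap 95% CI
(n_boot = 2,000) and a Wilcoxon signed-rank test against zero; electrodes
whose CI covers zero are flagged not-significant.  Both the
envelope-separation and the signed-rank readings are provided because
either can be meant by a "band overlap plus rank test" analysis; no
multiple-testing correction is applied across electrodes/windows by
default (per-site reporting), with Holm correction left to the caller.
Note the percentile bootstrap's finite-sample coverage at cohort sizes of
14–32 runs ~1–2 points below nominal — the coverage simulation in the
test suite measures exactly this.

## Statistics

Mann-Whitney U and Wilcoxon signed-rank switch to full enumeration at
small sizes (pooled n ≤ 12; n ≤ 10), which stays exact under ties, and
otherwise use tie-corrected normal approximations; effect size r = |Z|/√N
uses the number of pooled observations.  Φ and Cramér's V come from the
uncorrected χ²; Cohen's d uses the pooled SD.  ρ^G is implemented as the
Gaussian rank (normal-scores) correlation — Pearson correlation of
Φ⁻¹(rank/(n+1)) — the standard robust correlation index this notation
denotes; it is invariant to strictly monotone marginal transforms.
Linear/robust mixed-effects modelling is intentionally exported-not-
implemented: the tidy observation tables (one row per participant ×
electrode × condition × component) are written precisely so standard
fitters can consume them downstream.

## Simulation study sizes

The validation studies use the study-scale conditions: 14 participants per
group (the effective EEG cohort), 160 trials each, 80 epochs per
condition, with 50 seeded replicates for the latency-recovery and
frontal-power checks, 20 for the null calibration, and 500 datasets for
bootstrap coverage.  These sizes give the binomial margins quoted in the
tests (e.g. ≥45/50) while each replicate still exercises the full
generator → preprocessing → detection chain.

## Known limitations

- Latency recovery is validated under the generator's own additive model;
  systematic component overlap beyond the calibrated widths biases any
  extremum-based latency estimate (see width discussion above).
- The EDF writer targets this package's recordings (one rate, ≤16-bit
  dynamic range, 1 s records); it is not a general-purpose EDF library.
- The LOF RT screen flags ~5–10% of well-behaved log-normal draws at the
  conventional 1.5 threshold; treat the threshold as a tunable, not truth.
- No source modelling, re-referencing, or downsampling; channels are
  simulated as referenced.
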