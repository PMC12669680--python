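# Methods

`oculaware` analyzes stimulus-evoked eye metrics — pupil size, blinking, and
microsaccades — as objective markers of visual conscious awareness, with a
focus on cerebral blindness, where stimuli presented in the blind visual
field may or may not reach awareness. This note documents the models,
parameter choices, numerical conventions, and the limits of what the
synthetic data can demonstrate.

## Task and data model

A session consists of blocks of trials with three phases: a pre-stimulus
fixation period jittered uniformly over 3–5 s, a 3-s peripheral stimulus,
and a post-stimulus period jittered over 3–5 s. Stimuli are drawn from two
targets (plus- and x-oriented, requiring an immediate keypress indicating
orientation) and four nontargets (white, glare, nonglare, isoluminant —
graded in real or illusory brightness, requiring no response), presented in
one of two fields (a patient's sighted or blind field; a control's left or
right field). Recordings are monocular at 1000 Hz: pupil diameter in
recorder units (pixels), gaze in degrees of visual angle, with samples
missing wherever the tracker lost the eye.

## Synthetic-session generator

The generator exists because clinical recordings of this kind are not
broadly redistributable; it reproduces the statistical structure the
analysis relies on, with every effect size injectable and known.

- **Evoked pupil kernels.** Targets add a unimodal dilation transient
  (t/τ)·exp(1 − t/τ) with peak at τ = 1.2 s; nontargets add a sustained
  constriction (1 − e^(−t/0.35 s)) held for the 3-s stimulus and recovering
  with a 0.8-s time constant. Kernel amplitudes are per class (defaults
  −90/−60/−30/−10 units for white/glare/nonglare/isoluminant, +60 for
  targets, on a 1000-unit baseline) and are scaled per field by an evoked
  gain (1 in a responsive field, 0 in a fully unresponsive blind field,
  intermediate values for partial blind-field responsiveness). The class
  amplitudes implement the luminance-graded pupillary light response, the
  field gain the awareness manipulation.
- **Noise.** Pupil noise is AR(1) with coefficient 0.99 at 1 ms plus a
  10% white floor, stationary SD 10 units by default. Strong
  autocorrelation matters: i.i.d. noise would make epoch-level
  classification unrealistically easy.
- **Blinks.** An inhomogeneous Poisson process (base 0.25 events/s,
  500-ms refractoriness) modulated by piecewise-constant multipliers in
  the windows 0–0.5 s and 3–3.5 s after stimulus onset (defaults:
  suppression ×0.2 at onset, enhancement ×2 at offset). Each blink blanks
  the pupil for a lognormal duration (median 150 ms, log-SD 0.4) flanked
  by 30-ms, 400-unit ramp artifacts so the detector sees the rapid
  fluctuations real eyelid closure produces.
- **Microsaccades.** A modulated point process (base 1.5 events/s, 50-ms
  refractoriness) realized as raised-cosine gaze steps of 0.1–1.0°
  amplitude over 2–12 ms, direction random but biased back toward fixation
  once gaze strays beyond 0.5°, so position does not random-walk away.
  Fixational drift is white noise smoothed over ~200 ms plus a 0.002°
  white tracker-noise floor, keeping intersaccadic gaze velocity near
  1 °/s as in head-fixed video-oculography.
- **Behavior.** Each target is perceived with a per-field probability;
  perceived targets get a keypress at onset plus a truncated-normal
  latency (mean 0.9 s, SD 0.25 s), with the correct orientation key chosen
  with probability 0.9 by default.
- **Seeding.** One master seed expands into named substreams (trials,
  pupil noise, blinks, microsaccades, gaze, responses, blanks, …), so each
  component is independently reproducible and perturbable.

What the generator does *not* emulate: arousal-linked slow pupil drifts,
head movement, binocular disagreement, saccadic suppression of the pupil,
main-sequence coupling between microsaccade amplitude and duration, and
verbal reports (the pipeline proxies report frequency with the blind-field
perception rate). Tests passing on synthetic sessions therefore demonstrate
the pipeline's correctness and statistical calibration, not the empirical
effect sizes of patient data.

## Preprocessing

Blinks are flagged by three independent criteria on the pupil trace:
missing samples, absolute sample-to-sample change above 10 units/ms, and
deviation from the session median beyond 5 × MAD. Flags are padded by
50 ms per side and intervals closer than 100 ms merge. Cleaning replaces
blink samples by linear interpolation between bracketing valid samples and
smooths with a 50-ms centered moving average. With the default generator
amplitudes an occasional deep evoked constriction can trip the MAD
criterion — a confound real pupillometry shares — so detector ground-truth
tests use configurations with evoked amplitudes disabled.

Microsaccades are detected from gaze velocity using the standard
moving-window estimator (centered differences over a 5-sample window, edge
samples undetectable) with per-axis thresholds λ·σ, where
σ = √(median(v²) − median(v)²) is the median-based velocity SD and λ = 6.
A candidate is a run with elliptic criterion (vx/ηx)² + (vy/ηy)² > 1
lasting ≥ 6 ms; candidates overlapping blinks or exceeding 1° displacement
are discarded, and events closer than 20 ms merge. These defaults follow
the fixational eye-movement detection literature and are all exposed in
`MicrosaccadeParams`. By construction the detector cannot see events
shorter than its minimum duration, so sensitivity is validated over
injected events within that operating range (where it exceeds 0.99 at the
default noise calibration, with no false detections).

## Epoching

Epochs span −9000..+9000 ms around event onset (18,001 samples). Every
stimulus gets one paired blank event drawn uniformly from 4000–7000 ms
after its onset, clipped to end 1000 ms before the next onset (or before
block end for a block's final trial); a stimulus whose admissible interval
is empty gets no blank and is dropped from paired analyses. Pupil epochs
are baselined to the mean of the 1000 ms before the event; binary epochs
never are. Exclusion (over −1000..+6000 ms): pupil epochs with any raw
value > 1750 units or more than 50% missing samples; binary epochs with
more than 50% of samples lacking valid tracking. The thresholds are strict
inequalities (a value of exactly 1750, or exactly 50% missing, is
retained). The literal variant of the binary rule — excluding epochs in
which more than half the *values* are zero — would also reject epochs that
merely contain few blinks; it is available behind `literal_zero_rule` but
the tracking-validity reading is the default. Excluded epochs are masked,
not deleted, so stimulus/blank pairing survives exclusion bookkeeping, and
a pair is dropped whenever either member is excluded. Blink/microsaccade
fraction timecourses are per-sample means over included epochs, smoothed
with a 100-ms centered moving average (the width is a package choice; it
is exposed in `fraction_timecourse`).

## Stacked classification

Stimulus-vs-blank decoding uses two levels of linear maximum-margin
(hinge-loss) classifiers with C = 1, per-training-fold feature
standardization, and a 2000-iteration solver cap (applied uniformly to
observed and permutation-null fits; decision signs stabilize long before
the cap on these problem sizes). First level: one classifier per eye metric on epoch
samples from (0, 4000] ms averaged in 20-ms bins (200 features; raw-sample
mode via `bin_ms=1`). Ten-fold cross-validation is stratified by
construction: stimulus/blank pairs are assigned to folds as units, which
both balances labels per fold and prevents twin leakage between a stimulus
epoch and its temporally adjacent blank. Second level: a linear classifier
on the three out-of-fold signed decision scores, trained and evaluated
with the *same* fold partition, so no epoch's final prediction is informed
by any model that saw it. A second-level score of exactly 0 predicts
blank (conservative toward the null). Accuracy is the fraction of correct
held-out predictions; chance is the majority-class proportion.
Classification is restricted to epochs included for all three metrics.
When a session yields fewer pairs than requested folds, the fold count
drops to the pair count. The leakage guarantee is checked structurally and
empirically: 200 full-pipeline label permutations center on chance.

Group statistics: one-sided Wilcoxon signed-rank of accuracy against
per-participant chance; paired Wilcoxon for within-group condition
contrasts; one-sided Mann–Whitney U for blind-field accuracy in aware vs
unaware patients; Holm–Bonferroni applied separately within the
against-chance and cross-condition families. Signed-rank p-values use
exact sign-flip enumeration over midranks when n ≤ 16 with no zeros,
otherwise the normal approximation with zero-splitting.

## Behavioral and brightness statistics

A target is perceived if a keypress lands in (onset, onset + 5000 ms];
presses are credited greedily to the earliest unmatched target, so one
press never counts twice, and the false-positive rate is unmatched presses
over total presses. Orientation accuracy is correct keys over perceived
targets (chance 0.5, two-target task versions only); a one-sided exact
binomial test evaluates accuracy above chance. Reaction-time comparisons
use a paired signed-rank test, trimming to the common trial count when
lengths differ (unpaired rank-sum as a flagged fallback); responses later
than 3 s are flagged as possibly offset-locked but not modeled.

Brightness judgments over the three pairings (10 trials each) award
1 / 0.5 / 0 points for brighter / equal / dimmer, so each stimulus spans
0–20 points; per pairing the two stimuli always split the trial count.
Group-level: Friedman test over the three stimuli, post-hoc paired
Wilcoxon (glare vs nonglare, nonglare vs isoluminant) with Holm
correction.

The correspondence table reduces three measures to present/absent per
blind field: task behavior present iff perception rate > 0.25, verbal
report present iff awareness reported on > 10% of trials, and eye metrics
present iff at least one metric shows a stimulus-evoked response. The last
designation is visual in origin; the operational criterion here is
classification accuracy above the 95th percentile of its permuted-label
null (`eye_metric_presence`), with the pipeline using an exact binomial
screen as a cheap stand-in.

## Luminance-slope pupil analysis

Per participant and stimulus (white, glare, nonglare), the minimum of the
mean baselined pupil trace over (0, 1500] ms measures peak constriction.
A least-squares line through the three minima against ranks 1–3 (computed
in closed form for the equally spaced ranks, so degenerate equal minima
give exactly zero slope) summarizes the luminance gradient; rank coding
makes the expected pattern — deepest constriction for white, weakest for
nonglare — a positive slope. The group test is a Wilcoxon signed-rank of
slopes against zero, one-sided by default (two-sided available), with
Pratt handling of exact zeros and Holm correction across participant
groups. Calibration checks: with 1:1:1 injected amplitudes the rejection
rate is ≈ α; with 3:2:1 amplitudes across 8 simulated participants power
exceeds 90%.

## Field-potential statistics

Single-sensor traces are band-passed 0.1–115 Hz (4th-order Butterworth,
zero-phase) with notches at 60 and 120 Hz, then segmented into 8001-ms
epochs centered at event time + 19 ms (the projector's presentation
delay). The evoked-response generator places a P1 bump at ~100 ms, an N2
trough centered at 160 ms, and a sustained late negativity from ~250 ms,
in femtotesla, per condition.

The cluster-based permutation test baseline-corrects each epoch by its
mean over −500..0 ms (per-epoch rather than per-condition-average; the
choice is recorded here because either reading is defensible), computes
pooled-variance two-sample t-values per sample over 0..500 ms, forms
maximal contiguous same-sign runs where |t| exceeds the two-sided critical
value at cluster-forming α = 0.05, scores each run by its summed t, and
compares against the maximum |mass| over label exchanges
(default 5000; p = (1 + #{null ≥ observed}) / (1 + n_perm)). Zero-variance
samples map to t = 0, so identical epochs yield no clusters rather than
an error. The three contrasts (sighted vs blank, blind vs blank, sighted
vs blind) run as independent families with no cross-contrast correction,
matching per-contrast reporting conventions. Empirically the family
type-I error sits at ≈ 0.05 under the null.

## Pipeline

`run_full_analysis` wires the stages together for a roster of simulated
participants; the default roster mirrors the study shape (8 controls, 4
blind-aware patients at blind-field evoked gain 0.4, 4 blind-unaware at
gain 0) with 10 blocks of 40 trials each, and writes a deterministic
summary JSON plus a log of every parameter in effect. Test runs use
smaller rosters and 1–2 blocks; statistical calibration suites use
replicate counts of a few hundred, sized so the whole suite runs on one
CPU in minutes while keeping Monte-Carlo error well inside each asserted
tolerance.

## Known limitations

- The blink detector's MAD criterion and large evoked constrictions can
  interact (see Preprocessing); on real data the margin is wider because
  blinks drive the recorded pupil far below any evoked change.
- Microsaccade amplitude and duration are sampled independently, so the
  synthetic main sequence is flat; detection metrics are unaffected but
  velocity-based amplitude analyses would be.
- The false-positive rate is a session-level quantity (keypresses carry no
  field label) and is reported identically per field.
- Verbal report has no generative model; correspondence analyses on
  synthetic data proxy it with the blind-field perception probability.
- Cluster p-values are resampled, so label-swap symmetry holds exactly for
  cluster masses but only to Monte-Carlo error for p-values.
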