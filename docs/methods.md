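# Methods

## Problem setting

The pipeline classifies five functional activities — sit, stand, walk, stair
ascent, stair descent — from a single waist-worn triaxial accelerometer
sampled at 30 Hz, for a cohort of 11 healthy subjects (3 sessions, no
device) and 11 KAFO users recorded over 3 sessions with each of two leg
orthoses: a passive stance-control brace ("control") and a
microprocessor-controlled brace ("novel"). The scientific question is how
much the *specificity* of the training data (same population? same device?
same person?) matters when predicting a patient's activities on the novel
device. No real recordings ship with the package; the cohort is synthetic
(below), and the study-level claims are therefore ordinal — which training
schemes beat which — not numeric reproductions of accuracies measured on
real patients.

## Windowing

Recordings carry half-open labeled intervals `[start, end)`. Windows are
6 s (180 samples) with 75% overlap (stride 1.5 s = 45 samples), anchored at
the start of each labeled interval and never crossing a boundary, so every
window has exactly one label; trailing partial windows are dropped. An
interval holding D seconds of samples yields `floor((D − 6)/1.5) + 1`
windows (0 if D < 6). Anchoring per interval is a deliberate resolution of
transition handling: the protocol is scripted with ≥ 30 s activity blocks,
so discarding boundary-straddling content costs little and guarantees clean
labels. Because overlapping windows within a session share samples, the
pipeline only offers session- and subject-level train/test splits (all five
schemes are at least session-level), never window-level random splits, which
would leak.

## Features (131 per window)

Eleven families over axes x, y, z, in a frozen registry order with sizes
(9, 9, 12, 12, 1, 1, 3, 6, 6, 12, 60):

1. mean, range, interquartile range per axis;
2. population SD, skewness, excess kurtosis per axis;
3. per-axis counts of z-scores in the four equal bins partitioning [−2, 1)
   (width 0.75); out-of-range z-scores are excluded, not clipped — the bin
   arithmetic (12 features over 3 axes) forces exactly 4 bins;
4. mean, SD, skewness, kurtosis of the first difference per axis
   ("moments of the derivative"; the alternative reading — a derivative of a
   scalar moment — is undefined for a single window);
5. mean of the squared norm ax² + ay² + az²;
6. sum of the three axial SDs;
7. Pearson r for xy, xz, yz;
8. mean cross-products per pair, raw (`mean(ai·aj)`) and normalized
   (`mean(zi·zj)` on z-scored axes — deliberately redundant with Pearson r,
   preserving the original 131-feature inventory rather than deduplicating);
9. absolute values of those six means (read as |mean(product)|, not
   mean(|product|));
10. mean, SD, skewness, kurtosis of the one-sided periodogram ordinates per
    axis;
11. mean periodogram power in the twenty 0.5 Hz bands covering [0, 10) Hz
    per axis.

Conventions, fixed so every oracle is reproducible: quantiles use linear
interpolation; skewness/kurtosis are population (biased) estimators, kurtosis
as excess; the periodogram uses a rectangular window after mean removal,
normalized so the ordinates sum to the population variance (Parseval) — at
L = 180 and 30 Hz the bin width is 1/6 Hz, so every 0.5 Hz band holds three
ordinates. Zero-variance axes take fallback values (skew/kurt 0, histogram
counts 0, Pearson r and normalized products 0) so outputs are always finite.
A vectorized batch path featurizes stacks of windows; tests pin it to the
per-window reference implementation at 1e-12.

## Classifier

`sklearn.ensemble.RandomForestClassifier` with √p features per split,
unlimited depth, `n_jobs=1`, seeded. Tree counts default to the tuned values
of the emulated study — 10 for the healthy-trained model, 50 for all others —
and `tune_n_trees` re-exposes the tuning as leave-one-group-out balanced
accuracy over an explicit grid (10, 25, 50, 100), since the original grid is
not documented. No class weighting or resampling: imbalance is handled at
the metric level.

## Evaluation

Balanced accuracy is the mean of per-class recalls TP_i/n_i over classes
*present* in the test set; absent classes (patients who cannot do stairs)
are flagged rather than averaged as NaN, keeping the metric defined per
patient. Scheme comparisons report median and IQR per scheme, a
Shapiro-Wilk normality note, and four sequential two-sided Wilcoxon
signed-rank tests along the specificity order at α = .05 with no
multiple-testing correction (four separate planned tests). Zero differences
are discarded; for n ≤ 12 the exact null is enumerated over all 2^n sign
assignments with midranks under ties, above that the normal approximation is
used. The per-patient score of the leave-one-session-out personal scheme is
the mean over its session folds.

Learning curves draw, for each n, `n_iterations` random (test patient,
n-subject training set) pairs — subjects without replacement within a draw,
the test patient never in their own training pool — and report the median
balanced accuracy with a 95% percentile-bootstrap CI of the median
(`n_bootstrap` resamples). Both the raw median (the point estimate) and the
bootstrap mean-of-medians are emitted, since either can serve as the curve's
center. Patient-trained curves extend to n = 10 of 11 patients.

## Synthetic cohort generator

Each activity is a gravity orientation (unit vector, 1 g) plus, for dynamic
activities, three harmonics of a cadence fundamental with per-axis
amplitudes, plus white noise. Defaults: sit and stand differ by 50° of trunk
pitch; walk 1.8 Hz, stair ascent 1.2 Hz, stair descent 1.4 Hz, with distinct
per-axis amplitude ratios (0.15–0.40 g fundamentals) and noise SD 0.02–0.08 g.
Sessions follow the scripted order sit, stand, walk, stairs up, stairs down
with default durations 60/60/120/20/20 s — stairs deliberately
underrepresented (stairs windows ≈ 26% of walking windows) to reproduce the
class imbalance that motivates balanced accuracy.

Two effect-size dials define the hierarchy:

* **Subjects** (`delta_subject`, default 1): per-subject log-normal
  amplitude scale (SD 0.25), cadence shift (SD 0.15 Hz), orientation jitter
  (half-normal, SD 8°), plus a 3°-SD per-segment session wobble and a small
  per-(subject, device) response jitter (log-SD 0.08).
* **Devices** (`delta_device`, default 1): each device sits at a distortion
  coordinate c (none 0, control 0.5, novel 1.0). Scaled by `delta_device`,
  the coordinate drives a posture tilt (10°·c), per-activity log-linear
  amplitude and cadence factors that are strongest on the stairs classes
  (stairs-ascent cadence ×e^0.32c drifts toward walking cadence), and a
  harmonic-redistribution "pattern shift" on stairs. Placing the control
  brace at c = 0.5 folds the patient-population gait alteration into the
  device axis: healthy-trained models face the full c = 1 mismatch,
  control-trained models half of it, novel-trained models none — which is
  what makes the specificity ordering emerge. With both dials at 0 every
  subject shares identical generative parameters, giving the
  parameter-recovery regime (held-out balanced accuracy > 95%).

All randomness flows from one integer seed through named
`numpy.random.SeedSequence` substreams keyed by (seed, stream, subject,
device, session, segment), so cohorts are bitwise reproducible and adding a
subject never perturbs another subject's data; the substreams are also
independent of the effect sizes, so distances between device conditions grow
smoothly (and, per the tests, strictly monotonically) in `delta_device`.

What the generator does **not** emulate: biomechanically realistic gait
waveforms, free-living (unscripted) behavior, activity transitions (segments
switch instantaneously), sensor drift or re-mounting variability, and the
heterogeneity of real neuromuscular impairments. Synthetic cohorts are
consequently *cleaner* than real data — absolute balanced accuracies run
high (medians 0.77–1.00 versus mid-50s to mid-70s on real patients) — so
passing tests certify the pipeline's correctness and the direction of the
specificity effects, not field accuracy.

## Problem sizes and profiles

The comparison experiments run on the full default cohort (22 subjects,
16 929 windows). Stochastic stages have three profiles: `paper`
(1000 learning-curve iterations, 1000 bootstrap replicates — the emulated
study's values), `test` (50/200), and `smoke` (6/100). The shipped analysis
scripts use desk-scale draw counts (12 iterations / 200 replicates per
curve point) and the suite's ordering experiment uses five reduced cohorts
(4 healthy + 6 patients, shortened sessions) at `delta_device = 1.5`, the
documented strong-effect threshold at which the median ordering
healthy ≤ impairment-specific ≤ device-specific ≤ patient+device-specific
is expected in at least 4 of 5 seeds.

## Known limitations

* The five schemes assume every patient has novel-device data for all
  sessions; recordings with missing sessions simply shorten the
  leave-one-session-out folds.
* 30 Hz is assumed, not enforced: other rates are accepted (band-power bins
  stay [0, 10) Hz) but nothing resamples.
* The Wilcoxon exact null enumerates 2^n sign patterns and is capped at
  n = 12 by design; the cohorts of interest have 11 patients.
* Device relabeling (control ↔ novel) swaps the schemes' *training*
  selectors exactly, but also moves the test set to the other device's
  windows, so scheme scores are not numerically symmetric under relabeling —
  only the selector symmetry is guaranteed (and tested).
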