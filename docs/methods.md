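# Methods

This note documents the models, defaults, and numerical choices behind
`restpredict`, and what its synthetic-data tests do and do not establish
about real clinical EEG.

## Outcome model

The outcome is a binary response label derived from the Montgomery–Åsberg
Depression Rating Scale (MADRS, 0–60 points): responder iff the score
decreased by at least 50% from baseline to week 8.  The boundary is read
inclusively (exactly 50% counts as response) and tested explicitly; scores
at exactly the boundary are rare in practice but the convention matters for
the synthetic generator, which draws responder percent-decreases on
[50, 100] and nonresponder decreases strictly below 50.  Subjects without a
week-8 score cannot be labeled and are dropped from all modeling.

## Synthetic cohort generator

The generator's defaults describe the emulated study population: 122
subjects over four sites (52/45/18/7), responder fraction 55/122, week-2
recordings for 115 of 122, 250 Hz sampling, 60 s of resting EEG per
recording, 19-channel 10–20 montage.  MADRS trajectories use baseline
~ N(30.1, 5.8) truncated to [12, 55] and group-specific truncated-normal
percent decreases (responders: mean 73.3, SD 16 on [50, 100];
nonresponders: mean 20.4, SD 21.6 on (−40, 50)), with the week-2 score
halfway down the trajectory plus 3 points of noise.  Scores are kept as
continuous reals so that the ≥ 50% rule reproduces the intended group
assignment exactly; rounding to integer MADRS points could flip
near-boundary subjects.

Per channel, the signal is a sum of

* a 1/f background (spectral exponent 1, RMS ≈ 8 µV with log-normal
  between-subject variation),
* a subject-specific alpha oscillator (9.5–10.5 Hz, ~6 µV, doubled over
  posterior electrodes),
* optional effect oscillators or an autocorrelated AR(1) component
  (φ = 0.97) blended into the channel, and
* white sensor noise with a site-specific floor (1.5–3 µV), the whole
  channel scaled by a site-specific gain (0.9–1.15).

Group effects are parameterised as Cohen's *d* on the underlying
subject-level parameter: band-power effects shift the log-amplitude of an
oscillator placed at the band's centre frequency (between-subject SD 0.15
dex, so log band power inherits the intended *d* as long as the oscillator
dominates the band — verified by a Monte Carlo test recovering d = 1.0
within ±0.3 at n = 200); complexity effects shift the AR(1) mixing weight
(mean 0.35, SD 0.08), lowering sample entropy for the group with larger
weights.  Week-2 recordings reuse the same subject parameters with fresh
noise plus week-2-specific effects, giving the early-change feature source
a known ground truth.

Two propagation properties of the model are worth knowing when reading
ranking maps.  First, the average reference spreads any focal oscillator
into every channel (−1/E per channel), so a week-2-only frontal effect also
shifts week-2 entropy and spectra elsewhere on the scalp — as it would in
real average-referenced EEG.  Second, the AR(1) blend rescales the carrier
signal, so complexity effects also perturb total power slightly.  Injected
effects are therefore detectable beyond the nominal channels/bands, and
tests that need a clean one-feature story use the feature-level generator
instead (below).

What the generator does **not** emulate: volume-conducted anatomy (the
leadfield is a random average-referenced matrix, labeled synthetic),
realistic artifact morphologies (only amplitude outliers), eye-state
effects, medication or drift effects within a session, and any correlation
between EEG features and MADRS beyond the group labels.  Passing tests
therefore demonstrate that the *procedure* behaves correctly under known
effects — not that any particular real-data accuracy is attainable.

The feature-level generator (`simulate_feature_cohort`) skips signal
synthesis entirely: features are iid standard normal with a mean shift of
*d* between groups on a chosen subset, optional per-site offsets.  It is
the right tool for calibrating the ranking and evaluation machinery at
exactly specified effect sizes, and is what the null-calibration and
signal-recovery tests use (at n = 120, matching the cohort scale).

## Preprocessing

Defaults: resample to 250 Hz, reorder/subset to the target montage, average
reference; 60 Hz line removal by a zero-phase 4th-order Butterworth
band-stop (58–62 Hz); band-pass 1–30 Hz for spectral/microstate/source
analysis and a parallel 0.5–55 Hz copy for entropy (entropy is sensitive to
aggressive filtering); 2 s epochs; rejection of any epoch exceeding
±100 µV; at least 15 surviving epochs or the subject is flagged for
exclusion.  All of these are config-exposed — they are reasonable
stand-ins for a multi-site harmonisation protocol, not a claim about any
specific study's supplement.

## Feature classes

* **Spectral**: Welch PSD with one Hann segment per 2 s epoch, no overlap,
  zero-padded to ≤ 0.5 Hz resolution; band power by trapezoid integration
  over the seven-band grid; absolute power, log10-transformed before
  modeling (stabilises variance for t-tests).  Lateralization is
  (L−R)/(L+R) on raw power — bounded, scale-free, undefined (missing) only
  when both sides are zero.  Note the trapezoid rule half-weights band-edge
  bins: an on-bin tone adjacent to a band edge attributes a predictable
  1/12 of its power outside the band (tested analytically).
* **Multiscale entropy**: m = 2, r = 0.15 × SD, 70 scales.  The tolerance
  is fixed in absolute terms from the scale-1 SD of each recording and held
  constant across scales (the original multiscale-entropy convention).
  Entropy is computed on the concatenated artifact-free signal, not on 2 s
  epochs: at scale 70 a 2 s epoch would leave ~7 coarse samples.  Scales
  whose coarse length falls below 100 samples return NaN, and undefined
  estimates (zero template matches) return NaN rather than ±∞.  Missing
  entropy values are excluded feature-wise from ranking, not imputed.
* **eLORETA**: fixed (scalar) source orientations; regularisation α
  expressed as a fraction (default 0.05) of the mean eigenvalue of KKᵀ;
  fixed-point iteration from unit weights, tolerance 1e-6 on the relative
  weight change, max 100 iterations, with non-convergence reported (not
  silently accepted).  The defining zero-localization-error property is
  verified exhaustively over all 200 sources of a 20×200 synthetic
  leadfield.  Source features computed on synthetic anatomy are exactly
  that; users may supply a real leadfield plus ROI map as delimited text.
* **Microstates**: k = 4 by default; polarity-invariant modified k-means on
  GFP-peak maps (class update = dominant eigenvector of the members'
  covariance), best of 10 restarts by GEV, deterministic given the seed.
  One group-level model is fitted across subjects and back-fitted per
  recording, so microstate features are comparable across subjects;
  a per-recording model can be fitted with the same function.  Labels are
  smoothed by merging segments shorter than 30 ms into their predecessor.

## Feature sources and assembly

Early change is the raw difference week-2 − baseline per feature (percent
change is ambiguous for log-scale and signed features); combined is the
column-wise union of baseline and early-change features, tagged to keep
keys unique.  The baseline source keeps all subjects; the other three keep
the week-2 subset.  Z-scoring is deliberately **not** part of assembly — it
is fitted inside each training partition during evaluation, to keep
held-out statistics out of the model.

## Ranking and selection

100 iterations; each draws 80% of subjects without replacement, stratified
by class; Welch (unequal-variance) two-tailed t-test per feature;
p < 0.05 earns a vote.  Selection keeps features with votes ≥ T.  The
per-iteration alpha is 0.05 and config-exposed.  A property worth knowing:
votes are strongly *dependent* across iterations (all subsamples share the
full-sample t-statistic), so the null vote distribution is heavy-tailed —
the bulk sits near 100·α = 5, but one null feature in ~10³ will score very
high by chance.  Vote counts are a stability ranking, not calibrated
p-values, and the threshold T should be read accordingly.

The column-wise Welch test is implemented directly with nan-aware vectorised
moments (validated against `scipy.stats.ttest_ind(..., nan_policy="omit")`
to 1e-15); the scipy path per column is several hundred times slower on
matrices with thousands of features.

## Classification and evaluation

Class-weighted RBF SVM; C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}, γ ∈ {2⁻¹⁵, …, 2³} (log₂
steps of 2); inner stratified 5-fold CV choosing (C, γ) by balanced
accuracy, ties broken toward smaller γ then smaller C, deterministically.
The inner search precomputes RBF kernels per (fold, γ) and shares them
across the C grid.  Outer evaluation: stratified 10-fold CV with ranking,
selection, and scaling refit on each training partition (a non-nested mode
that ranks once on all data exists for comparison and is flagged as
optimistically biased); and leave-one-site-out validation, default T = 60,
reporting per-site confusion counts, sensitivity, specificity, and balanced
accuracy plus the pooled row.  Sites whose test set lacks a class get NaN
for the undefined rate and a `degenerate` flag.  Subjects missing a
selected feature are dropped from that fit with a logged count.  A leakage
canary test (an oracle feature encoding the label only in held-out rows
must not lift accuracy) guards the wiring.

## Label-noise ceiling

Given per-subject (baseline, week-8) scores taken as truth, each Monte
Carlo replicate adds independent N(0, σ²) noise to both visits (a
week-8-only variant is selectable), derives observed labels from the noisy
scores by the same ≥ 50% rule, and scores the oracle that always outputs
the true label against the observed labels with balanced accuracy.  The
ceiling is the replicate mean with a 2.5–97.5 percentile interval.  Draws
depend only on (seed, replicates, n), so a σ grid under one seed uses
common random numbers and the estimated curve is monotone non-increasing;
σ = 0 gives exactly 100% and σ → ∞ tends to 50%.  Only subjects near the
50% boundary flip at small σ, so the ceiling is a property of the cohort's
percent-decrease distribution as much as of σ.  This oracle formulation is
one defensible definition of "upper bound on achievable accuracy"; σ must
be supplied by the user (e.g., from test–retest literature), and the
package makes no claim about any particular study's ceiling.

## Problem sizes used in scripts and tests

The `analysis/` drivers run the EEG-level pipeline at a reduced scale
chosen to keep a desktop run comfortable while preserving the study's
structure: 40 subjects over four sites (18/12/6/4), 8 electrodes, 40 s
recordings, three injected effects (frontocentral complexity d = 1.2 at
both timepoints; posterior high-alpha d = 1.0 at both timepoints; frontal
mid-beta d = 0.8 at week 2 only).  The test suite exercises the EEG-level
path end-to-end at n = 24 with 6 electrodes and 16 s recordings, and the
statistical calibration suites at the full n = 120 in feature space.
Ranking requires at least 10 non-missing values per class by default
(config-exposed); the small end-to-end runs lower this floor to match their
fold sizes.

## Known limitations

* EDF export is not provided (no writer dependency); recordings persist in
  a documented HDF5 container, while EDF and BrainVision are supported for
  reading.
* The eLORETA implementation covers fixed-orientation sources only; free
  (3-moment) orientations, real head models, and statistical mapping in
  source space are out of scope.
* Microstate features are procedure-faithful but no claim is made about
  their predictive value; remission-type (absolute score) outcome criteria
  and scales other than MADRS are not implemented.
* The accuracy ceiling and all accuracies reported by the analysis scripts
  describe synthetic cohorts with known effects; they are calibration
  evidence, not clinical results.
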