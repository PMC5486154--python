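# Methods

## Problem setting

Subject-specific EEG emotion classifiers need labeled calibration trials
from the very person they will serve, and with music- or film-length
stimuli those trials are scarce (here: 16 trials of 30 s per subject, one
binary valence and one binary arousal label each).  Transfer learning
borrows labeled trials from other subjects ("source subjects", SS) to
improve a "target subject" (TS), but blind borrowing can *hurt* —
negative transfer — because emotional EEG signatures differ strongly
between people.  The framework implemented here makes transfer
conditional: it asks *when* to transfer (only for subjects whose own-data
model is no better than chance), *how* (from the sources with the most
similar discriminative feature spaces), and *what* (the sources' labeled
trials, pooled with the TS's training trials before the feature space and
classifier are rebuilt).

## Feature chain

Each 30-s trial is transformed with a short-time Fourier transform using
a 50%-overlapping 1-s Hamming window, giving a one-sided periodogram per
frame at (for a 1-s window) 1-Hz resolution.  Bins outside 1–50 Hz are
discarded — this realizes the band-pass — and the rest are grouped into
the five stereotyped bands δ(1–3), θ(4–7), α(8–13), β(14–30) and
γ(31–50 Hz).  Band power is the *mean* of the bins whose center
frequency lies inclusively inside the printed range, which keeps bands of
different widths on a common scale; with a 1-s window every printed band
edge coincides with a bin, and at non-integer resolutions bins falling in
the gaps between printed ranges are dropped.

Each (trial, channel, band) power series is divided by its own mean over
the frames lying fully inside the first 5 s of the trial — the gain-model
baseline calibration — yielding a dimensionless power ratio; a zero
baseline is treated as degenerate input, not silently patched.  The
differential-laterality (DLAT) feature for a symmetric electrode pair and
band is the left-minus-right difference of these calibrated series,
averaged over the post-baseline frames (frames starting at ≥ 5 s).
Baseline frames are excluded from the pooled value because they define
the reference; an `include_baseline_frames` switch restores them.  The
left-minus-right direction is a fixed convention, verified by the
antisymmetry test (swapping pair members negates every feature).  With
the standard 30-channel montage (12 symmetric pairs derivable from 10-20
label parity) and 5 bands the feature vector has 60 entries.  Finally
each feature column is z-scored across the subject's 16 trials
(population denominator); constant columns are zeroed and flagged.

## ReliefF and feature-count selection

Feature relevance uses two-class ReliefF with Manhattan distance on
max-min-scaled features, k nearest hits and misses per sampled instance,
every instance sampled once (`m="all"`, fully deterministic).  k defaults
to 10 clipped to (smallest class size − 1) — with 15 training trials that
is 6 — because the literature's recommendation of 10 cannot exceed the
class size.  Neighbour-distance ties break by ascending instance index,
ranking ties by ascending feature index.  Note one analytic property of
neighbour-based ReliefF relevant to testing: duplicating every instance
does *not* leave weights unchanged, because each duplicate becomes its
own zero-distance nearest hit and the hit penalty vanishes; the test
suite asserts this true behaviour.

The number of features d is selected per training set by the
add-one-feature-in protocol: ReliefF ranks all features, then over
`n_balance_reps` repetitions (500 by default; 50 in the desk-scale runs
below) the majority class is subsampled to the minority size, stratified
5-fold cross-validation is run, and a Gaussian naive Bayes is evaluated
on every ranked prefix d = 1…60.  The selected d maximizes accuracy
pooled over repetitions × folds, smallest d on ties.  Internally all
prefixes are evaluated in one pass by cumulative summation of per-feature
log densities along the ranking — naive-Bayes log joints are additive
over features, so this is numerically identical to refitting per d (unit
tested) while ~60× cheaper.  If the minority class is smaller than the
fold count the repetitions fall back to leave-one-out CV.

## Classifier

Gaussian naive Bayes with empirical class priors and per-class
per-feature moments (population denominator).  Variances are floored at
1e-9 × the largest pooled feature variance so within-class constant
features cannot produce division errors; posteriors are computed in log
space and exact ties resolve to class 0.  Under the balanced subsampling
used throughout, priors are 1/2 each up to a one-instance imbalance in a
CV fold.

## Transfer logic and validation

Every subject in turn is the TS; all others are SSs.  Leave-trial-out
(LTO) validation holds out each of the 16 trials once; the held-out trial
is never seen by ReliefF, by the similarity computation, by the
feature-count optimization, or by classifier training within its fold (an
optional audit records SHA-1 row hashes so tests assert this).  The
subject's *default* accuracy is the LTO accuracy using only its own 15
training trials per fold.

Transferability gate ("when"): a subject is *poor* — and therefore a
transfer candidate — iff its default accuracy is at or below the chance
level (0.5 for two balanced classes; the boundary is inclusive on the
poor side).  By default the gate uses the subject's own full-LTO default
accuracy, matching how the good/poor groups are defined in the original
analysis; a `nested` option estimates the gate per fold from the 15
training trials only for strictly prospective use, at ~15× cost.

Similarity ("how"): per LTO fold, ReliefF weights from the TS's 15
training trials are correlated (Pearson, on raw weight vectors) with each
SS's weights computed from that SS's full 16 trials; the O most similar
(or most dissimilar, as a control) sources are selected.  Ties break by
ascending subject id.  A Spearman option exists because "similar
ReliefF-sorted feature spaces" admits a rank-based reading.  The TS–SS
dissimilarity statistic is the population standard deviation of the
absolute correlations of the selected sources.

Augmentation ("what"): the selected sources' full trial sets, with their
own task labels, are row-concatenated with the TS's 15 training trials
(15 + O × 16 rows), sources in ascending-id order so the augmented set
depends only on the selected *set* — this makes the similar and
dissimilar modes provably identical at O = n − 1.  ReliefF is re-run and
d re-optimized on the augmented set; the final model is trained on one
seeded balanced subsample of it and tested on the held-out TS trial.

Scenarios: `default` never transfers; `rTL` (routine) always transfers;
`cTL` transfers only to poor subjects, leaving good subjects'
results bit-identical to default; `oTL` keeps the per-subject best of
default and transferred accuracy — an oracle upper bound, not a
prospective method.  Scenario comparison uses paired two-sample t-tests
on per-subject accuracies plus one-sample t-tests of improvements
against zero; zero-variance difference vectors are reported as
degenerate (a self-comparison gives t = 0, p = 1) instead of erroring.

## Randomness and reproducibility

All randomness flows from one master seed through
`numpy.random.SeedSequence([master, subject, fold, stage, repetition])`
derivations, where the stage code distinguishes default-pass
optimization, default final fit, transfer-pass optimization and transfer
final fit.  The derivation never depends on the scenario, so a transfer
fold computed for rTL is bit-identical to the same fold under cTL or oTL;
`fit_all_scenarios` exploits this to serve all four scenarios from one
shared pass.  Identical seeds give bit-identical results.

## Synthetic cohorts

The generator emulates the shape of a 26-subject music-listening study
(16 trials × 30 channels × 30 s at 250 Hz, jointly balanced binary
valence/arousal labels — four trials per label combination) with two
scientific knobs:

* **engagement** ≥ 0 — the per-subject SNR of the class-discriminative
  signal; 0 plants a non-engaged subject whose data carry no class
  information whatsoever.
* **signature_similarity** ρ ∈ [0, 1] — each subject's discriminative
  pattern is `unit(ρ·common + (1−ρ)·idiosyncratic)` over the active
  (pair, band) slots; ρ = 1 plants a cohort-common signature.

Each channel is 1/f pink noise plus per-band band-limited Gaussian
noise.  On the active slots the left/right band amplitudes are modulated
post-baseline by ±(engagement × effect_size × pattern) according to the
trial's class label; the first 5 s are never modulated, so the
calibration baseline is class-neutral.  Active slots default to four
frontal alpha pairs for valence and four centro-parietal beta pairs for
arousal — the hemispheric-asymmetry loci the affective-EEG literature
most often reports — disjoint between tasks so both label sets act
independently on one signal.  Defaults: effect_size 0.5, pink exponent 1,
overall amplitude 10 µV, ρ 0.7.

A per-(trial, channel, band) amplitude perturbation
(`amplitude_noise_sigma`, default 0.2, applied post-baseline like the
class modulation) gives band power realistic trial-to-trial variability.
Without it every nonzero asymmetry is asymptotically detectable from the
~50 pooled frames and engagement degenerates into a switch; with it,
engagement 0.3–0.5 produces the near-chance "weakly engaged" regime and
engagement ≥ 1 a clearly separable one, mirroring the wide accuracy
spread real cohorts show.

What the generator does *not* emulate: eye blinks and other artifacts,
ERP-like transients, nonstationarity beyond the baseline/response split,
volume-conduction correlations between channels, oscillatory phase
structure (the class signal lives purely in band-power amplitude, which
is all the feature chain observes), or any relationship between the two
tasks' signals.  Passing tests therefore demonstrate the pipeline's
correctness and its qualitative transfer behaviour under controlled
conditions, not expected accuracy levels on real recordings.

`planted_truth` exposes the ground truth for recovery tests: expected
transferability (poor iff engagement = 0) and two subject-by-subject
matrices — the signed pattern correlation (what class-conditional DLAT
expectations realize) and the pattern-magnitude overlap.  ReliefF weights
a feature by how informative it is, not by which hemisphere dominates, so
similarity in ReliefF-weight space is sign-blind and the magnitude
overlap is the ordering it can recover; the recovery test asserts
Spearman ≥ 0.6 against that matrix in a high-SNR, 48-trial cohort.

`structured_cohort_spec` freezes an 8-subject cohort used by the
hypothesis tests: three engaged cluster members sharing the cohort
signature (engagement 1.2, ρ = 1), two engaged but fully idiosyncratic
subjects (ρ = 0), two weakly engaged cluster members (engagement 0.35)
and one non-engaged subject.  On it, conditional transfer improves the
gate-defined poor group (regression to chance for the signal-free
subject, genuine signal gain for weak cluster members borrowing from the
cluster), routine transfer degrades the good group on average (the
idiosyncratic subjects suffer most), and similar-source selection beats
dissimilar-source selection for the poor group across the O sweep.

## Desk-scale problem sizes

The heavy checks run at sizes chosen for a single CPU: chance-level
calibration uses 20 cohort seeds × 8 subjects with 50 balance
repetitions; the hypothesis tests use 10 seeds of the structured cohort
(4 seeds for the full O = 1…7 similar/dissimilar sweep).  The 500-rep
optimization and 26-subject cohorts remain the defaults of the public
API.

## Gate noise and its consequences

With 16 trials the default-accuracy estimate of a truly signal-free
subject is approximately symmetric around 0.5 (empirically
P(accuracy ≤ 0.5) ≈ 0.6), so the chance-level gate identifies such a
subject as poor only somewhat better than a coin flip, and per-subject
gate agreement with planted labels is intrinsically limited.  The
recovery test therefore pools agreement across cohorts dominated by
clearly informative subjects.  This is a faithful property of the
gate-at-chance design at this trial count, not an implementation
artifact; prospective deployments with more trials per subject would
sharpen the gate.

## Known limitations

* EDF export requires MNE's optional `edfio` backend; without it the NPZ
  array container is the interchange format (EDF *reading* always works
  through MNE, with its 16-bit quantization caveat on round trips).
* The z-transform is computed across all 16 trials per subject before
  LTO, as in the original protocol; it mildly couples folds at the
  normalization level even though all modelling steps are fold-disjoint.
* Only binary tasks and a single shared montage per cohort are
  supported; cross-dataset transfer and multi-class tasks are out of
  scope.
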