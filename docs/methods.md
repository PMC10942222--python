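# Methods

This note documents the models, conventions and design choices behind the
package, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Timeline data model

A case is a time-ordered list of gesture events over the two analyzed LC
phases (MHT, DGB).  Times are seconds relative to the phase start, with
half-open intervals `[start, end)`: an event may begin exactly when the
previous event on the same stream ends.  Streams are (phase × hand); events
on different hands may overlap (bimanual work), events within one stream may
not.  Unattributed events (single-instrument gestures) form their own
stream.  Events sort by (phase, start, hand, label), a total order, so any
permutation of input rows parses to the same timeline and file writes are
byte-stable (canonical float rendering at µs-irrelevant 1e-6 precision).

The default vocabulary has 14 gestures.  Six names are fixed by the
annotation scheme this package models (hook, inefficient hook, grasp,
inefficient grasp, push, blunt dissection); the remaining eight (pull,
spread, retract, cut, clip, coagulate, suction, irrigate) are declared
placeholders completing a clinically plausible LC vocabulary, and the six
bimanual gestures (grasp, inefficient grasp, push, pull, spread, retract)
are tracked per hand, giving 2×6 + 8 = 20 categories.  Functional classes:
dissection = {hook, inefficient hook, blunt dissection, cut, clip,
coagulate, spread}; exposure = {grasp, inefficient grasp, push, pull,
retract, suction, irrigate}.  Inefficient variants inherit the class of
their base gesture and therefore contribute to the D/E ratio.  All of this
is overridable through a YAML/JSON taxonomy config; feature cardinalities
follow the configured vocabulary (2C + 23 features for C categories).

## The 63 features

Counts and total durations per tracked category are summed over MHT+DGB
combined (per-phase variants are out of scope).  Interval features are the
mean/max/min/sample-SD (ddof = 1) of inter-event gaps, computed within each
phase (never across the phase boundary) for three streams: all events,
left-hand events, right-hand events.  Gaps in the all-events stream can be
negative when hands overlap; they are clamped to 0, reading them as "no
idle time".  A stream with fewer than two events reports all four
statistics as 0 with a logged warning, so the vector length never varies.
Shift frequency is the number of label changes between consecutive events
of a stream, divided by manipulation time in minutes — a rate rather than a
raw count, so it is comparable across cases of different operative length.
The D/E block reports class counts and durations, their ratios, and the
per-minute rate of D↔E class changes along the all-events stream.  Ratio
denominators of zero are floored at 1 event / 1 s (with a warning) to keep
feature matrices finite.  Manipulation time is reported in minutes
(units cancel after standardization; minutes match how operative time is
conventionally reported).  Total: 20 + 20 + 12 + 3 + 7 + 1 = 63.

## Ratings and grouping

mGOALS scores four items, each 1–5 (the GOALS autonomy item is dropped for
independently operating surgeons); a case score is the mean over raters of
the item sums.  Agreement uses ICC(2,1) — two-way random effects, absolute
agreement, single measure, computed from the two-way ANOVA mean squares —
with the conventional 0.75 qualification threshold, plus Kendall's W with
midrank ties and the standard tie correction.  ICC(2,1) was chosen because
the same fixed pair of raters scores every video and absolute agreement
(not mere consistency) is what qualifies a rating panel.

Grouping is per surgeon on the mean of that surgeon's case scores, using
linear-interpolation empirical quantiles at 0.25/0.75 (both configurable):
bottom below q1, top above q3, boundary scores medium (the natural
resolution of "within the quartile" at ties).  The binary split is
competent (top + medium) vs incompetent (bottom), and a surgeon's label
propagates to each of their videos.  Item-level binary targets mirror this
construction per item (below the item's 0.25 quantile), which is invariant
to monotone rescaling of the item scores.

## Group statistics

The 2×2 outcome test is the uncorrected Pearson χ² (continuity correction
off, matching how such tables are conventionally reported in this
literature), with a warning when an expected count falls below 5 and an
error on zero marginals.  Feature contrasts report both a Kruskal–Wallis
rank test — identical to the tie-corrected Mann–Whitney for two groups —
and Student's t, plus the direction of the group difference.  No
multiple-testing adjustment is applied across the 63 features by default;
a Benjamini–Hochberg option exists but is off, since the feature screen is
descriptive rather than confirmatory.

## Augmentation

Class balancing oversamples minority timelines with perturbed copies:
boundary jitter (Gaussian truncated at ±1.5 SD; ordering, positivity and
same-stream non-overlap re-enforced by clipping), independent event
deletion (at least one event always survives; p_delete = 1 is rejected),
and duplication-with-jitter.  Labels are never altered and every output
passes full timeline validation.  The scheme is the event-stream analogue
of light text augmentation (synonym-level noise, deletion, insertion).
Augmentation happens strictly inside training folds — perturbing cases
before the fold split would leak case identity into held-out folds.

## Classification

Cross-validation is five-fold, stratified by class and grouped by surgeon
(all of a surgeon's videos share a fold) so models cannot score by
recognizing a surgeon's style rather than skill.  Per fold, feature
standardization is fit on the training rows only; augmentation, when
enabled, regenerates features from perturbed training timelines.  Scores
are continuous (class probability or SVM margin), never hard labels, and
AUC is the in-package midrank Mann–Whitney form, which equals the
trapezoidal area under the tie-aware ROC curve.  Cell summaries report the
fold-mean AUC (default) and the pooled-prediction AUC; single-class folds
are skipped with a log note and the cell averages the rest.

Hyperparameters are fixed, conventional defaults, not tuned values:
logistic L2 with C = 1; SVM RBF with C = 1, gamma scaled by feature count
and variance; 500-tree random forest; 100 trees of depth 3 at learning
rate 0.1 for gradient boosting; AdaBoost over 100 depth-1 stumps.  All are
overridable per model.  Feature importance offers the native profile
(|coefficients| or impurity importances; unavailable for the RBF SVM) and
permutation importance (mean AUC drop over column shuffles, floored at 0),
the latter being the cross-model default because it is comparable across
families.  Scores are normalized to sum to 1; the top-10 list breaks ties
by feature name for determinism.

## Synthetic cohorts

Each video is a two-phase alternating semi-Markov stream: exposure and
dissection blocks with exponential dwell times (mean exposure dwell 25 s),
filled with log-normal events (median ≈ 4.5 s, σ = 0.45) separated by
short exponential gaps; consecutive event labels persist or shift with a
configured probability, and labels are drawn from per-class weights with
inefficient variants substituting their base gesture.  Phase durations are
log-normal around 330 s (MHT) and 220 s (DGB), so a default competent case
runs ≈ 9 min and an incompetent one ≈ 1.5× longer — cohort operative times
land near the 11-minute scale typical of simple LC.

The group contrasts are direct parameters: the incompetent group has a
2.0× inefficient-substitution rate, 1.5× phase durations, 2.0× label-shift
probability, and a D/E dwell ratio lower by the configured 1.6 fold
(competent dwell ratio 1.25 × 1.6 = 2.0 vs 1.25).  Because block dwell
means determine the expected D/E duration ratio and the event-fill process
is class-symmetric, the configured fold is recovered in the extracted
`de.dur_ratio` feature — the generator is self-calibrating, which is what
the parameter-recovery tests exploit.  Vascular injury is Bernoulli per
video at 6.1% (competent) / 30.8% (incompetent).  Latent skill is drawn
per surgeon (≈ N(17.4, 1.3) competent, N(13.6, 1.2) incompetent, clipped
to disjoint ranges so the bottom quartile of scores tracks the true
group), wobbles slightly per video, and two simulated raters emit
rounded/clipped item scores with Gaussian noise (SD 0.35 per item), which
keeps two-rater ICC above the 0.75 qualification threshold.

What the generator does *not* model: real inter-feature correlation beyond
what the shared skill group induces (feature-driving processes are drawn
independently given the group), anatomy or difficulty effects (Parkland
grade and CVS score are carried as inert metadata), cross-hand
simultaneity (generated events never overlap, though the data model allows
it), and rater idiosyncrasies beyond symmetric noise.  Passing tests
therefore show that the pipeline recovers *configured* structure, not that
real annotated cohorts are classifiable at any particular AUC.

## Problem sizes and numerical choices

Tests and the acceptance script use cohorts of 40–600 videos for pipeline
and classifier checks (150 videos / 66 surgeons for effect recovery and
headline CV), 10 000-video draws for outcome-rate recovery (the test pools
three independent draws, shrinking the Monte-Carlo SE on a 30.8% rate to
≈ 0.45 points), 10 000 label permutations for type-I-error calibration,
and 100 seeded replicates for importance-ranking reliability.  The null
cohort check uses 600 videos so each model's fold-mean AUC noise (SD
≈ 0.03) sits well inside the ±0.1 chance band.  Event times are written at
1e-6 precision and generated on a 1 ms grid with a 10 ms separation floor
so rounding can never reorder a stream.  Every stochastic component — the
generator, augmentation, fold assignment, tree ensembles, permutation
importance — takes an explicit seed, and the pipeline manifest (config
hash, seeds, per-artifact SHA-256, no timestamps or absolute paths) is
byte-identical across re-runs of the same configuration.

## Known limitations

Gesture definitions beyond the six named ones are placeholders; analyses
that depend on the identity of the remaining vocabulary should supply
their own taxonomy config.  The interval-feature and shift-frequency
stream allocation (all/left/right) is one defensible reading of a
12 + 3 feature budget and is configurable in principle only by replacing
the feature module's stream list.  Kendall's W between exactly two raters
cannot fall much below 0.5 under independence (W = (ρ+1)/2 for k = 2), so
it is a coarse screen there; ICC carries the qualification decision.
Augmentation hyperparameters are an interpretation of "NLP-style"
augmentation for event streams, not a reconstruction of any specific
published recipe.
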