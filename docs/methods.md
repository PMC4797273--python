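# Methods

## Binding-event classification

Peaks are BED-convention intervals (0-based, half-open) with an absolute
summit position; narrowPeak summit offsets are converted to absolute
coordinates on read, and an offset of −1 (summit not called) falls back to
the interval midpoint. Two peaks *a* (TF A) and *b* (TF B) qualify as a
co-occupied pair when

    overlap(a, b) / |a| ≥ f   and   overlap(a, b) / |b| ≥ f,

with f = 0.30 by default (`min_frac`). Overlap is computed on full peak
intervals; summits are used only for window centering downstream. Every
input peak yields exactly one record (`A_only`, `co_occupied` or `B_only`),
so a co-occupied region contributes two records, one per source TF — the two
partners' summits are generally at different positions, and the two sides of
the contrast are analyzed separately for that reason.

When several partners qualify, a peak is assigned the partner with the
largest min of the two fractions, ties broken by leftmost partner start,
then end, then name. Nothing in the definition forces a single partner; we
chose a deterministic single-best-partner rule so that event tables are
exactly reproducible (the alternative — recording all qualifying partners —
changes nothing about the three-way categorization, only the partner
annotation). The implementation is a start-sorted sweep with an active
candidate set; the test suite checks it against an all-pairs brute-force
classifier on random instances up to 1,000 peaks per TF.

## Feature quantification

* **Windowed signal.** For each record the `window_bp` (default 100 bp)
  window centered at the summit is counted against each read track; a read
  counts when it overlaps the window by ≥ 1 bp (a 5′-end-in-window rule is
  available via `count_mode="five_prime"`; the choice is not dictated by the
  definition of RPKM and both are exposed). RPKM = count / (window kb) /
  (library millions); the model feature is log₂(RPKM + 1). The pseudocount
  (default 1.0, configurable) handles zero counts, which are legitimate and
  common.
* **Profiles.** The 6-kb span around the summit is cut into 100-bp bins;
  each bin is converted to RPKM with the bin width as region length and
  averaged per event category. Bins extending past a chromosome edge are
  excluded from that site's contribution rather than zero-filled; per-bin
  site counts record the denominator.
* **GC content** is (G+C)/(A+C+G+T) on the same central window, case
  insensitive, N excluded from the denominator, all-N missing.
* **Methylation** is the mean CpG beta over the window; windows without a
  CpG have no measurement. When methylation is part of the feature set those
  rows are dropped (most binding sites carry no CpG, so imputing would
  manufacture a value for the majority of rows); otherwise the column is
  simply absent.
* **Chromatin state** is the label of the segmentation interval containing
  the summit (half-open convention at boundaries), one-hot encoded over the
  full state alphabet; a gap is missing.
* Strand is ignored throughout: nothing in the analysis orients windows.
* bedGraph coverage tracks are supported as an alternative to read
  intervals; there is no library size in that mode, so the statistic is the
  base-pair-weighted mean coverage (log₂ with pseudocount), not RPKM — a
  documented mode difference, not an approximation of it.

## Contrasts

Each feature column is compared between co-occupied and solo sites with a
two-sample t-test, missing cells excluded pairwise. The default is Welch's
unequal-variance form: the two event classes routinely differ greatly in
size and spread, and Welch is the safe default in that regime; the pooled
Student form is available (`equal_variance=True`) and both agree with
closed-form oracles to 1e-10 in the tests. Degenerate zero-variance input
follows the convention t = 0, p = 1 for equal means and p = 0 otherwise. Raw
p-values are the primary output (enrichment thresholds for this kind of
contrast are conventionally quoted raw); a Benjamini–Hochberg column is
emitted alongside.

## Classifiers and evaluation

All four kinds operate on z-scored features (training-set mean/sd, stored on
the model and reapplied at prediction; required by the RBF kernel, harmless
elsewhere; constant features are retained with an sd floor of 1).

* `rbf_margin`: scikit-learn SVC, C = 1, gamma = 1/n_features on the
  standardized data — the common untuned heuristic; a decision value is the
  score.
* `tree_ensemble`: scikit-learn RandomForestClassifier (100 trees), class-1
  probability as the score.
* `gaussian_nb`: per-class per-feature mean and variance (floored at 1e-9)
  with empirical class priors; the score is the exact log-odds.
* `linear_discriminant`: pooled covariance, w = Σ⁻¹(μ₁ − μ₀), intercept from
  the class midpoint and prior ratio; singular covariance triggers a ridge
  fallback (1e-6 · mean diagonal). NB and LDA are written from their closed
  forms so the linear-vs-nonlinear comparison does not depend on an opaque
  implementation; both are checked against analytic formulas in the tests.

Evaluation draws a stratified split — floor(2/3) of each class trains, the
rest tests — repeated 10 times; repetition *i* uses master seed + *i* for
both the split and the classifier. AUC is the exact rank statistic
P(score⁺ > score⁻) + ½ P(tie); the ROC curve sweeps unique score thresholds
from (0,0) to (1,1). ACC uses the kind's natural threshold (probability 0.5
for the forest, 0 otherwise; configurable) — no tuned threshold, since none
is implied by the procedure. No class rebalancing is applied: AUC is
insensitive to imbalance and ACC is reported as-is with class sizes logged.

Cross-cell transfer applies a trained model to the *full* feature matrix of
another cell — no refit, training-cell standardization reused. Using the
full set rather than a held-out third maximizes the test size and involves
no leakage because nothing from the target cell enters the model; the
alternative would only shrink n. |ΔAUC| is the absolute difference between
the within-cell mean AUC and the transfer AUC on the same test cell,
feature set and classifier.

Models serialize to versioned JSON: NB/LDA parameters and the SVM's kernel
expansion (support vectors, dual coefficients, intercept, gamma — evaluated
directly with numpy on load) are stored natively; the random forest embeds
an opaque base64 payload, the one part of a model file that is not
human-readable.

## Synthetic data

The generator produces complete inputs in the standard formats with *exact*
truth labels. Defaults describe one simulated "cell": two chromosomes of
1.5 Mb, 500 sites per class (A-only, B-only, co-occupied), 300-bp peaks, 12
signal channels (DNase I accessibility plus 11 histone channels including
H2A.Z), 36-bp reads, and a 15-state segmentation.

* **Placement.** Sites occupy disjoint slots (≥ 1 bp apart) placed uniformly
  per chromosome, so solo peaks overlap nothing by construction. A
  co-occupied pair shares the peak width; the partner summit offset is drawn
  Normal(0, 60 bp) and clamped to ±⌊0.7 w⌋ so the reciprocal fraction is
  ≥ 30% with certainty. Truth labels are therefore exact, and the tests
  require the classifier to reproduce them for 100% of sites after a full
  file round trip.
* **Counts.** Central-window counts are negative binomial via Poisson–gamma
  mixing: mean μ = 20 reads for solo windows, μ·2^e for co-occupied windows,
  variance μ + μ²/r with size r = 10 (r → ∞, i.e. `dispersion=None`, is the
  Poisson limit and is unit-tested). Default effects e: +1.5 on the six
  active channels (DNase I, H2A.Z, H3K4me2, H3K4me3, H3K9ac, H3K27ac), 0 on
  five channels, −0.5 on H3K27me3 — the typical enrichment direction at
  co-occupied sites.
* **Read placement.** A solo site's reads are placed uniformly among the
  positions that overlap its central window. For a co-occupied pair a single
  count is drawn and every read is placed where it overlaps *both* partners'
  windows (possible whenever the summit offset ≤ window + read − 2 bp, the
  vast majority under the default jitter; otherwise the partners get
  independent draws with non-overlapping placement ranges). Both windows
  therefore observe exactly the configured count law, and the class
  difference in mean log₂-RPKM recovers the configured effect within
  sampling error — a property the tests assert at 3 standard errors.
  5,000 background reads per channel are scattered uniformly (≈ 0.3 reads
  per 100-bp window, negligible relative to μ = 20). The per-channel library
  size is the total read count actually emitted.
* **Sequence, methylation, states.** Bases are i.i.d. with G+C probability
  0.41 genome-wide, 0.45 in solo windows, 0.55 in co-occupied windows. CpGs
  are Poisson-placed at 10/kb with Beta-distributed betas (concentration 10)
  around means 0.75 background / 0.60 solo / 0.25 co-occupied — co-occupied
  regulatory regions are modeled hypomethylated. The segmentation tiles each
  chromosome with exponential-length segments (mean 1 kb, min 200 bp) and
  uniform states E1–E15; the segment containing a co-occupied summit is
  reassigned to an active state E1–E4 with probability 0.9.
* `SyntheticConfig.null()` zeroes every class difference (effects, GC,
  methylation, state preference) for calibration experiments.

What the generator does **not** emulate: mappability and copy-number
artifacts, fragment-size distributions and strand asymmetry, motif-bearing
sequence, spatially correlated signal outside the central window, and
peak-calling noise (peaks are given, not called). Passing tests therefore
show that the pipeline's arithmetic, bookkeeping and statistical behavior
are correct under the stated generative model — not that the reported
classification accuracies would be attained on experimental ENCODE-scale
data, where signal-to-noise is far less favorable.

## Problem sizes and numerical choices

The bundled tests run the classifier-oracle comparison at up to 1,000 peaks
per TF (100 instances), the null-calibration and signal-recovery
experiments at 500 sites per class with 12 channels (20 and 10 seeds,
2 repetitions per seed), and the transfer experiment on 5 independent cell
pairs — sizes chosen so the full suite completes in about a minute on one
core while keeping Monte-Carlo bands (binomial 95% for test calibration,
±0.05 for chance-level AUC) meaningful. All randomness flows from explicit
seeds: the generator uses a single `numpy` Generator per cell, evaluation
fans a master seed out as seed + repetition index, and identical seeds
reproduce byte-identical written files.

Known limitations: the single-best-partner rule discards secondary partner
annotations; coverage-mode tracks cannot be mixed meaningfully with RPKM
tracks in one model (units differ); the tree ensemble's JSON payload is
opaque; and ACC at the default threshold is sensitive to class imbalance in
a way AUC is not.
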