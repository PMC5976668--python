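# Methods

## Problem and model

The package addresses two-class phenotype prediction from a genes × samples
log2 expression matrix when one class is rare and the sample is small (the
emulated design: 36 subjects, 12 fatigued vs 24 non-fatigued). The binary
phenotype is defined from a patient-reported instrument: FACT-F totals on
the 16–53 scale, *fatigued* iff the score decreases by ≥ 3 points from
baseline to the 1-year follow-up (a boundary decrease of exactly 3 is
fatigued). Fractional totals are accepted but logged, since the instrument
sums integer item scores.

Feature relevance is measured per gene by the Fisher's ratio
FR_j = (μ_j1 − μ_j2)² / (σ²_j1 + σ²_j2), with unbiased (n−1) class
variances (a `ddof` switch exposes the maximum-likelihood variant). FR is
invariant to location/scale changes of the data and symmetric in the
classes; it is a separability score, not a test statistic, which is why the
pipeline also reports conventional ANOVA/FDR differential expression — the
two rankings deliberately disagree on genes with large mean shifts but
heterogeneous classes.

Fold change is the difference of class mean log2 intensities (fatigued −
non-fatigued). The printed default bands (FR ∈ [0.70, 1.72], FC ∈
[−0.92, −0.15] ∪ [0.09, 1.13]) straddle zero with magnitudes < 2,
consistent with log2 differences rather than linear ratios; all intervals
are treated as closed on both ends. The band is always an explicit input —
the package never infers it from data.

## Classification and signature search

The classifier is 1-nearest-neighbor with Euclidean distance on the
selected genes' log2 values ("the reduced base"); no rescaling is applied
by default because all features share the log2-intensity scale. `k` (odd)
and the metric (`euclidean`, `correlation`) are configurable, and an
optional z-scoring mode standardizes using training-fold statistics only.
Accuracy is leave-one-out cross-validated, hence always an integer multiple
of 1/n. Distance ties resolve to the lower sample index; vote ties (only
possible when the effective neighbor count is even) resolve to the nearest
neighbor.

The minimal signature is found by recursive elimination from the bottom of
the FR-ranked list: the LOOCV accuracy of every top-k prefix is evaluated
for k = n … 1 and the smallest k attaining the maximum observed accuracy is
returned, with the full accuracy curve. For the default classifier the
whole curve is computed in one sweep by accumulating per-gene squared
distance contributions (squared Euclidean distance is additive over genes),
which is algebraically identical to evaluating each prefix separately; the
equivalence is tested against a naive per-prefix loop and an exhaustive
enumeration oracle.

Because features are ranked on the full dataset before the LOOCV loop, the
reported accuracy carries the selection-bias optimism inherent to this
methodology; the package reproduces the procedure rather than correcting
it, and the sampler below is the method's own uncertainty control.

## Network sampler

Networks are gene subsets, not pathway objects. Each draw takes a size
uniform on [size_min, size_max] (defaults 2–20) and that many distinct
genes uniformly from the high-FR pool; the subset's LOOCV accuracy is
scored, and subsets at or above the retention threshold are kept (default:
the minimal signature's accuracy minus 1/n, i.e. one misclassification of
slack). The posterior sampling frequency of a gene is the fraction of
retained networks containing it; the integer membership counts are kept
alongside so the consistency identity (Σ frequencies × n_retained = Σ
retained sizes) can be checked without floating error. A single RNG stream
is consumed strictly draw-by-draw and scoring consumes no randomness, so
results depend only on the seed. Draw count defaults to 10,000.

## Synthetic data

The generator emulates: two classes of 12 and 24 samples; per-gene Gaussian
log2 intensities around a grand mean of 7.0 (typical normalized microarray
scale); planted genes shifted by `effect_size` log2 units in the fatigued
class; additive per-batch offsets (default 3 batches, SD 0.2 log2 units)
shared across genes and assigned round-robin so batches are balanced across
classes; and FACT-F pairs (baseline uniform integer in [30, 50], decrease
uniform integer in [3, 8] for fatigued, [−3, 2] for non-fatigued) that
reproduce the labels exactly under the ≥ 3-point rule. Defaults
`effect_size = 0.6`, `sigma_within = 0.5` place planted genes at population
FR 0.72 and fold change +0.6, inside the default selection bands; the
planted population FR (e²/2σ²) is the closed-form oracle used throughout
the tests. 54,675 features and 40 planted genes are the default scale.

What the generator does **not** emulate: probe-level effects and background
(simulation starts at the summarized matrix), heavy-tailed or
intensity-dependent noise, gene–gene correlation blocks, confounded
batch/class designs, negative or heterogeneous planted effect sizes, and
clinical covariates. Passing tests therefore demonstrate correctness of the
algorithms and their behavior under an idealized Gaussian design, not
robustness to those real-data features.

## Numerical choices and degenerate inputs

- Zero summed class variance: FR = 0 if the means agree, +inf otherwise
  ("perfect separability", ranked above all finite ratios and excluded by
  any finite FR ceiling).
- Rank ties broken by gene-id lexicographic order (stable mergesort).
- Differential expression: two-group one-way ANOVA computed as the
  equal-variance t-test (F = t² on 1, n−2 df); zero-variance genes get
  p = 1 when group means agree and the smallest positive double when they
  differ, with a logged warning; q-values by Benjamini–Hochberg
  (statsmodels), significance at q < 0.05.
- Quantile normalization maps average ranks onto the mean sorted profile
  (ties interpolate between adjacent reference values); a single-sample
  matrix is returned unchanged with a warning. Idempotent to float
  tolerance.
- Batch correction subtracts per-gene batch means and restores the per-gene
  grand mean — the exact fixed-effect solution for a one-factor batch model
  with no covariates, and an identity for a single batch.
- Signature tie at equal accuracy: smallest subset size wins.
- Pipeline seeding: the global seed is fanned out to stage seeds via
  SHA-256 of `"{seed}:{stage}"` (kept below 2³¹), so stages re-run in
  isolation reproduce the pipeline.

## Design choices where the design was open

- Whether scoring happens before or after batch removal is configurable;
  the default applies scoring after normalization and batch removal.
- The elimination scheme is prefix peeling of the ranked list (remove the
  single lowest-ranked gene per step), which makes the search exhaustive
  over prefixes and deterministic; no re-ranking occurs between steps.
- The sampler's subset-size law, draw count, and retention rule are not
  dictated by the method's definition; uniform sizes, uniform draws, and an
  accuracy threshold are the minimal choices and all are exposed in
  `SamplerConfig`.
- An LDA-projection variant of the classifier is a possible reading of the
  method family's name; the operational definition implemented here is
  FR ranking + nearest neighbor, and the classifier interface (`k`,
  `metric`, z-scoring) is the extension point for such variants.

## Problem sizes used by the checks

The acceptance script runs the default chip-scale profile (54,675 × 36,
seconds of runtime thanks to vectorized scoring and the cumulative-distance
prefix sweep). The test suite uses 300–10,000-gene profiles chosen so each
statistical check has the power it needs: null calibration at 10,000 genes
(binomial 99% bounds on the type-I rate), permutation nulls at 200
permutations (3-standard-error bands), planted-recovery checks at 1,000–
2,000 genes over 20–25 seeds.

## Known limitations

- LOOCV accuracy is optimistic when feature selection precedes it (see
  above); external validation is out of scope.
- The FACT-F range is enforced as 16–53; totals of a 13-item 0–4 scale
  would arithmetically span 0–52, but the instrument's printed range is
  treated as authoritative.
- `correlation` distance requires ≥ 2 genes and is undefined for constant
  sample vectors.
- The sampler scores subsets with the default 1-NN Euclidean classifier
  regardless of the signature-stage settings.
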