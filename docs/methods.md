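# Methods

## The relevance score

A dataset is a gene-by-sample matrix **E** (*n* × *m*) whose rows have been
centered, so each sample is a point in an *n*-dimensional gene space and the
total sum of squares ‖E‖² is *m* times the total sample variance. A query
gene set of size *k* defines, through its binary membership indicator **p**
over the dataset's genes, the unit direction **p**/√k. The score

pctVar(E, p) = ‖Eᵀp‖² / (‖E‖² · k) · 100

is the fraction of total variance explained by projecting the samples onto
that direction, as a percentage. It coincides with PCA's explained-variance
functional evaluated at a fixed rather than optimal direction, which yields
two exact properties used as test oracles: the score never exceeds the first
principal component's variance share, and it is invariant to any orthogonal
rotation of the sample coordinates (it depends on **E** only through
**E Eᵀ**).

The denominator uses the overlap count *k* (query genes present in the
dataset after gene filtering), not the full query size: genes absent from a
dataset contribute nothing to the numerator and should not dilute its score.
A configurable minimum overlap `k_min` (default 1, the most permissive
defensible choice) excludes datasets the query barely touches; excluded
datasets are reported with the reason rather than silently dropped.

## Preprocessing

Each raw dataset passes through:

1. **Normalization.** RNA-seq counts: logCPM, log₂(c/colsum·10⁶ + 1), which
   removes library-size differences; a zero library size is a hard error.
   Microarray intensities: log₂(x+1) when the matrix maximum exceeds 100
   (linear-scale heuristic; threshold configurable), then quantile
   normalization to the mean empirical distribution, with ties receiving the
   mean of the reference quantiles they span.
2. **Gene filtering.** The 10 000 most highly expressed genes (row mean of
   the normalized matrix) are retained; ties at the cutoff keep the earlier
   row, and gene order is preserved.
3. **Row centering**, which the score requires.
4. **Sample reduction.** Datasets with more than 20 samples are compressed
   by truncated SVD to scores **U**ᵣ**S**ᵣ (genes × r) and column-orthonormal
   loadings **V**ᵣ (samples × r), r = min(20, m, rank). Row centering
   survives reduction exactly because the right singular vectors of a
   row-centered matrix are orthogonal to the all-ones vector.

After reduction the score's denominator is the stored representation's own
Frobenius norm (‖UₛSₛ‖²), not the pre-reduction norm. This keeps the score
self-consistent: for any dataset of rank ≤ 20 the reduced score equals the
full-matrix score to machine precision (a tested contract), and for higher
rank the discarded energy leaves both numerator and denominator. The
loadings are stored so the per-sample query profile — the mean centered
expression of the query genes, (pᵀUₛSₛ)Vᵀ/k — can be reconstructed for the
metadata correlation.

## Monte Carlo significance

The P-value of an observed score s is the probability that a uniformly
random gene set of the same size, drawn without replacement from the
dataset's retained genes, scores ≥ s. Sampling from the dataset's own gene
universe (rather than a global one) matches how the indicator is defined.

* **Exact**: full enumeration, guarded to C(n,k) ≤ 2·10⁵; the oracle for the
  other two estimators.
* **Simple Monte Carlo**: p̂ = (r+1)/(N+1) over N uniform subsets — the
  standard conservative estimator, never zero.
* **Adaptive multilevel splitting** for small tails: an odd-sized population
  (default 101) of random size-k sets is repeatedly conditioned on exceeding
  its own median score. Each level discards the lower half, replaces every
  discarded particle with a copy of a distinct survivor, and refreshes the
  whole population by single-gene swap moves (a random member swapped for a
  random non-member, accepted iff the score stays at or above the level
  threshold; the projection sum is updated incrementally from the two
  changed rows, O(r) per move). After L levels the estimate is
  2⁻ᴸ·(1+r)/(N+1), reported as log₁₀ p, with a level cap of 40 (p floor
  ≈ 10⁻¹²) flagged as truncation.

  The refresh budget is 6k proposals per particle per level. A lighter
  budget (k proposals applied only to duplicates) leaves particles
  correlated across levels and produces a measurable downward bias
  (~0.3 log₁₀ units by p ≈ 10⁻⁴); with the full refresh the estimator is
  unbiased within sampling error across p ∈ [10⁻⁴, 10⁻²] against
  enumeration, at ~0.15 log₁₀ units standard deviation for the default
  population size.

Across datasets, P-values are Benjamini–Hochberg adjusted; with
significance on, ranking switches from score-descending to P-ascending with
score as tiebreaker (ties broken by dataset id for determinism).

## Metadata mining

Sample metadata is tokenized to lowercase alphanumeric tokens, dropping
tokens under 3 characters and a fixed ~120-word English stopword list
shipped with the package (reproducibility over coverage). Word correlation
uses Pearson correlation between the query profile and the binary presence
vector — the point-biserial correlation, the standard statistic for a
continuous/binary pair; words must appear in at least 2 and at most m−2
samples to be informative. A constant profile yields empty lists with a
flag.

Ranking-level terms are unigrams plus adjacent bigrams from each dataset's
description; bigrams never cross punctuation, and a dropped token breaks
adjacency (so "expression of lung" yields no bigram). This deliberately
replaces model-based term markup with a transparent scheme; the term map
passed to `term_enrichment` is pluggable, so curated terms can be
substituted. Enrichment tests each term appearing in ≥ 5 datasets (Fisher on
singletons is uninformative and inflates the testing burden) with a
one-sided Fisher exact test on top-300-versus-rest membership, BH-adjusted.

## Synthetic data

The generators emulate log-scale microarray-like data: iid Gaussian noise
(sd 1) around a baseline of 10, which keeps intensities non-negative and
below the log-detection threshold so the preprocessing stays linear and the
fixtures analytically tractable. A planted dataset adds a·z to each of the
first `module_size` genes, with z a standard-normal latent factor per
sample; samples with z > 0 optionally carry a marker word, and planted
descriptions share a fixed term. Defaults (500 genes, 20 samples, 30-gene
module, effect a = 2, noise sd 1) put the planted score around 10–20% of
variance against a null level of 100/n = 0.2%, a separation comparable to a
clear real signature hit. Null datasets can share the module gene *names*
(without signal) so they are scored rather than excluded under a module
query.

What the fixtures do not emulate: RNA-seq count noise (negative binomial),
batch structure, correlated background genes, heavy-tailed intensities, and
realistic metadata vocabulary. Passing tests therefore demonstrate the
correctness and calibration of the machinery, not retrieval performance on
real repositories.

For an iid null dataset the expected score of a random size-k query is
100/n: in expectation each of the n gene-space directions carries an equal
share of the total sum of squares, independent of k and m. The simulations
confirm this scale.

## Numerical choices

* Score ties in P-value estimation count as successes, with an absolute
  tolerance of 10⁻⁹ on the percent scale.
* Quantile-normalization ties receive the mean of their reference
  positions; gene-filter ties keep the earlier row (stable sort).
* Rank in the SVD truncation is detected at s₁·max(n,m)·ε.
* Degenerate datasets (all-zero after centering, e.g. m = 1) score 0 and
  short-circuit to p = 1.
* All generators and estimators are pure functions of their integer seeds;
  per-dataset seeds in ranking are derived from the master seed and the
  dataset id (CRC32), so results are independent of iteration order and
  thread count.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
desk scale: oracle checks on 50×8 and 120×(30–100) matrices, enumeration
oracles at C(12,3) = 220 and C(30,5) = 142 506 subsets, calibration over 200
null datasets, and recovery rates over 50 simulated compendia of 21 datasets
(500 genes, 12–20 samples) — sizes chosen so every check reruns in about a
minute while leaving the estimators' regimes (p down to 10⁻⁴ against
enumeration) genuinely exercised.

## Known limitations

* Gene identifiers are opaque case-sensitive strings; no cross-platform or
  cross-species identifier mapping is performed (a mapping hook can wrap
  `read_gmt`).
* For datasets of rank > 20 the reduced score is an approximation whose
  error lives in the discarded spectral tail; no bound is reported per
  dataset.
* The multilevel estimator's accuracy contract is validated to p ≈ 10⁻⁴
  (enumeration limit); below that only the scheme's internal consistency is
  checked.
* Quantile normalization assumes columns are comparable after the log step;
  no outlier-sample detection or batch correction is attempted.
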