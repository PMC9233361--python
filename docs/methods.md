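# Methods

## Model

`specrqe` scores per-feature habitat specificity.  The data are a
samples-by-features weight matrix (weights may be relative abundances or
any nonnegative importance score) and, per variable, a sample-by-sample
dissimilarity matrix *D*.  For one feature's weight vector *p*,

RQE = Σ over ordered pairs i ≠ j of D_ij · p_i · p_j.

Both summation triangles are counted everywhere (empirical value,
permutation null, genetic-algorithm search); the factor of two cancels in
every ratio below, so only internal consistency matters.  RQE = 0 exactly
when all positive weight sits on mutually zero-dissimilarity samples;
near-zero weights contribute near-zero terms, which is what makes the
metric robust to spurious low-weight detections (e.g. index-hopping reads).

Standardization uses the permutation null RQE_sim: RQE recomputed under
uniform-random permutations of *p* (default 500 permutations; the count
trades p-value resolution against runtime and is overridable).  With *c*
the null's central tendency (mean by default, median available) and
RQE_max the maximum of RQE over permutations of *p*:

- Spec = (RQE_emp − c)/c when RQE_emp ≤ c (so −1 at perfect
  specificity, 0 at the null), and
- Spec = (RQE_emp − c)/(RQE_max − c) when RQE_emp > c (so +1 at maximal
  generality).

`denom_type="sim_center"` replaces the second branch's denominator with
*c*: much faster (no search), identical Spec for every feature with
Spec < 0 and identical p-values; positive values are then only ordinal and
may exceed 1.

Hypothesis testing is left-tailed: p = #(RQE_sim < RQE_emp)/n_sim, exactly
the literal proportion (an optional add-one mode, (#+1)/(n_sim+1), avoids
exact zeros).  Benjamini–Hochberg adjustment is applied across the features
of one variable, never across variables — which is also why results are
written as one TSV per variable.

### Degenerate and edge cases

- Features with fewer than two positive weights carry no pairwise signal;
  they are reported with a `low_occupancy` flag and a missing Spec rather
  than silently dropped.
- If the null center is 0 (e.g. an all-zero *D*), Spec is undefined:
  `degenerate_null` flag, missing Spec.
- A feature's Spec = −1 and Spec = 0 anchors are exact in floating point
  ((0 − c)/c = −1 and (c − c)/c = 0 hold bitwise).
- Scale invariance — Spec(c·p, D) = Spec(p, k·D) = Spec(p, D) — is exact in
  real arithmetic.  In floats the rescaled inputs are themselves rounded,
  and the numerator RQE_emp − c amplifies that rounding for features near
  the null; agreement is at the 1e-12 relative level, which is the
  tolerance the test suite asserts.

## Variable transforms

- Numeric vectors: D_ij = |x_i − x_j|.  No standardization of the variable
  is applied (Spec's ratios make it unnecessary).  Constant vectors are
  accepted with a warning: they yield an all-zero *D* and a degenerate null.
- Trees: cophenetic (tip-to-tip path) distances; samples mapped to the same
  tip are at distance 0, the host-phylogeny convention for replicate
  samples of one host species.
- Ontologies: an ordered coarse→fine table of categorical levels becomes a
  rooted cladogram (root → level-1 → … → finest tips) with every branch
  length 1; samples map to their finest category.  Singleton internal
  nodes are kept, so tip depth always equals the number of levels; this
  choice only scales the cophenetic distances, which standardization
  cancels.
- Co-occurring tables: Bray–Curtis (compositional) or Euclidean
  (concentration-style) pairwise dissimilarity via `scipy.spatial.distance`.
- All builders funnel through one validator: square, labels unique,
  nonnegative, zero diagonal, symmetric within relative tolerance 1e-8
  (symmetrized by averaging when inside the tolerance), reordered to the
  abundance table's sample order.  A sample without metadata for one
  variable is dropped for that variable only, with a logged count.

## RQE_max search (genetic algorithm)

The generality denominator needs the permutation maximum of RQE, found by
an elitist GA over index permutations of *p* (index, not value,
permutations — ties among weights stay unambiguous, and the PMX operator is
well defined).  Defaults: initial population = 150 random permutations +
150 random-swap variants + *p* itself (301); each generation keeps the 5
highest-RQE vectors (ties broken by first occurrence) and refills with
swap-mutated copies of the elites allocated round-robin, each mutant
receiving a swap count drawn from {1, 1, 2, 3}; a swap exchanges two
distinct uniformly chosen positions.  Termination: 400 generations, or 10
consecutive generations without strict improvement of the best-ever score.
Partially-mapped crossover (PMX) is implemented and off by default —
in practice it does not improve search efficiency for this problem; when
enabled, children of randomly paired elites replace a configurable fraction
(default 25%) of the mutants.

Properties guaranteed by construction and asserted by tests: the
per-generation best never decreases (elitism); the result is ≥ RQE_emp
(*p* is in the initial population) and in practice ≥ the null mean (150
random permutations are in the initial population), which keeps the upper
Spec branch well defined.  At enumerable sizes (n ≤ 7) the default
configuration recovers the exhaustive maximum essentially always; the test
suite requires ≥ 95% of 50 random instances with mean relative shortfall
below 1%.

Search is invoked only for features with RQE_emp > c, which is typically a
small minority; `sim_center` mode avoids it entirely.

## Simulation machinery

Synthetic species respond to a 1-D environmental gradient (uniform sample
locations on [lo, hi], defaults [0, 1000]) as a Gaussian curve: weight at a
sample ∝ (1 − uniform_mix)·φ(env; optimum, sd) + uniform_mix/(hi − lo),
summed over modes for multimodal species, normalized to sum 1.  The
response curve is deterministic given the gradient — "drawing" weights from
the niche distribution is represented by its density rather than by
stochastic counts, which makes every validation run exactly reproducible; a
Poisson wrapper (`add_poisson_noise`) resamples weights as counts at a
chosen sequencing depth when count noise matters (it is also what puts
weakly specific species on the generality side of the null, exercising the
GA branch).

Occupancy is manipulated by zeroing uniformly chosen positive weights down
to an exact target; empirical weight multisets are re-ordered into maximal
specificity by rank-matching descending weights onto ascending distance
from a chosen optimum; and specificity decay is traced by recursively
applying 2 random swaps per generation for 1000 generations, scoring every
saved vector.

`make_dataset` assembles a full study over a grid of niche breadths
(default sds 10/30/100/300 on the 0–1000 gradient), uniform mixes
(0/0.25/0.5) and occupancy targets, one Gaussian responder per cell with a
random optimum on the middle 80% of the gradient.  Narrow niches can
occupy fewer samples than an occupancy target asks for; the target is then
clamped to the attainable occupancy.

### What the simulations do and do not emulate

They emulate: graded niche breadth, background (indifferent) occurrence,
multimodal niches, occupancy variation, count noise at a fixed depth.
They do not emulate: compositional coupling between species, sequencing
error/chimeras, spatial autocorrelation of the gradient, or overdispersed
(non-Poisson) count noise.  Passing tests therefore demonstrate the
statistic's behaviour under controlled niche structure, not performance on
any particular real survey.

Two behavioural boundaries worth knowing:

- Multimodality is detected as specificity only while the inter-mode
  spread stays below the null-average dissimilarity; a species with modes
  at opposite extremes of the gradient genuinely spans maximal
  environmental breadth and scores at or above the null.  This is a
  property of Rao's metric, not an artifact.
- A species whose mass is effectively confined to a single sample carries
  no pairwise signal at all — RQE needs co-located *pairs*.  This is the
  statistical reason for the minimum-occupancy preprocessing filter
  (`filter_occupancy`), and why validation species are parameterized to
  occupy ≳10 samples.

## Determinism and parallelism

Every stochastic step derives its generator from
`SeedSequence(entropy=(master_seed, variable_index, feature_index))`, so
serial and parallel runs agree bit-for-bit and any single feature can be
replayed in isolation (the CLI run log records the derivation).  Features
are parallelized with joblib; the GA consumes the same per-feature stream
after the null draw, keeping `ga` and `sim_center` runs identical wherever
the GA is not invoked.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes at which the asserted properties are statistically stable:
40–80 samples per study, a 504-feature suite for the range check, 1000
replicate features at 500 permutations for p-value calibration (nominal
rate 0.05 within three binomial standard errors), 150 features over a
five-level occupancy sweep (|Spearman ρ| < 0.25 ≈ 3/√150), and the full
1001-vector swap-decay series at 300 permutations.

## Known limitations

- The GA provides no optimality certificate at large n; RQE_max may be
  slightly underestimated, which can only shrink positive Spec values
  toward 0 (never past +1 thanks to the RQE_emp ≥ lower-bound guard).
- The literal-proportion p-value can be exactly 0; use the add-one mode if
  downstream tooling requires strictly positive p-values.
- `sim_center` generality values are ordinal, not bounded by 1.
- Ontology conversion assumes a strict hierarchy (each fine label has one
  parent per coarser level); DAG-like ontologies are rejected.
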