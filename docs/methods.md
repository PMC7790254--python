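# Methods

## Model and procedure

The package treats personality prototyping as a model-selection problem
over partitions of persons in Big Five z-space. A solution is a partition
of n persons into k clusters of their 5-dimensional standardized trait
profiles; its quality is judged not by any single index but by (i)
split-half replicability under classifier-based reallocation and (ii) a
battery of internal validity indices, combined by vote counting.

**Scoring and exclusions.** Trait scores are means of three keyed Likert
items each (reverse-keyed items flipped as `levels + 1 − value` first).
A person with exactly one missing item keeps the mean of the remaining
items; a trait with all three items missing is missing. Persons are
excluded when they have more than one missing item or when their
intradimensional answer variance — the mean over traits of the population
variance (denominator = number of available items) of the items within a
trait, skipping traits with fewer than two available items — is strictly
greater than four times the sample average, computed before any exclusion
over persons with a computable variance. Reading "more than four times
higher" as strictly `> 4×` (not `> 5×`) is a deliberate choice; the rule's
source text does not define the statistic precisely, so the
operationalization above is documented here as this package's convention.

**Engines.** `ward_kmeans` builds a Ward linkage on Euclidean distances,
cuts it at k, and uses the cut's cluster means as the single
initialization of Lloyd's k-means (tolerance 1e-6 on center movement,
cap 300 iterations; empty clusters are re-seeded from the farthest
points). `lpa_fit` fits Gaussian mixtures by EM for four covariance
families — spherical-equal (one scalar variance shared across components
and traits; in-house EM with a variance floor of 1e-6 × total variance),
spherical-varying, diagonal, and full — and keeps the family with the
lowest BIC; hard labels are maximum-posterior assignments. The four
families cover the spherical↔full spectrum with testable parameter counts;
mixture software commonly explores more, but the extra families change
parameter counts, not the mechanics. `spectral_cluster` is the
Ng–Jordan–Weiss variant: RBF affinity with bandwidth = median pairwise
distance unless set explicitly, symmetric normalized Laplacian, first k
eigenvectors row-normalized, k-means with 10 restarts on the embedding.
The median-distance default is a global-scale heuristic: for manifold-like
structure (e.g. concentric rings) a locally scaled bandwidth must be
passed explicitly. All engines return 1-based labels, centers recomputed
as per-cluster means, and are deterministic under a fixed seed.

**Replication protocol.** Each of `n_resamples` (default 20) rounds
permutes the included sample (sampling fraction 1.0 by default — the
protocol's "samples" are permutations of the full sample, since no
subsample size is prescribed) and splits it 50/50 without stratification.
Every engine × k (default 3..10) is fitted on both halves; each half's
members are then reallocated by one-vs-rest soft-margin SVMs (RBF kernel,
C = 1, γ = 1/(5 · feature variance), i.e. scikit-learn's "scale" on five
features) trained on the opposite half's solution, taking the cluster with
the largest decision value. κ, Rand and adjusted Rand between a half's own
labels and its reallocation are averaged per resample (mean of the two
halves) and then across resamples. Cohen's κ between independent
clusterings is computed after optimal one-to-one label alignment
(Hungarian assignment on the contingency table, padded when cluster counts
differ); Rand and adjusted Rand need no alignment. A training cluster with
fewer than two members is handled by a nearest-centroid fallback kept
separate from the SVM argmax (margins and distances share no scale).

**Gate and vote.** κ is averaged across algorithms per k; k survives iff
the mean is ≥ 0.6 (empty survivor sets fall back to the single best k with
a warning). Retained (algorithm, k) pairs are refitted on the full sample
and scored with the internal battery; external criteria from the
replication summary join the table. Each index votes for its best
solution within each algorithm (within-algorithm votes) and across all
solutions (between-algorithm votes); missing values abstain, exact ties
share the vote. The winner maximizes between-algorithm votes, ties broken
by within-algorithm votes, then by smaller k.

**Indices.** The pair-based indices operate on all n(n−1)/2 Euclidean
pair distances split into within- and between-cluster sets. Tied
within/between comparisons count toward neither s⁺ nor s⁻ (the index
literature cites but rarely restates the formulas; the tie rule is made
explicit here). Γ = (s⁺−s⁻)/(s⁺+s⁻), G+ = 2s⁻/(n_t(n_t−1)),
C-index = (S−S_min)/(S_max−S_min) over within-pair sums, GDI31 = min
pairwise mean between-cluster distance over max intra-cluster diameter,
point-biserial = (mean_between − mean_within)·√(n_w·n_b/n_t²)/SD(all
distances) — algebraically the Pearson correlation between pair distance
and the between-pair indicator with population SDs. S_Dbw follows the
original Halkidi–Vazirgiannis formulation (average normalized cluster
scatter plus inter-cluster density at pair midpoints with the
average-stdev radius); published S_Dbw values for this design exist only
at an irreproducible scale, so only ordering properties are asserted.
AIC/BIC for LPA use the mixture log-likelihood and family parameter count;
for hard partitions a complete-data classification likelihood is used —
Gaussian components at the cluster means with one pooled spherical
variance *plus the multinomial assignment term Σ m_k ln(m_k/n)*, with
p = 5k + 1 + (k−1). Without the assignment term, BIC rewards splitting
true components indefinitely; with it, BIC bottoms out at the planted k.

**Labeling, similarity, prediction.** Cluster centers are named by
Euclidean distance to a reference prototype table (nearest-name by
default; optimal one-to-one assignment on request, with shared-nearest and
exact-tie conflicts reported and ties resolved lexicographically). Profile
similarity D is the Euclidean distance between 5-vector z-profiles;
"inverse distance" is −D by default (sign change preserves all
correlation structure) with 1/(1+D) selectable. Predictive validity tables
are pairwise-complete Pearson correlations of criteria with prototype
similarities and with raw traits, flagged at two-sided p ≤ 0.001 (the
conventional large-panel reporting threshold); zero-variance criteria are
reported missing.

## The synthetic generator

The generator emulates a large household-panel Big Five assessment with
planted prototype structure:

* **Mixture.** Persons are drawn from five components in trait z-space
  with default mixing proportions (0.144, 0.173, 0.246, 0.225, 0.212) —
  the reported prevalence of the resilient, overcontroller,
  undercontroller, reserved and vulnerable-resilient types — and
  within-component SD 0.5 per trait (0.4 in the tighter recovery
  benchmarks).
* **Profiles.** Default component means are sign patterns at ±0.9 z
  (resilient = (−,+,+,+,+), overcontroller = (+,−,−,0,0),
  undercontroller = (0,0,−,−,−), reserved = (−,−,−,+,+),
  vulnerable-resilient = (+,+,+,+,+)). The source literature reports only
  directions, so the magnitude is a modelling constant: 0.9 makes the
  observed traits approximately unit-variance under the default weights
  and noise (between-component variance ≈ 0.67, within 0.25, measurement
  ≈ 0.11), i.e. planted profiles are expressed in observed z units. Note
  the sign patterns are *not* mean-centered under the mixing weights, so
  z-standardization shifts each planted profile by the trait grand mean;
  ground-truth recovery is therefore judged against the components'
  observed mean profiles (`true_prototype_profiles`), not the raw config
  vectors.
* **Items.** A trait value z maps to each of its three items as
  `midpoint + slope·z + noise`, midpoint = (1+levels)/2, slope =
  (levels−1)/6 (±3 z spans the scale), additive Gaussian item noise
  (SD 0.5 default), reverse-keyed flip, round and clip to 1..levels. The
  real inventory's key map is not public; the default (second item of each
  trait reversed) is arbitrary but fixed and configurable.
* **Pathologies.** Careless responders replace all 15 answers with
  uniform draws — the mechanism that maximally inflates intradimensional
  variance, matching the exclusion rule's intent; MCAR missingness applies
  cellwise to the remaining persons.
* **Criteria.** For a target correlation vector ρ, the criterion is
  y = Z·w + σe with w solved from R·w = ρ (R the empirical trait
  correlation matrix) and σ² = 1 − ρᵀR⁻¹ρ; infeasible targets (implied
  R² > 1) are rejected.

What the generator does **not** emulate: longitudinal trait drift (a
"fresh wave" is an independent draw from the same population), non-MCAR
missingness, item response theory measurement, and — importantly — the
coarse-partition ambiguity of real panel data. The planted five types have
a hierarchical geometry (resilient/vulnerable-resilient differ mainly on
neuroticism; over/undercontroller are also mutually close), so merged 3-
and 4-cluster solutions are themselves highly split-half-stable on
synthetic data. Real-data findings that coarse solutions replicate *worse*
than the five-cluster solution reflect structure a clean mixture does not
have; passing tests here demonstrate mechanism correctness and recovery
under planted truth, not that five clusters would win on any given real
sample.

## Numerical choices and problem sizes

* Distances are Euclidean on the five trait z-scores everywhere.
* k-means: tolerance 1e-6, 300 iterations; spectral k-means 10 restarts;
  EM: 200 iterations, tolerance 1e-5·n on the log-likelihood, variance
  floor 1e-6 × total variance, collapsed components re-seeded at random
  points.
* Degenerate definitions (all logged): κ with a single shared category is
  1 iff the partitions are identical, else 0; adjusted Rand with a
  degenerate expectation likewise; C-index is 0 when all distances are
  equal; Γ is missing when all comparisons tie; GDI31 is missing when all
  clusters are singletons; point-biserial and S_Dbw are missing at zero
  variance/scatter.
* The test suite and the acceptance script size their simulations to run
  on one CPU in minutes: oracle equivalence on 200 random instances with
  n ≤ 30; the replication benchmark at n = 4000 with 20 resamples; the
  multi-seed winner-rate check at n = 2000 with 2 resamples per seed; the
  stability and labeling checks at n = 3000; the criterion calibration at
  n = 14 048. Larger sizes change runtimes, not mechanisms.

## Known limitations

* The split-half κ of a clean planted mixture is high at *every* k ≤ the
  true k (coarse merges are deterministic), so the κ curve does not peak
  at the planted k the way it can on real data; see the generator notes
  above.
* Post-alignment κ is mildly inflated for large k (the optimal assignment
  is itself selected on the data); on structureless noise this offsets the
  classical small-k bias of external criteria.
* Vote counting mixes AIC/BIC computed under different likelihood families
  (mixture vs classification); the votes are comparable only as "best
  within its column", which is how they are used.
* The one-item-per-criterion design of several published validity measures
  means the generator's Gaussian criteria are an idealization; correlation
  recovery there is a calibration check, not a psychometric claim.
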