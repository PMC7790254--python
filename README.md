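# prototyper

Person-centered personality prototyping on Big Five trait profiles:
multi-algorithm clustering, split-half SVM-reclassification reliability, a
twelve-index cluster-validity battery with vote-count model selection,
literature-anchored prototype labeling, and profile-similarity-based
stability and predictive validity.

## The problem

Variable-centered personality research describes people by five trait
scores (neuroticism, extraversion, openness, agreeableness,
conscientiousness). Person-centered research instead asks whether trait
*profiles* recur — prototypes such as **resilient** (low N, high
everything else), **overcontroller** (high N, low E/O),
**undercontroller** (low O/A/C), **reserved** (low N/E/O, high A/C) and
**vulnerable-resilient / confident** (above average on all five,
including N) — and how many of them a population supports. Deciding the
number of types from data is notoriously fragile: single clustering
algorithms impose their own geometry, and single validity indices have
known biases.

`prototyper` implements a replication-first selection pipeline:

1. **Cluster** standardized trait profiles z ∈ ℝ⁵ with three algorithms of
   different families — Ward's hierarchical agglomeration refined by
   k-means, Gaussian-mixture latent profile analysis (best of four
   covariance families by BIC), and Ng–Jordan–Weiss spectral clustering —
   for every k in 3..10.
2. **Replicate**: draw resamples, split each 50/50, cluster both halves,
   and reclassify each half's members with one-vs-rest RBF support-vector
   machines trained on the opposite half's solution. Agreement between a
   half's own partition and its SVM reallocation is scored by Cohen's κ,
   the Rand index and the Hubert–Arabie adjusted Rand index (after optimal
   label alignment). SVMs rather than nearest-centroid reallocation keep
   non-convex (spectral/LPA) solutions from being penalized.
3. **Gate**: average κ per k across algorithms; keep only k with mean
   κ ≥ 0.6.
4. **Vote**: score every retained solution with the internal battery —
   C-index, Baker–Hubert Γ, G+, generalized Dunn index GDI31,
   point-biserial, silhouette, S_Dbw, AIC, BIC — plus the three external
   criteria; each index votes for its best solution, and the solution with
   the most votes wins.
5. **Label** the winner's centers by Euclidean distance to reference
   prototype profiles, and compute each person's profile similarity
   D(p, c) = ‖z_p − z_c‖ (Cronbach–Gleser) to every prototype; −D (or
   1/(1+D)) serves as a continuous type-membership measure for stability
   checks and criterion-validity correlations.

Because the original panel data (SOEP) is restricted-access, the package
ships a first-class synthetic generator: a five-component mixture over
trait z-space with configurable prototype profiles and mixing proportions,
Likert discretization into 15 items (3 per trait, reverse-keyed items
supported), careless responders, MCAR missingness, and criterion variables
with exact target correlations to the traits. Every stage of the pipeline
is tested against this planted ground truth.

## Worked example

```python
import prototyper as pt
from prototyper.prototypes import true_prototype_profiles

config = pt.GeneratorConfig(n_persons=4000, seed=7)
items, truth = pt.generate_population(config)
z, _ = pt.zstandardize(pt.score_traits(items))

solution = pt.ward_kmeans(z, 5, seed=0)
profiles = true_prototype_profiles(z, truth)   # planted observed profiles
labeling = pt.label_prototypes(solution.centers, reference=profiles,
                               one_to_one=True)
print(pt.cluster_profiles(z, solution.labels, labeling).round(2))
for c in sorted(labeling.names):
    print(f"cluster {c}: {labeling.names[c]:<22s} D = {labeling.distances[c]:.3f}")
```

```
                      neuroticism  extraversion  openness  agreeableness  conscientiousness   size  proportion
prototype
resilient                   -1.06          0.96      1.07           0.70               0.63  541.0        0.14
vulnerable-resilient         0.90          0.96      1.13           0.58               0.64  883.0        0.22
reserved                    -0.99         -0.88     -0.61           0.63               0.63  853.0        0.21
undercontroller             -0.03          0.08     -0.61          -1.31              -1.29  929.0        0.23
overcontroller               0.82         -0.86     -0.62          -0.27              -0.30  794.0        0.20

cluster 1: resilient              D = 0.124
cluster 2: vulnerable-resilient   D = 0.029
cluster 3: reserved               D = 0.047
cluster 4: undercontroller        D = 0.095
cluster 5: overcontroller         D = 0.051
```

The rows are the recovered cluster centers in observed z units with their
membership shares (compare the planted mixing proportions 0.144, 0.173,
0.246, 0.225, 0.212); `D` is the Euclidean distance between each recovered
center and the matching planted profile — all well under the 0.3 band used
by the recovery checks.

The full protocol (replication, gate, votes) runs through
`pt.select_model(z, pt.ProtocolConfig(...))`, or from the shell:

```sh
prototyper generate --n-persons 4000 --seed 7 --out items.csv
prototyper replicate --input items.csv --out results/
```

which writes the averaged external criteria (κ/Rand/ARI per algorithm × k),
the validity-index table, the vote table, the labeled centers, and a JSON
summary with the winning solution.

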