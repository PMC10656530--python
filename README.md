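# connica

Functional-connectome fingerprinting and independent FC-trait extraction
for resting-state fMRI, with group statistics over the extracted traits.

Resting-state functional connectivity (FC) matrices — pairwise Pearson
correlations between parcellated regional time series — act like
fingerprints: a subject's test and retest connectomes resemble each other
more than they resemble anyone else's. This package implements the
two-step *connICA* analysis built on that observation:

1. **Differential identifiability.** Stack the vectorized upper triangles
   of all M connectomes into a group matrix (M × E edges). For each number
   of principal components K, reconstruct the matrix from its top-K
   components and measure

   *I*<sub>diff</sub> = (mean within-subject test–retest similarity −
   mean between-subject similarity) × 100,

   where similarity is the Pearson correlation between edge vectors. The
   K maximizing *I*<sub>diff</sub> gives a denoised, subject-optimal
   reconstruction.

2. **FC-traits.** Decompose the reconstruction by robust multi-run ICA as
   X ≈ A·S: rows of S are statistically independent edge patterns
   (*FC-traits*), columns of A weight each trait's expression in every
   connectome. Components recurring across ICA restarts (matched by
   absolute pattern correlation) are kept as run centroids; weights are
   re-estimated by least squares.

Trait weights are then screened for group differences with a
repeated-measures ANOVA (group between subjects, acquisition sequence
within subjects, covariate-adjusted) under Benjamini–Hochberg FDR, with
covariate-adjusted pairwise post-hoc F tests and nested-model partial F
tests against cognitive and clinical variables. Significant traits are
characterized by their top-1% strongest edges, per-region nodal strength
and per-network contribution labels (−/+/++).

Because patient connectomes of this kind are not publicly deposited, the
package ships a seeded synthetic-cohort generator (`connica.simulate`)
that plants known FC-traits, a group effect on one trait's weights, and
weight-linked cognitive scores, so every stage can be validated against
ground truth. It also covers the upstream deterministic rules of such a
study: motion-based frame censoring (ENORM > 0.4 mm or despiked-voxel
fraction > 10%), subject exclusion (> 20% censored frames in either
session), cognitive z-scoring against a control sample, and Level-II
mild-cognitive-impairment classification (> 1.5 SD below control values
on ≥ 2 tests).

## Worked example

```python
from connica import CohortConfig, ConnICA, IdentifiabilityReconstruction, generate_cohort

cohort = generate_cohort(CohortConfig(seed=11))     # 63 subjects x 2 sessions, R=100
group = cohort.group_matrix()                       # 126 x 4950 edge matrix

sweep = IdentifiabilityReconstruction().fit(group)
print(f"I_diff {sweep.idiff_original_:.2f} -> {sweep.idiff_optimal_:.2f} at K={sweep.optimal_k_}")
# I_diff 39.81 -> 85.51 at K=5

ica = ConnICA(n_components=sweep.optimal_k_, n_runs=10, random_state=11)
ica.fit(sweep.transform(group))
print(ica.patterns_.shape, ica.robustness_)
# (5, 4950) [1. 1. 1. 1. 1.]
```

The sweep reports that reconstructing the 126 connectomes from 5
principal components more than doubles differential identifiability
(39.81 → 85.51 on the percent-like scale), and the ICA stage recovers 5
traits, each reappearing in every restart (robustness 1.0). Screening the
trait weights against the cohort's group labels flags exactly the planted
effect trait.

The same analysis is available from a shell:

```sh
connica simulate --seed 11 -o cohort/
connica run --config pipeline.yaml --seed 11 -o results/
```

where `pipeline.yaml` points at the cohort's `fc/` (or `timeseries/`)
directory, parcellation and covariate tables. The run writes every
intermediate artifact (group matrix, I_diff curve, trait patterns,
weights, test tables, characterizations) plus a `report.json` manifest.

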