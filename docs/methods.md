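# Methods

This note documents the models, parameter choices and numerical
conventions behind `connica`, and what the synthetic validation does and
does not demonstrate about real data.

## Connectome construction

Per subject and acquisition session (monoband, multiband), the input is a
T × R table of parcellated ROI time series. The default parcellation
layout follows a Schaefer-style lookup table: cortical parcels split
between hemispheres and assigned in contiguous runs to the seven canonical
resting-state networks (VN, SMN, DAN, VAN, LN, FPN, DMN), plus 8 bilateral
subcortical structures. The full-scale table has 408 ROIs (400 cortical +
16 subcortical labels); desk-scale analyses default to R = 100.

Frame censoring uses two per-frame criteria: the Euclidean norm of the
frame-to-frame derivative of the six realignment parameters (ENORM, first
frame 0 by convention) and the fraction of voxels adjusted during
despiking (an input column — voxel-level preprocessing is upstream and out
of scope). A frame is dropped when ENORM exceeds 0.4 mm or the despike
fraction exceeds 10%; both rules are strict inequalities, so boundary
frames are kept. Subjects losing more than 20% of frames in *either*
session are excluded. Rotation parameters are consumed as provided and
must already be commensurate with the translations (the usual
degrees-as-mm convention is applied upstream).

FC is the Pearson correlation over retained frames only (censoring by
deletion, not interpolation); a constant ROI raises an error naming the
ROI. Matrices are vectorized in a single fixed convention — row-major
upper triangle excluding the diagonal, (1,2), (1,3), …, (2,3), … — and
stacked subject-major, monoband before multiband, into the M × E group
matrix. Fisher z-transformation of edges before PCA/ICA is available as a
config flag but off by default, matching the plain-r formulation of the
procedure.

## Differential identifiability

The identifiability matrix correlates each subject's monoband edge vector
with every subject's multiband edge vector (the test/retest convention;
all-pairs variants are out of scope). I_diff = (diagonal mean −
off-diagonal mean) × 100; the ×100 scale matches how such values are
conventionally printed (e.g. gains from the mid-20s to the low 40s on real
cohorts). PCA uses per-edge mean centering over the M rows with no
variance scaling (all edges share the r scale); reconstruction at K is the
truncated SVD plus the means. The sweep visits every integer K in
[2, min(M, E)] by default (a stride option trades optimality of the grid
for speed), computes I_diff of each reconstruction incrementally (one
rank-1 update per step), and picks the maximizing K with ties broken to
the smallest K for parsimony. At full rank the reconstruction reproduces
the input to numerical tolerance, so the original I_diff is always on the
curve.

`IdentifiabilityReconstruction` is a scikit-learn transformer: `fit`
performs the sweep, `transform` projects any matrix onto the retained
principal basis. The estimator requires the `GroupFCMatrix` container for
fitting because the subject/session block structure lives in the row
index.

## Robust ICA trait extraction

The group matrix (or its reconstruction) is modelled as X ≈ A·S. Each run
applies whitened fixed-point ICA with the logcosh contrast (sklearn
`FastICA`) to X^T, treating edges as samples, yielding candidate patterns.
Defaults: 100 runs, convergence tolerance 1e-6, 1000 iterations; runs that
fail to converge are dropped but still count in the robustness
denominator. Components are matched to the first converged run greedily by
absolute pattern correlation with threshold 0.75; components recurring in
at least 75% of runs are retained as their sign-aligned run centroid,
unit-normalized. Weights are re-estimated by least squares on the retained
patterns, so the reported decomposition minimizes Frobenius reconstruction
error given the patterns, and all scale lives in the weights. Sign
indeterminacy is resolved by flipping each trait so its pattern skewness
is positive (tie: largest-|loading| edge positive), flipping weights
jointly. The number of components defaults to the sweep's optimal K.

## Statistics

*Repeated-measures group test.* The design has one between-subjects
factor (HC, PD-CN, PD-MCI), one within-subject factor (sequence) and
subject-level covariates (age, gender, total grey matter by default).
The group effect is computed in the between-subjects stratum by the
classical two-stage route: average each subject's two session weights,
then form the covariate-adjusted extra-sum-of-squares F of group
membership on those means. With two groups and no covariates this reduces
exactly to the one-way ANOVA F (and to the squared pooled t). Post-hoc
pairwise tests apply the same model restricted to each group pair, read at
p < 0.01. Screening across traits controls FDR by Benjamini–Hochberg at
q < 0.05 (via statsmodels; the test suite checks it against a hand-coded
step-up oracle).

*Associations.* Nested one-way model comparisons on the pooled M rows
(both sessions; the sequence indicator is a baseline variable): baseline =
intercept + age + sequence + average ENORM + TGM + eTIV, augmented adds
one cognitive/clinical variable. The partial F has (1, M − 7) df; the
augmented model's overall F with (6, M − 7) df — F(6, 119) at M = 126 —
is reported alongside. The pooled design mirrors the reporting convention
of such analyses; it treats a subject's two rows as exchangeable
observations, a repeated-measures caveat documented rather than modelled.
A condition-number guard (1e10) rejects explanatory variables collinear
with the baseline. Healthy controls carry MDS-UPDRS-III = 0 by coding
convention; a config switch can exclude them from clinical regressions
instead.

*Cognition.* z = (raw − control mean)/control SD per test; five domain
composites are unweighted means of each domain's two tests (attention:
inverse span + digit-symbol; executive: trail making + phonemic fluency;
memory: RAVLT + ROCF; language: semantic fluency + Boston naming;
visuospatial: VOSP objects + VOSP numbers). Level-II MCI requires z
strictly below −1.5 on at least two tests, within or across domains;
missing scores raise an error rather than being imputed.

## Trait characterization

Top edges: the ⌈pct/100 × E⌉ largest |loadings| (default 1%, minimum 1
edge, ties broken by edge index for determinism; at E = 83,028 the 1%
selection is 831 edges). Nodal strength: loadings normalized over the
whole pattern (default z-score; max-abs and none available), each selected
edge contributing its absolute normalized loading to both endpoints.
Network contribution: mean |loading| over edges touching the network,
relative to the pattern-wide mean; labels "−" below 1.0, "+" in
[1.0, 1.5), "++" at or above 1.5, chosen so a perfectly uniform pattern
sits at "+" everywhere. The −/+/++ rule is an explicit quantitative
surrogate for what is often an expert judgment; thresholds are config and
the rule is echoed in the run report. All steps use absolute loadings, so
characterization is invariant to the trait's global sign.

## Synthetic cohorts

The generator emulates the study conditions end to end with known ground
truth:

- **Patterns**: n_traits (default 5) unit-norm edge patterns, each
  supported on 3 random within/between-network blocks at density 0.5,
  redrawn until all pairwise |cosines| < 0.3.
- **Weights**: per-subject i.i.d. standard normal, copied to both sessions
  with N(0, 0.3²) jitter; the designated group (PD-MCI by default, sizes
  23/19/21) is shifted by 1.5 on one trait — a standardized mean
  difference of 1.5, the default planted effect.
- **Edges**: weights·patterns + N(0, σ²) per edge, squashed through tanh
  into (−1, 1) (monotone, so rank order and ICA recovery stay well-posed)
  and devectorized to symmetric unit-diagonal matrices. σ defaults to the
  RMS of the composite signal, i.e. the planted signal explains ≈ half the
  pre-squash edge variance.
- **Time series** (optional): zero-mean multivariate normal draws whose
  correlation equals the nearest-PD repair of the target FC (eigenvalue
  floor 1e-6, diagonal renormalized; the largest entry change is
  reported). Frames per session default to 198 (TR 2 s) and 600
  (TR 0.8 s), mirroring the two acquisition types.
- **Covariates/cognition**: group-wise age, gender, education, average
  ENORM and MDS-UPDRS-III distributions follow the published cohort
  tables; TGM/eTIV use realistic volumetric ranges. Selected variables are
  linear in the subject's mean effect-trait weight plus noise; domain raw
  scores are back-computed from z through control-sample stats; HC rows
  carry MDS-UPDRS-III = 0.

What the generator does *not* emulate: voxel-level artifacts, realistic
head-motion spectra, scanner physics of the two sequences (session
differences are only weight jitter), spatial autocorrelation of edges
beyond the block structure, and the heavy-tailed, globally-positive mean
structure of real FC. Passing tests therefore demonstrate correctness of
the pipeline's algebra and its statistical calibration under the planted
model — not that real cohorts of this size would yield the same power.

## Problem sizes and determinism

Desk-scale validation uses R = 100 (E = 4950) cohorts of 63 subjects for
recovery and identifiability checks, R = 50 for the 200-simulation
screening-calibration study, and 10 ICA restarts per extraction; these
sizes make the full validation run in minutes while leaving the measured
properties (recovery correlations ≥ 0.9, null family error ≈ 5%,
identifiability gains) far from their thresholds. Every stochastic step
takes an explicit seed, sub-seeds are derived through a single
`numpy` Generator, and rerunning any stage with the same config and seed
reproduces outputs byte for byte.

## Known limitations

- The mixed-design ANOVA is the two-stage subject-means formulation, not a
  likelihood-based mixed model; with missing sessions it refuses rather
  than estimates.
- The post-hoc df convention follows the two-stage model; published
  analyses of this kind sometimes report other df layouts for their
  post-hoc F values.
- ICA run-matching is greedy against a reference run (first converged),
  not full ICASSO-style clustering; with well-separated components the two
  agree.
- The identifiability similarity is strictly monoband-vs-multiband; no
  site or demographic deconfounding of the identifiability matrix.
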