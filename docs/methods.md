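# Methods

This note documents the models, the synthetic-data process, the
numerical choices and the known limitations of `msnbiotype`, in the
order of the analysis chain.

## Morphometric similarity networks

A subject's MSN edge between regions *i* and *j* is
`exp(-[KL(p_i||p_j) + KL(p_j||p_i)])`, computed on discretized
densities. Densities are histograms on a shared per-subject grid
(default 128 bins spanning the subject's pooled value range) with a
probability floor ε = 1e-10 added to every bin before renormalization,
which keeps both directed KL terms finite; Gaussian KDE is available as
a config alternative. The symmetrized divergence is the *sum* of the two
directed KLs inside the exponent, so the similarity is symmetric, equals
1 iff the two distributions coincide, and decreases monotonically as
distributional overlap shrinks. The grid is per subject (not per
cohort): each network is built from that individual's own value range,
matching individualized network construction. With a small pseudo-count
floor, empty-vs-occupied bin pairs dominate the divergence when sample
counts are low; this inflates all divergences roughly uniformly and is
rank-preserving, but absolute edge values should not be compared across
density settings.

## Hub topology

Networks are proportionally thresholded: the strongest
`sparsity · R(R−1)/2` undirected edges are kept (default sparsity 0.3,
fixed across subjects; ties at the cutoff break toward lexicographically
smaller index pairs). Three metrics per node:

* **Degree centrality** — weighted node strength.
* **Nodal efficiency** — mean inverse shortest-path length with edge
  lengths 1/weight; unreachable pairs contribute zero, so disconnected
  thresholded graphs are handled without special-casing.
* **Participation coefficient** — Guimerà–Amaral form against one fixed
  community partition estimated from the mean training-control network
  by seeded Louvain consensus (20 restarts, co-assignment threshold 0.5,
  iterated to unanimity). Using one partition for all subjects makes PC
  comparable across subjects, which the normative models require.
  Isolated nodes get PC = 0 by convention.

Thresholding scheme, resolution γ and sparsity are exposed as config
knobs because reasonable alternatives exist for all three.

## Normative models

Each node × metric phenotype is fitted on training controls only:

* standardize y; warp `t = sinh(δ·asinh(y_std) − ε)` (sinh-arcsinh; ε
  skew, δ > 0 tail weight; identity warp is ε = 0, δ = 1);
* Bayesian linear regression of t on [1, B-spline(age), sex] with
  isotropic Gaussian prior; (α, β) by closed-form evidence iteration;
* (ε, log δ) by bounded L-BFGS-B on the negative profile marginal
  likelihood including the warp Jacobian (bounds ε ∈ [−2, 2],
  δ ∈ [0.25, 4], start at identity); non-convergence falls back to the
  identity warp with a flag.

The age basis is a cubic B-spline with 5 interior knots at training-age
quantiles — flexible enough for pediatric growth curves at n ~ a few
hundred per model without overfitting. Deviations are
`z = (t(y) − μ_pred)/sqrt(σ²_pred + σ²_noise)`; |z| ≥ 2 defines an
extreme deviation (two-sided Gaussian tail expectation 4.55%).
Predictions outside the training age range ± 0.5 y are refused.
Constant phenotypes (e.g. PC identically zero at a node) get a
degenerate pass-through model whose deviations are raw offsets.

**Site handling.** Site never enters the regression. For a new site,
`transfer_recalibrate` re-estimates an offset and scale from the
standardized residuals of ≥ 20 adaptation controls; recalibration always
restarts from the uncalibrated model, making it exactly idempotent. A
2-fold linear-SVM site-prediction check on control deviations reports
balanced accuracy vs chance as a harmonization diagnostic.

## Deviation cartography

Overlap maps are per-node fractions of a group with the extreme mask
set (positive, negative, or either; the two signed masks are mutually
exclusive so the either-direction proportion is their sum). Difference
maps are case − control in percentage points. Inference:

* **Group permutation** — labels shuffled within site by default
  (multisite design; config flag), two-sided on |difference|, add-one
  rule `p = (1 + #{|null| ≥ |obs|})/(n_perm + 1)`. The statistic is
  lattice-valued, so ties make the test conservative, never
  anti-conservative.
* **Spin test** — surrogates by uniformly random 3-D rotations of the
  node coordinates. Default reassignment is one-sided nearest neighbor
  (the surrogate reads each node's value from the node whose rotated
  coordinate lands closest; duplicates permitted). A one-to-one
  `assignment="hungarian"` variant (linear sum assignment) preserves the
  value multiset exactly, at slightly higher cost.
* **FDR** — Benjamini–Hochberg across nodes (or annotations).
* **Effect sizes** — Cohen h for proportion pairs; per-subject extreme
  counts compared by two-sample t with pooled-SD Cohen d; between-biotype
  per-node frequencies by Pearson χ² without continuity correction
  (expected counts < 5 trigger a warning and a Fisher-exact fallback for
  2×2 tables).

## Fusion (mCCA + jICA)

Multiset CCA maximizes the sum of squared pairwise correlations
(SSQCOR) of the modality variates, solved deflationarily: per component,
alternating eigen-updates of each modality's direction in its whitened
subject-space basis until the objective stalls (tol 1e-10), then
deflation of the found variate. D_k are orthonormal per modality; maps
are C_k = D_kᵀ X_k. Joint ICA runs FastICA (logcosh contrast, symmetric
decorrelation) on the node-wise concatenation of the C_k from 20 seeded
restarts, keeping the run with the highest total negentropy; each source
is sign-fixed so its largest-magnitude element is positive, and an
all-sources-near-Gaussian outcome sets a `low_nongaussianity` flag
(Gaussian sources are not identifiable). Mixing coefficients are
`A_k = D_k · pinv(W)`. Component count is the smallest m whose
reconstruction explained variance exceeds the floor (default 0.8) in
every modality, capped by rank.

## HYDRA biotypes

K linear max-margin faces (exact-QP linear SVC per face) separate all
controls (negative side) from each face's assigned cases; alternating
(i) per-face fits and (ii) reassignment of each case to its
highest-scoring face minimizes a single regularized hinge objective, so
the trajectory is non-increasing (asserted in tests). Case sample
weights are fixed at `k·n_controls/n_cases`, which balances aggregate
class weight per face *and* keeps the objective monotone (weights that
depend on current face occupancy would not). Empty faces are reseeded
with the case deepest inside the polytope.

**Initialization.** Restarts are initialized by seeded k-means on the
cases' unit displacement directions from the control centroid, not by
random balanced assignment: at practical C any case subset is linearly
separable from the controls, so a face fitted to a random subset scores
all cases almost equally and random initializations freeze into
near-arbitrary fixed points; the displacement directions, in contrast,
carry exactly the polytope geometry. Random-balanced initialization
remains available (`init="random"`). The restart ensemble is reduced by
spectral clustering of the case co-assignment matrix, followed by one
final alternating refit from the consensus labels so the returned
hyperplanes and labels are mutually consistent. C defaults to 1.

**Model selection.** For each k, the full-sample consensus model
provides reference labels; fold models (cases 10-fold, all controls in
every fold) assign their held-out cases via expression scores, and the
mean held-out ARI is tabulated with its fold-level SE. Selection uses a
one-SE plateau rule toward the largest k: when the data supports a
stable k-cluster solution, every coarser model merges the same clusters
deterministically and is spuriously just as stable, so a plain argmax
systematically under-selects; the largest k statistically
indistinguishable from the best is the informative choice. Split-half
agreement and permutation validation (case rows with features permuted,
destroying nodal structure while preserving per-row margins) provide the
reproducibility checks. Expression scores are normalized by ‖w_j‖ by
default (config: raw); argmax assignment breaks ties toward the lowest
face index.

## Decoding

The three metric-wise difference maps are fused by z-scoring each across
nodes and averaging (config: sum, max-abs); z-scoring makes the metrics
commensurate, and zero-variance maps are excluded with a warning.
Annotation correlations use Spearman by default (product-moment by
config — both are meaningful for monotone receptor-density
relationships), spin surrogates shared across the annotation set, and BH
across annotations ("spin-FDR"). PLS decoding takes the fused map as the
response and the term-map matrix as predictors, scores only the first
component, tests its explained variance by spin-rotating the fused map,
and stabilizes term weights by a node bootstrap with sign alignment
(each resample's scores correlated with the original scores); Z = weight
/ bootstrap SE. The predictor/response orientation is recorded here
because the transpose convention also appears in the literature.

## Clinical statistics

Kruskal–Wallis with tie correction; η² = (H − k + 1)/(n − k) (the
H-based formula, recorded in the output metadata). Post-hoc pairwise
two-sample t tests with pooled-SD Cohen d and Holm adjustment by default
(Bonferroni and BH by config) — Holm gives familywise control over the
three biotype pairs without Bonferroni's conservatism. Raw symptom
scales rescale to [0, 1] by (x − lo)/(hi − lo) with clipping and a
clipped-value count.

## Synthetic cohort generator

The generator defines the study conditions under which the chain is
validated. Regional values for subject s, region r are
`N(m_sr, τ²·site_scale²)` with

```
m_sr = b_module(r) + Δb_r + f_r(age_s) + c_r·sex_s + s_site(s)
       + a·F_{s,module(r)} + e_sr
```

— module base levels spaced over [4, 6] (arbitrary volume-like units),
regional offsets SD 0.08, smooth nonlinear age curves (region-specific
linear trend + Gaussian bump, amplitude ~0.15), sex effects SD 0.05,
additive site offsets SD 0.10 with per-site noise-scale multipliers in
[0.8, 1.25], shared module-level subject factors with loading a = 0.25,
idiosyncratic noise SD 0.05, and within-region sample SD τ = 0.3.
Same-module regions thus have nearly identical within-subject value
distributions (strong KLS edges) while modules separate cleanly, so the
consensus partition recovers the planted modules and the topology
metrics carry age, sex and coupling information.

**Planted biotypes.** Each biotype k owns a disjoint set of designated
hub nodes (10% of regions each). For its cases, every *sample* of those
regions receives independent zero-mean noise with SD
`effect_size · a` — i.e. the node's value distribution widens. This
decouples the node from *all* regions simultaneously (its KLS edges
collapse), which is the defining property of a network-level biotype
here: the effect lives in distributional concordance, the MSN's measured
space, and is exactly absent at effect 0. A mean-shift perturbation was
rejected during design because a shift comparable to the inter-module
spacing relocates a node into another module's operating range instead
of decoupling it, producing erratic rather than consistent topological
deviations. At the default conditions, effect size 3 yields essentially
exact biotype recovery, effect 2 strong recovery, and effect ≤ 1 is in
the weak-signal regime.

**Symptoms.** Case scores are truncated normals with biotype-graded
means (k = 3 defaults: inattention 0.77/0.71/0.75, hyperactivity
0.68/0.65/0.60 for biotypes 1/2/3 — biotype 1 most severe on both;
SDs 0.16/0.23), controls at 0.25/0.20 (SD 0.15); all scores lie in
[0, 1]. Truncation pulls high means down slightly, so small-sample
empirical orderings of close pairs are noisy by design.

**Validation cohorts.** `CohortSpec.biology_seed` separates the
population-level biology (geometry, regional parameters, planted node
sets) from the sampling seed, so an independent validation cohort draws
new subjects and new sites from the same underlying population — the
setting in which normative transfer recalibration plus expression-score
assignment is meaningful.

**What the generator does not emulate:** image-level artifacts and
preprocessing variation, non-modular long-range connectivity, agewise
sampling imbalance, comorbidity structure, missing data, and any
specific scanner's noise profile. Passing tests therefore demonstrate
the chain's statistical correctness and calibration under its stated
assumptions, not performance on real clinical MRI.

## Problem sizes and numerical choices

The test suite and acceptance script run the full chain at 300
controls / 300 cases / 60 regions / 200 samples per region for the
planted-recovery and transfer checks, 120/120/40 for null calibration,
and smaller cohorts for unit tests; permutation and spin tests use 1000
draws where the inference itself is under test and ~100–200 where only
plumbing is exercised. HYDRA permutation validation wraps full model
refits per null draw, so its inner permutation count is kept small (19)
and calibration is assessed over repeated outer runs. Key numerical
defaults: histogram floor 1e-10; warp optimization tolerance 1e-6 with
identity fallback; evidence iteration tolerance 1e-8; SSQCOR tolerance
1e-10; FastICA tolerance 1e-7 with 20 restarts; alternating HYDRA capped
at 100 iterations with a stall guard; all archives written with fixed
timestamps and sorted keys so a fixed master seed reproduces every
artifact byte for byte.

## Limitations

* KLS magnitudes depend on the density-estimation settings; only
  comparisons under a fixed configuration are meaningful.
* The participation coefficient inherits the consensus partition; a
  poorly modular cohort yields an unstable partition and noisy PC.
* Stability-based k selection cannot distinguish merges of genuinely
  well-separated clusters without the plateau rule documented above; in
  weak-signal regimes all stability criteria are low and selection is
  unreliable (as the validation utilities make visible).
* The normative predictive distribution ignores warp-parameter
  uncertainty; with small training samples the tails are slightly
  miscalibrated.
* Group permutation p-values are conservative under heavy ties (small
  groups, rare extremes).
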