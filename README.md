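# msnbiotype

Normative modeling of morphometric-similarity-network hub topology and
semi-supervised biotype discovery for multisite pediatric case-control
cohorts.

Clinical heterogeneity is the central obstacle to stratifying
neurodevelopmental disorders such as ADHD: a single diagnostic label
covers children with very different underlying network biology.
`msnbiotype` implements an analysis chain that addresses this by
quantifying, for every child, *how far each brain region's network role
deviates from normative expectations*, and then clustering cases on
those deviations rather than on symptoms:

1. **Morphometric similarity networks (MSN).** For one subject with
   regional gray-matter value samples, the edge between regions *i* and
   *j* is the Kullback-Leibler divergence similarity of their value
   distributions:
   `KLS(p, q) = exp(-[KL(p||q) + KL(q||p)])` ∈ (0, 1].
2. **Hub topology.** On the proportionally thresholded MSN, three
   node-wise hubness metrics: degree centrality (strength *k_i*), nodal
   efficiency `E(i) = (1/(R-1)) Σ_{j≠i} 1/d(i,j)` with lengths 1/w, and
   the Guimerà–Amaral participation coefficient
   `PC(i) = 1 − Σ_s (k_is/k_i)²` against a consensus control partition.
3. **Normative models.** Per node × metric, a warped Bayesian linear
   regression on a B-spline basis of age plus sex:
   `t = sinh(δ·asinh(y_std) − ε)` is Gaussian given covariates; the warp
   (ε, δ) is fitted by profile marginal likelihood. Each subject's
   deviation is the predictive z-score; |z| ≥ 2 marks an extreme
   deviation. Pretrained models transfer to new sites by re-estimating
   an offset and scale from adaptation controls.
4. **Deviation cartography.** Per-node extreme-deviation overlap maps,
   case−control difference maps, group-label permutation nulls and
   spatial-rotation ("spin") permutation nulls, BH-FDR, Cohen *h*.
5. **mCCA+jICA fusion** of the three metric-wise deviation matrices into
   joint independent components with subject-wise mixing coefficients
   `A_k = D_k · W⁺`.
6. **HYDRA biotypes.** K max-margin hyperplanes jointly separating
   controls from cases form a convex polytope; each case's face is its
   biotype. Model selection by 10-fold cross-validated stability (ARI),
   validated by split-half agreement and permutation testing; expression
   scores `E_ij = (w_j·x_i + b_j)/‖w_j‖` transfer assignments to new
   cohorts.
7. **Spatial decoding.** Fused deviation maps correlated with
   receptor-density-like annotation maps under spin nulls (spin-FDR),
   and PLS regression against cognitive-term maps with bootstrap term
   loadings.

Because the clinical imaging cohorts behind this design are not
distributable, the package ships a first-class synthetic cohort
generator (`msnbiotype.synthetic`) that reproduces the statistical
structure the chain assumes — multisite samples aged 6–18, nonlinear age
effects, site offsets, module-structured regional coupling, planted
biotypes that decouple designated hub nodes, and biotype-graded symptom
scores in [0, 1] — so every stage is testable end to end.

## Worked example

`examples/03_biotype_discovery.py` plants three biotypes (effect size 3,
150 controls / 150 cases, 40 regions), derives deviation features and
recovers them:

```
stability per k:
 k   ari  ari_se
 2 0.216   0.200
 3 1.000   0.000
 4 0.801   0.021
chosen k = 3 (planted k = 3)
ARI vs planted biotypes: 0.979  (1 = exact recovery)
inattention: H = 9.13, eta^2 = 0.048, p = 0.0104
hyperactivity: H = 1.96, eta^2 = -0.000, p = 0.374
```

The cross-validated stability peaks at the planted k; the fitted
polytope reassigns 97.9% of cases to their true biotype (ARI 0.979); and
the discovered biotypes differ in inattention severity (Kruskal–Wallis
H = 9.13, p = .01) even though clustering never saw the symptom scores.
The other examples cover MSN construction, normative calibration,
spin-test decoding, and the full file-based pipeline.

## Command line

The stage-wise pipeline is also a CLI (`simulate`, `msn`, `topology`,
`normative`, `deviations`, `fuse`, `cluster`, `decode`, `transfer`,
`report`, `run-all`):

```bash
msnbiotype run-all --seed 11 --workspace ws/
cat ws/report.md
```

Runs are deterministic per master seed, resumable (unchanged stages are
skipped by checksum), and logged in a byte-reproducible `manifest.json`.

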