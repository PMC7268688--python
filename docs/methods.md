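# Methods

This note records the models, estimator choices, defaults and numerical
conventions behind `volcov`, and what the synthetic validation does and does
not demonstrate.

## Regional volume estimation

A subject's image is assumed registered to a labelled template by a rigid
rotation, an affine transform (both supplied as 4×4 matrices mapping
individual → template) and a nonlinear warp whose Jacobian-determinant
field J_F is sampled on the template grid. The regional volume is

    V_i = (Σ_{voxels labelled i} J_F) · v / (|det R₃ₓ₃| · |det A₃ₓ₃|)

with v the template voxel volume in mm³. Conventions, each chosen where the
formula alone is ambiguous:

* **J_F covers the nonlinear component only.** An alternative reading makes
  J_F equal to the inverse linear determinant under a purely linear
  registration; combined with the explicit determinants in the denominator
  that double-counts linear scaling (a subject twice the template size would
  get 64× rather than 8× the volume correction). The canonical convention —
  J_F ≡ 1 for linear registrations, linear scale entering only through the
  denominator — satisfies the consistency requirement that an exact affine
  scaling *s* of the template yields (template volume)/s³; the literal
  reading stays available via `literal_linear_jacobian=True` for
  comparison.
* **The sum runs over template-space voxels** (the label map lives in
  template space and "the corresponding area in the template" defines V_t).
* **Exact label equality, no partial-volume weighting.** Label maps are
  integer-valued; fractional assignment is a segmentation concern upstream
  of this package.
* **Summation is compensated** (`math.fsum`), so the estimate is exactly
  independent of voxel iteration order.
* Regions absent from a label map are reported as *missing*, never as zero:
  a zero would silently corrupt every downstream covariance.

The atlas packaged with the library lists 64 gray-matter regions — 32 named
structures in each hemisphere, thalamus first, insular cortex last — with
label codes 1..64 assigned in row order. External label maps must be
remapped to this convention; printed sources of such tables give no numeric
codes. Two region names ("Cingular gyrus", "Entorhinal cortex") are
transcribed as printed without attempting to reconcile sub-parcellation
detail with any particular atlas release.

## Synthetic cohorts

The generator is the package's test bed: it produces data with exactly the
statistical structure the analysis assumes, so every downstream claim can be
checked against known ground truth.

* **Log-normal volumes.** Each subject draws a 64-vector of standard
  normals with block correlation (4 equal modules by default; within-module
  correlation 0.6, between 0.1 — enough modularity to make the resulting
  covariance network small-world, which is the regime of interest). Each
  coordinate is mapped to a log-normal with *exactly* the configured
  per-region mean and SD on the volume scale (moment-matched), which
  guarantees positivity and makes workflow biases multiplicative.
  Positive definiteness of the implied correlation is checked at config
  construction, before any sampling.
* **Defaults.** 22 subjects; per-region mean volumes are round,
  order-of-magnitude plausible constants (thalamus 4000 mm³, cerebellar
  hemisphere 12000 mm³, amygdala 700 mm³, …) with SD = 10 % of the mean.
  They make no claim of matching real neonatal volumetry; only relative
  scale matters to the pipeline.
* **Workflow biases.** The three emulated preprocessing variants share one
  latent subject draw; per-region multiplicative bias vectors are the only
  systematic difference. Defaults: the BET-like workflow is 0.95 everywhere
  (volumes mostly smaller), the iBEAT-like workflow is 1.05 on the
  skull-base-adjacent subset (cerebellar hemispheres, inferior temporal,
  fusiform, parahippocampal and entorhinal regions, both sides), the
  corrected workflow is unbiased. The magnitudes are uncalibrated
  placeholders — published comparisons report the directions graphically
  but not the sizes — and are fully configurable.
  One consequence worth knowing: a region-*uniform* multiplicative bias
  (the BET default) leaves partial correlations, and hence the network,
  exactly unchanged — correlation statistics are scale invariant. Only
  region-selective distortions (the iBEAT default) propagate into the
  graph. Network-level workflow effects in the synthetic world therefore
  come from the skull-base subset, while volume-level ANOVA effects come
  from both.
* **Repeats.** Repeated measurements share the latent volumes and add
  independent Gaussian noise (SD `repeat_sd`, volume scale), so the
  population ICC is exactly σ_b²/(σ_b² + σ_w²) per region.
* **Registration fixtures** lay regions out as disjoint voxel runs (overlap
  impossible by construction), with identity rigid, scaled-identity affine
  and either a uniform or a smoothed-noise Jacobian field.
* All sampling flows from a single cohort seed through fixed named
  sub-streams, so any stage is reproducible in isolation.

What the generator does **not** emulate: image intensities, tissue contrast,
registration error that correlates across neighbouring regions, age/sex
covariate structure, or heavy-tailed measurement error. Passing tests on
synthetic cohorts show the chain is correct and well-calibrated *under the
stated model*; they cannot certify behaviour on real neonatal data.

## Network construction

Partial correlations are computed from the precision matrix of the region
columns: p_ij = −Ω_ij/√(Ω_ii Ω_jj). With 22 subjects and 64 regions the
sample covariance is singular, and no published description of the
group-level estimator resolves how this was handled historically; this is
the largest methodological free parameter in the pipeline. The default is
**Ledoit–Wolf shrinkage** toward a scaled identity with analytically chosen
intensity; `shrinkage="none"` (fails loudly on singular input) and fixed
intensities in (0, 1] are available. Downstream metrics consume only the
binarized graph, and edge *rankings* are far more stable under shrinkage
than the weights themselves, which is why a shrinkage default is defensible
even though its intensity is data-driven.

Binarization keeps the top round(s·n(n−1)/2) undirected edges at each
sparsity s in the default grid 0.10–0.46, step 0.02 (19 levels, a common
structural-covariance convention; the grid is configurable since no
canonical range exists). The default edge rule ranks by signed weight
(`positive`: negative partial correlations are admitted last); `abs` ranks
by magnitude. Ties are broken by (lower node index, then partner index),
making the selection total — the edge count is exact, not approximate, at
every level. A hook exists to regress covariates (age, sex) out of the
volumes before correlation; it defaults off, matching the reference
analysis.

## Graph metrics and null models

On a binary graph the geometric-mean clustering form reduces exactly to
triangle counting, C(i) = 2T(i)/(k_i(k_i−1)); the implementation uses the
binary reduction and keeps the weighted form alongside (it is exercised in
tests against an independent implementation). Nodes with degree ≤ 1 take
C(i) = 0.

Path-based metrics use all-pairs BFS distances (computed by dense level-set
matrix products, exact for unweighted graphs). L_p is the mean over ordered
pairs at *finite* distance, with a `disconnected` flag whenever infinite
pairs were excluded — efficiency metrics need no such convention because
1/∞ = 0. An edgeless graph reports L_p = NaN with the flag set.

Null models are Maslov–Sneppen double edge swaps: 10·|E| attempted swaps
per null, proposals creating self-loops or multi-edges rejected, 100 nulls
by default, all driven by a seeded generator (identical seeds give
bit-identical C_rand, L_rand). Degree sequences that admit no swap (e.g.
complete graphs) return the input's own metrics. Small-worldness requires
γ = C_p/C_rand > 1 and λ = L_p/L_rand ≤ 1.5 — the conventional "λ ≈ 1"
must be operationalized somewhere; 1.5 is deliberately permissive and
configurable, and the binding criterion in practice is γ.

Metric curves are aggregated across the sparsity grid by trapezoidal AUC;
with a single grid level no AUC is reported. Both per-sparsity values and
AUCs appear in every report, since comparisons may be wanted at either
granularity.

## Statistics

* **ICC.** Form ICC(2,1): two-way random effects, absolute agreement,
  single measures — the standard test–retest choice, computed directly from
  the mean-squares decomposition and tagged in the output so alternates can
  be added. Zero-variance regions report ICC 1 with a degenerate-data flag.
  Note the point estimator carries a small negative bias in small samples
  (about −0.009 at 22 subjects × 2 measurements for a population value of
  0.894); parameter-recovery checks at the study size must budget for it.
* **Bland–Altman.** Limits of agreement at mean ± 1.96 SD (n−1 SD), with
  the percentage of pairs inside the limits. "Whole-brain volume" is taken
  as the sum of the 64 regional volumes; an independent brain-mask volume
  would be equally defensible but is not available to this pipeline.
* **ANOVA.** One-way F test per region across workflow groups; significant
  regions counted at raw α = 0.05 by default (matching the convention of
  reporting unadjusted P < 0.05 over 64 regions), Benjamini–Hochberg
  available by flag.
* **Network comparison.** The covariance network is group-level — one graph
  per workflow, no per-subject networks — so classical tests do not apply.
  Inference uses subject-label permutation: within each paired subject row
  the two workflow labels are swapped with probability ½, both networks are
  rebuilt from scratch, and the metric-AUC difference is recomputed;
  p = (1 + #{|null| ≥ |observed|})/(n_perm + 1). This is a standard
  structural-covariance approach chosen here as a reconstruction; the
  historical analyses it emulates did not document their network-level
  inference.

## Problem sizes in the validation suite

The shipped tests run the full chain at the study's size (22 subjects, 64
regions, 19 sparsity levels) but scale ensemble counts to desk scale as the
package's own test-design choice: 12 nulls per sparsity level in the
20-seed small-world sweep (the acceptance script uses the full 100 nulls at
the midpoint level), 2000 simulated cohorts for ANOVA type-I calibration,
200 replicate cohorts for ICC recovery, and 40 null runs × 100 permutations
for permutation-validity (with the correspondingly wider binomial bound).

## Known limitations

* No registration solver, template construction or tissue segmentation:
  transforms, label maps and Jacobian fields are consumed as given.
* The partial-correlation estimator under n ≪ p is a modelling decision
  (see above), not a reproduction of any particular historical tool.
* Bias magnitudes in the generator are placeholders; volume-level effect
  sizes in synthetic runs should not be read as predictions for real data.
* Group-level networks only; no nodal, edge-level, modularity or rich-club
  statistics.
* The permutation comparison rebuilds shrinkage networks per permutation,
  which is O(n_perm) covariance fits; large n_perm is CPU-bound.
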