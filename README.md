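# volcov

Structural covariance brain networks from regional volumes — with the
repeatability and workflow-comparison statistics needed to judge how much a
preprocessing choice (in particular, imperfect skull stripping of neonatal
MRI) distorts the resulting network.

## What it does

Skull stripping is hard in neonates: automatic tools either leave residual
skull (inflating volumes near the skull base) or cut into parenchyma
(shrinking volumes). `volcov` implements the full analysis chain needed to
quantify the downstream consequences:

1. **Atlas-based volumetry.** Given a labelled template, per-subject
   rigid/affine transforms and the Jacobian-determinant field J_F of the
   nonlinear warp, the volume of region *i* is

       V_i = (Σ_{V_t} J_F) · v / (|det A³ˣ³_rigid| · |det A³ˣ³_affine|)

   where the sum runs over the template voxels V_t of the region and *v* is
   the voxel volume. A packaged 64-region gray-matter atlas (32 structures ×
   2 hemispheres, thalamus through insular cortex) defines the nodes.

2. **Covariance network.** Edges are partial correlations between regional
   volumes across subjects, p_ij = −Ω_ij/√(Ω_ii Ω_jj) with Ω the inverse of
   a Ledoit–Wolf-shrunk covariance (22 subjects × 64 regions is rank
   deficient without regularization). The weighted matrix is binarized by
   keeping the top round(s·2016) edges over a sparsity grid s = 0.10–0.46.

3. **Small-world metrics.** Clustering coefficient C_p, characteristic path
   length L_p, global and local efficiency E_glob/E_loc, compared against
   degree-preserving Maslov–Sneppen rewired nulls: the network is
   small-world when γ = C_p/C_rand > 1 while λ = L_p/L_rand ≈ 1.

4. **Statistics.** Test–retest repeatability via ICC(2,1) and Bland–Altman
   limits of agreement; per-region one-way ANOVA across preprocessing
   workflows; permutation inference (subject-label swaps with full network
   rebuild) for group-level network-metric differences.

5. **Synthetic cohorts.** A generator produces log-normal regional volumes
   with block (modular) correlation structure, workflow-specific
   multiplicative biases (a BET-like workflow runs small everywhere, an
   iBEAT-like one runs large near the skull base) and repeated-measurement
   noise — so the whole chain can be exercised and validated end to end
   without any image data.

## Worked example

```python
from volcov import (CohortConfig, NullModelConfig, generate_cohort,
                    generate_repeats, build_network, metrics_over_range, icc)

cfg = CohortConfig(seed=42)                      # 22 subjects, 4 modules
tables = generate_cohort(cfg)                    # one table per workflow
net = build_network(tables["iBEAT_corrected"])   # partial corr + binarize
report = metrics_over_range(net, NullModelConfig(n_null=100, seed=42))
m = report.per_sparsity[0.28]
print(f"Cp={m.cp:.3f} Lp={m.lp:.3f} gamma={m.gamma:.3f} lambda={m.lam:.3f}")
```

prints

```
Cp=0.457 Lp=1.783 gamma=1.212 lambda=0.990
```

— at 28 % sparsity the synthetic cohort's network is 21 % more clustered
than its degree-matched random nulls at essentially equal path length, i.e.
small-world (`report.small_world_overall` is `True` across the grid).
Repeatability on the same cohort with a measurement SD of 150 mm³:

```python
reps = generate_repeats(CohortConfig(seed=42, repeat_sd=150.0), 2)
print(f"average ICC = {icc(reps).average:.3f}")   # -> average ICC = 0.729
```

The command line mirrors the library (`volcov simulate | volumes | network |
metrics | repeatability | compare | run-all`); `volcov run-all --seed 1
--out results/` reproduces the whole chain in one call and writes a
manifest with the config hash and seed.

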