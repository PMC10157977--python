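# rohdepress

Genomic inbreeding coefficients and inbreeding-depression mapping for
repeated-records livestock traits, built around runs of homozygosity (ROH).

## The problem

Mating between relatives raises genome-wide homozygosity and depresses
quantitative traits — inbreeding depression.  For artificial-insemination
(AI) bulls, semen quality traits (ejaculate volume, sperm concentration,
sperm motility) are recorded repeatedly over each bull's service life, so
quantifying depression needs a repeated-records animal model on top of the
genomic inbreeding estimates.  ROH-based inbreeding additionally carries a
clock: an IBD haplotype whose common ancestor lived `gcA` generations ago
has expected length `E(L) = 100 / (2·gcA)` Mb, so long ROH mark recent
inbreeding and short ROH ancient inbreeding, and per-SNP ROH state can map
*where* in the genome homozygosity hurts.

## What the package computes

* **ROH calling** under five joint constraints (span ≥ 1 Mb, ≥ 15 SNPs,
  ≤ 1 SNP per 100 kb average density, ≤ 1 heterozygous call, no inter-SNP
  gap > 500 kb), as an exactly specified maximal-interval rule that is
  verified against a brute-force oracle, plus length classes
  [1,2), [2,4), [4,8), [8,16), [16,∞) Mb.
* **Inbreeding coefficients**: `F_ROH,i = Σ_k L_ROH,ik / L_g` (fraction of
  the SNP-covered autosomal genome in ROH) with its exact length-class
  decomposition, and the excess-of-homozygosity coefficient
  `F_SNP,i = (OH_i − EH) / (s − EH)` with
  `EH = Σ_j [1 − 2 m_j (1 − m_j)]`.
* **Animal model** (AI-REML with EM fallback): for record *l* of bull *m*,
  `y = μ + year_season + centre + interval + n_sample + b1·age + b2·F_m +
  u_m + pe_m + e`, with `u ~ N(0, G σ²_a)` (VanRaden method-1 GRM),
  permanent environment `pe ~ N(0, I σ²_pe)` and residual `e`; h² and
  repeatability from the variance components; a variant fits the five ROH
  length-class coefficients jointly.
* **Per-SNP scan**: each SNP enters with its additive dosage (0/1/2) and
  its 0/1 ROH state; the ROH-state coefficient measures local
  inbreeding-depression after additive adjustment.  Multiple testing is
  summarized by the proportion-based FDR `P(1−N) / (N(1−P))`, significant
  SNPs are merged into regions, and genes within ±500 kb are reported.
* **Synthetic populations** (gene dropping with Haldane recombination and
  exact IBD truth via founder-haplotype identity) so the whole pipeline is
  testable end to end with known effect sizes.

## Worked example

```python
from rohdepress import simdata, roh, inbreeding, io, lmm, scan

cfg = simdata.preset_config("default", seed=1)
g, truth = simdata.simulate_genotypes(cfg)
ph, truth = simdata.simulate_phenotypes(g, truth, cfg)

segments = roh.detect_roh(g)
table = inbreeding.inbreeding_table(g, segments)
print(f"called {len(segments)} ROH segments in {g.n_samples} bulls")
print(f"mean F_ROH = {table.f_roh.mean():.3f}   mean F_SNP = {table.f_snp.mean():.3f}")

grm = lmm.build_grm(io.filter_markers_qc(g))
base = lmm.fit_animal_model(ph, grm)
h2, r = lmm.heritability_repeatability(base.vc)
print(f"h2 = {h2:.3f}   repeatability = {r:.3f}")

fit = lmm.fit_animal_model(ph, grm, covariates=table[["f_roh"]])
c = fit.coefficient("f_roh")
print(f"b2 (F_ROH) = {c.estimate:.2f} +/- {c.se:.2f}  (p = {c.p:.2e}; simulated effect {cfg.b2_true})")

states = scan.roh_state_matrix(segments, g.markers, g.samples)
result = scan.run_scan(ph, grm, g, states, base)
p_star, fdr_star = scan.min_fdr_threshold(result, [1e-3, 1e-4, 1e-5, 1e-6])
print(f"minimum FDR {fdr_star:.2e} at p-threshold {p_star:g}")
```

prints

```
called 5561 ROH segments in 300 bulls
mean F_ROH = 0.241   mean F_SNP = 0.043
h2 = 0.134   repeatability = 0.385
b2 (F_ROH) = -7.05 +/- 1.05  (p = 1.10e-10; simulated effect -5.33)
minimum FDR 3.63e-05 at p-threshold 1e-06
```

The regression coefficient on F_ROH is the depression per unit inbreeding
in trait units (here sperm-concentration-like units of 10⁸ per mL): a 1 %
rise in F_ROH costs about 0.07 units.  The two deleterious loci injected by
the `default` preset dominate the scan's smallest p-values, so the minimum
FDR lands at the tightest threshold.

The same stages are available from the shell:

```sh
rohdepress simulate --preset default --seed 1 --out sim/
rohdepress roh --bfile sim/genotypes --out sim/roh.tsv
rohdepress all --config run.yaml
```

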