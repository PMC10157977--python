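# Methods

This note documents the statistical models, algorithms and numerical
choices behind `rohdepress`, and what the synthetic-data tests do and do
not establish about real data.

## Data model and quality control

Genotypes are biallelic autosomal SNP dosages (0/1/2 copies of one
allele) for ~hundreds of bulls; every downstream statistic is symmetric
in the allele orientation (property-tested).  Datasets are assumed fully
imputed: strict mode rejects missing calls; a permissive mode (off by
default) excludes missing calls from both the observed and expected
homozygosity sums.

Marker QC retains SNPs with MAF ≥ 0.01 and a Hardy–Weinberg 1-df Pearson
chi-square p ≥ 1e-6 (no continuity correction; allele frequencies from
the analyzed sample).  Two marker sets flow through the pipeline on
purpose: the **full** set feeds F_SNP, ROH calling and the scan (low-MAF
SNPs carry real homozygosity information), while the **post-QC** set
builds the genomic relationship matrix.  Phenotype records are kept on
closed plausibility ranges per trait: ejaculate volume 1–25 mL, sperm
concentration 1–30 ×10⁸/mL, sperm motility 0.10–0.98.

## ROH calling

A run of homozygosity is a set of consecutive mapped SNPs satisfying all
of: span ≥ 1 Mb, ≥ 15 SNPs, average density span/n ≤ 100 kb per SNP,
≤ 1 heterozygous call, and no adjacent-SNP gap > 500 kb.  Rather than a
sliding-window hit-proportion heuristic (whose window parameters are
tool-specific), the caller returns every **containment-maximal** interval
satisfying the five constraints: no returned run is a subinterval of
another satisfying run, which also implies no run can be extended by one
SNP without violating a constraint.

Algorithm: per individual and chromosome, the SNP string is first split
at gaps > 500 kb, then into maximal windows containing at most one
heterozygote.  A window that passes span/count/density is itself the
unique maximal run it contains.  When only the density rule fails, the
identity span ≤ d·n ⇔ f(j) ≤ f(i) + d − 1 with f(t) = pos(t) − d·t
reduces the search to, for each start, the largest admissible end, after
which a dominance sweep keeps the non-nested intervals.  Equivalence
with an O(n²) brute-force enumeration is asserted on 500 random fixtures
spanning all five rules.

Segment length is `end − start + 1` bp (1-based closed interval, as in
bim files).  Length classes are lower-closed Mb bins [1,2), [2,4),
[4,8), [8,16), [16,∞); a segment of exactly 16 Mb falls in the top
class.  Class totals per animal sum to the total ROH coverage exactly.

## Inbreeding coefficients

* `F_ROH = Σ L_ROH / L_g`, with L_g the SNP-covered autosomal genome
  length: per chromosome, last minus first mapped position plus 1
  (the +1 from the closed interval is negligible and documented);
  chromosomes with fewer than two SNPs are excluded with a warning.
* `F_SNP = (OH − EH) / (s − EH)` with `EH = Σ_j [1 − 2 m_j (1 − m_j)]`
  over all s markers, MAFs from the analysis sample itself.  It is 1 at
  complete homozygosity, negative when observed homozygosity is below
  the Hardy–Weinberg expectation, and undefined (error) when every
  marker is monomorphic.
* The haplotype-age clock `E(L | gcA) = 100/(2·gcA)` Mb and its inverse
  convert segment length to generations to the common ancestor; the
  length classes thus read as ~50–25, 25–12.5, 12.5–6, 6–3 and < 3
  generations.
* Pearson correlations among the seven measures use pairwise-complete
  samples, no shrinkage; zero-variance measures report NaN.

## Animal model and AI-REML

For record *l* of bull *m*:

y = μ + year_season + centre + interval + n_sample + b₁·age + Σ_q b₂q·F_mq + u_m + pe_m + e

with u ~ N(0, G σ²_a), pe ~ N(0, I σ²_pe), e ~ N(0, I σ²_e).  The GRM is
VanRaden method 1, `G = ZZ'/(2 Σ p_j(1−p_j))` with observed allele
frequencies (the field default for blupf90-family software), plus a
1e-6 diagonal ridge.  Categorical fixed effects are reference-encoded
(first level by string sort dropped; single-level factors absorbed into
the intercept); a singular fixed-effect design raises an error naming
the collinear columns; zero-variance covariates are reported as NA
coefficients rather than silently dropped.

Because both random effects are indexed by bull, V = σ²_e I + Z K Z'
with K = σ²_a G + σ²_pe I and Z'Z diagonal (records per bull), so the
Woodbury identity reduces every trace and quadratic form to q×q algebra
(q = number of bulls); record counts in the hundreds of thousands stay
tractable.  Iterations use the average-information update with the AI
step clamped to the parameter floor and step-halved if it does not
improve the restricted likelihood; remaining failures fall back to the
EM update (guaranteed ascent), so the accepted trajectory is monotone —
asserted in tests.  Convergence: relative VC change < 1e-8 or
|Δ log-likelihood| < 1e-9, at most 200 iterations (error carrying the
trajectory beyond that).  Components are floored at 1e-10 × phenotypic
variance.  Default starting values are equal thirds of the phenotypic
variance; an explicit prior can be supplied.  With G = I, σ²_a and
σ²_pe are only jointly identified; the flat likelihood direction is
handled by the same machinery and tests assert their sum against the
balanced-ANOVA closed form (σ̂²_e = MSE, σ̂²_a+pe = (MSB−MSE)/m).

Inference on fixed effects: estimate/SE referred to Student's t with
df = q − rank(X).  Bulls, not records, are the effective replication
for per-bull covariates such as the inbreeding coefficients, so the
bull count sets the df.  Heritability h² = σ²_a/total and repeatability
r = (σ²_a+σ²_pe)/total are reported from the fit *without* the
inbreeding covariate.

## Per-SNP scan and FDR

Model: the genome-wide F covariate is replaced by the SNP's additive
dosage and its 0/1 ROH state (1 iff the SNP lies inside any called ROH
segment of the bull, closed interval).  Variance components are held
fixed at the base-model estimates — refitting them 10⁴–10⁵ times is
computationally unjustified and leaves the per-SNP solutions exact GLS
solutions at those components, which the tests verify against full
dense joint refits (agreement to 1e-8).  Implementation-wise the base
q×q projections are precomputed once and each SNP costs one 2×2 Schur
complement, so a genome scans in seconds.  SNPs whose ROH-state column
is constant across bulls — or exactly collinear with the additive
dosage, leaving no independent homozygosity contrast — are flagged
`NA_no_variation`; monomorphic SNPs with a variable ROH state are fit
with the ROH state alone (additive coefficient NA).  Two-sided p-values
use t with df = q − rank(design).

The proportion-based FDR is `P(1−N)/(N(1−P))` with P the p-value
threshold and N the proportion of significant SNPs among the tested
(ok-status) SNPs; a threshold search returns the candidate with minimum
FDR, ties toward the smaller threshold.  Significant SNPs within 1 Mb
(configurable) on a chromosome merge into regions; genes from a user
BED overlapping the region ± 500 kb are listed.

## Synthetic populations

The generator emulates an AI-bull study: founder haplotypes drawn per
SNP at frequencies uniform in 0.05–0.5 on 5 × 100 Mb chromosomes with
50 kb marker spacing; a 20-generation random-mating burn-in at constant
size 100 (a Holstein-like effective population size) accumulates
ancient autozygosity (expected F ≈ g/2Ne ≈ 0.10, segments of a few Mb);
20 % of the 300 bulls come from deliberate sire × daughter matings
(three meioses between the two copies, so expected segment length
≈ 33 Mb and expected autozygosity 0.25 above background).  Gametes are
founder-haplotype mosaics recombined under a Haldane map at 1 cM/Mb, so
IBD is defined by founder-haplotype identity — exactly the
IBD-versus-IBS distinction the ROH literature relies on — and the truth
(per-bull IBD fraction and segment list) is recorded as dropped.  Each
truth segment carries a generation-of-origin *estimate* from the length
clock 100/(2L); exact ancestral tracing would require full ancestral
recombination-graph bookkeeping and is deliberately out of scope.

Phenotypes follow the same generative model the estimation stage fits:
trait-scale mean 12.67 and variance components (2.3, 4.4, 14.5)
chosen to mimic sperm concentration (h² ≈ 0.11, r ≈ 0.32), 12
year-season, 4 centre, 4 interval and 3 samples-per-day levels with
N(0, 0.5²) level effects, age uniform 12–120 months with slope 0.02
per month, 6–30 records per bull, genome-wide depression −5.33 trait
units per unit IBD, and (in the `default` preset) two deleterious
recessive loci of −3 trait units acting on the true IBD state.  The
additive effect is drawn N(0, G σ²_a) through a Cholesky factor of the
realized GRM (ridged and retried if needed).  One seed fans out into
named substreams (genotypes, effects, residuals).

What the generator does **not** emulate — and hence what passing tests
do not show about real data:

* Founder alleles are drawn independently per SNP, so there is no LD
  and no coalescent background sharing.  Two consequences: chance-IBS
  homozygous runs behave like independent-site noise (with the default
  MAF band they add a baseline of roughly 0.10 to called F_ROH, which
  is why the example's mean F_ROH of 0.24 exceeds the true mean IBD of
  0.14), and the correlation between called F_ROH and true IBD (≈ 0.96
  at study scale) is what licenses the regression tests despite that
  baseline.  On real chip data the same runs would largely be genuine
  ancient IBD.
* No selection, so no purging dynamics: the recent-versus-ancient
  contrast in the `recent-only` preset comes purely from mating design.
* Chromosomes are equal-length with evenly spaced markers and uniform
  record counts per bull (6–30), not the heavy-tailed 6–1,415 range of
  real service records.

Measurement error in called F_ROH attenuates the genome-wide regression
toward zero, while injected loci leak into it with the opposite sign
(their IBD state is correlated with total IBD); at the default study
scale the two partially offset and the 2-SE recovery band absorbs the
remainder.  The unbiasedness and SE calibration of the estimator itself
are tested with the true IBD fraction as covariate across 20 seeded
replicates.

## Problem sizes and tolerances in the test suite

Study-scale scenarios use 300 bulls × 10,000 SNPs with ~5,400 records
(simulated, called, fitted and scanned in well under a minute); oracle
equivalences run on ≤ 40-bull instances where dense n×n solves are
exact references; the ROH brute-force comparison uses 500 random
strings of ≤ 60 SNPs; replicate properties use 20 seeds of a reduced
200-bull, 3-chromosome variant.  Statistical assertions use 2-SE bands
for effect recovery, 3-SE bands for simulation means against classical
expectations, and the binomial 99% interval for type-I calibration; all
simulation tests are fixed-seed.
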