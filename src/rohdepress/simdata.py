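"""Gene-dropping simulator with exact IBD truth and repeated phenotype records.

The generator emulates the structure of an AI-bull study population:

* founder haplotypes drawn per SNP at frequencies in a configurable MAF
  band, on ``n_chrom`` equal autosomes with evenly spaced markers;
* a closed random-mating burn-in of ``n_generations_ancient`` generations
  at constant size ``n_founders`` (a small effective population size),
  which accumulates *ancient* autozygosity as short IBD segments;
* a final bull cohort in which a configurable fraction of bulls is
  produced by deliberate sire x daughter matings, injecting *recent*
  inbreeding as long IBD segments (expected length 100/(2 gcA) Mb);
* repeated phenotype records per bull generated from the same model the
  estimation stage fits: fixed year-season / centre / interval /
  samples-per-day effects, a linear age regression, a genome-wide
  inbreeding-depression effect acting on the *true* IBD fraction,
  optional locus-specific effects acting on the true IBD state at chosen
  markers, an additive genetic effect drawn from N(0, G sigma_a2) via the
  realized genomic relationship matrix, a permanent-environment effect
  per bull and an i.i.d. residual per record.

IBD is tracked by founder-haplotype identity (gametes are mosaics of
founder haplotype labels, recombined under a Haldane map), which
separates identity by descent from identity by state exactly: called ROH
can then be scored against the true autozygous segments.  One global
seed fans out into named substreams (genotypes, effects, residuals) so
each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix
from .lmm import build_grm

#: generations of meiosis separating the two copies in a sire x daughter
#: mating (bull->sire plus bull->daughter->sire)
_SIRE_DAUGHTER_MEIOSES = 3


@dataclass
class SimConfig:
    """Study-scale parameters of the synthetic population."""

    seed: int
    n_founders: int = 100
    n_generations_ancient: int = 20
    n_bulls: int = 300
    n_chrom: int = 5
    chrom_length_mb: float = 100.0
    snp_spacing_kb: float = 50.0
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    recomb_rate_cM_per_Mb: float = 1.0
    records_per_bull_range: tuple[int, int] = (6, 30)
    n_year_season: int = 12
    n_center: int = 4
    n_interval: int = 4
    n_sample_levels: int = 3
    age_range_months: tuple[float, float] = (12.0, 120.0)
    trait: str = "SC"
    mu: float = 12.67
    vc_true: tuple[float, float, float] = (2.3, 4.4, 14.5)
    b_age_true: float = 0.02
    b2_true: float = -5.33
    locus_effects: tuple[tuple[int, float], ...] = ()
    close_mating_fraction: float = 0.2
    fixed_effect_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        counts = (self.n_founders, self.n_bulls, self.n_chrom,
                  self.n_year_season, self.n_center, self.n_interval,
                  self.n_sample_levels)
        if min(counts) <= 0:
            raise ValueError("all population/level counts must be positive")
        if not 0.0 <= self.close_mating_fraction <= 1.0:
            raise ValueError("close_mating_fraction must lie in [0, 1]")
        if self.n_founders < 3 and self.close_mating_fraction > 0:
            raise ValueError("infeasible mating design: need >= 3 founders for close matings")
        if self.records_per_bull_range[0] < 1 or (
            self.records_per_bull_range[0] > self.records_per_bull_range[1]
        ):
            raise ValueError("invalid records_per_bull_range")
        if not all(np.isfinite(v) for v in self.vc_true) or min(self.vc_true) < 0:
            raise ValueError("true variance components must be finite and non-negative")
        if not all(np.isfinite(d) for _, d in self.locus_effects):
            raise ValueError("locus effects must be finite")

    @property
    def chrom_length_bp(self) -> int:
        return int(round(self.chrom_length_mb * 1e6))

    @property
    def morgans_per_chrom(self) -> float:
        return self.recomb_rate_cM_per_Mb * self.chrom_length_mb / 100.0

    def rng(self, stream: str) -> np.random.Generator:
        offset = {"genotypes": 1, "effects": 2, "residuals": 3}[stream]
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), offset]))


@dataclass
class SimTruth:
    """Ground truth recorded while dropping gametes and phenotypes."""

    ibd_fraction: pd.Series
    ibd_segments: pd.DataFrame
    breeding_values: pd.Series | None = None
    pe_values: pd.Series | None = None
    record_expected: np.ndarray | None = None
    config: SimConfig | None = None


# a haplotype on one chromosome: (segment start positions, founder hap ids);
# segment k covers [starts[k], starts[k+1] - 1] (last runs to chromosome end)
Hap = tuple[np.ndarray, np.ndarray]
Individual = list[tuple[Hap, Hap]]


def _gamete_chrom(hap_a: Hap, hap_b: Hap, length_bp: int, morgans: float,
                  rng: np.random.Generator) -> Hap:
    """One meiotic product: crossovers Poisson(morgans), Haldane (no interference)."""
    k = rng.poisson(morgans)
    cross = np.sort(rng.integers(2, length_bp + 1, size=k)) if k else np.empty(0, np.int64)
    cross = np.unique(cross)
    current = int(rng.integers(2))
    haps = (hap_a, hap_b)
    bounds = np.concatenate([[1], cross, [length_bp + 1]]).astype(np.int64)
    starts: list[int] = []
    ids: list[int] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if a >= b:
            continue
        s, i = haps[current]
        j0 = int(np.searchsorted(s, a, side="right")) - 1
        j1 = int(np.searchsorted(s, b, side="left"))
        for j in range(j0, j1):
            starts.append(max(int(s[j]), int(a)))
            ids.append(int(i[j]))
        current ^= 1
    starts_arr = np.asarray(starts, dtype=np.int64)
    ids_arr = np.asarray(ids, dtype=np.int64)
    keep = np.concatenate([[True], ids_arr[1:] != ids_arr[:-1]])
    return starts_arr[keep], ids_arr[keep]


def mate(parent1: Individual, parent2: Individual, cfg: SimConfig,
         rng: np.random.Generator) -> Individual:
    """Offspring of two individuals: one recombinant gamete from each."""
    child: Individual = []
    for c in range(cfg.n_chrom):
        g1 = _gamete_chrom(*parent1[c], cfg.chrom_length_bp, cfg.morgans_per_chrom, rng)
        g2 = _gamete_chrom(*parent2[c], cfg.chrom_length_bp, cfg.morgans_per_chrom, rng)
        child.append((g1, g2))
    return child


def founder_individual(index: int, cfg: SimConfig) -> Individual:
    one = np.array([1], dtype=np.int64)
    return [
        ((one.copy(), np.array([2 * index], dtype=np.int64)),
         (one.copy(), np.array([2 * index + 1], dtype=np.int64)))
        for _ in range(cfg.n_chrom)
    ]


def _ibd_segments_chrom(hap_a: Hap, hap_b: Hap, length_bp: int) -> list[tuple[int, int]]:
    """Intervals where the two haplotypes carry the same founder haplotype."""
    sa, ia = hap_a
    sb, ib = hap_b
    bounds = np.union1d(sa, sb)
    out: list[tuple[int, int]] = []
    for idx, start in enumerate(bounds):
        end = int(bounds[idx + 1] - 1) if idx + 1 < len(bounds) else length_bp
        id_a = int(ia[np.searchsorted(sa, start, side="right") - 1])
        id_b = int(ib[np.searchsorted(sb, start, side="right") - 1])
        if id_a == id_b:
            if out and out[-1][1] == start - 1:
                out[-1] = (out[-1][0], end)
            else:
                out.append((int(start), end))
    return out


def _marker_map(cfg: SimConfig) -> pd.DataFrame:
    spacing = int(round(cfg.snp_spacing_kb * 1000))
    per_chrom = cfg.chrom_length_bp // spacing
    rows = []
    for c in range(1, cfg.n_chrom + 1):
        pos = spacing // 2 + spacing * np.arange(per_chrom)
        for k, p in enumerate(pos):
            rows.append((f"snp{c}_{k}", c, int(p), "A", "B"))
    return pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp", "allele_a", "allele_b"])


def _hap_alleles(hap: Hap, pos: np.ndarray, founder_alleles: np.ndarray,
                 chrom_offset: int) -> np.ndarray:
    starts, ids = hap
    out = np.empty(len(pos), dtype=np.int8)
    cut = np.searchsorted(pos, starts, side="left")
    cut = np.concatenate([cut, [len(pos)]])
    for k in range(len(starts)):
        lo, hi = cut[k], cut[k + 1]
        if lo < hi:
            out[lo:hi] = founder_alleles[ids[k], chrom_offset + lo : chrom_offset + hi]
    return out


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Drop gametes through the burn-in and bull cohort; return genotypes
    plus exact IBD truth per bull."""
    rng = cfg.rng("genotypes")
    markers = _marker_map(cfg)
    n_snps = len(markers)
    chroms = markers["chrom"].to_numpy()
    pos_all = markers["pos_bp"].to_numpy()
    chrom_slices = {
        c: slice(int(np.nonzero(chroms == c)[0][0]), int(np.nonzero(chroms == c)[0][-1]) + 1)
        for c in range(1, cfg.n_chrom + 1)
    }

    lo, hi = cfg.founder_maf_range
    maf = rng.uniform(lo, hi, size=n_snps)
    freq_b = np.where(rng.random(n_snps) < 0.5, maf, 1.0 - maf)
    founder_alleles = (
        rng.random((2 * cfg.n_founders, n_snps)) < freq_b[np.newaxis, :]
    ).astype(np.int8)

    population = [founder_individual(i, cfg) for i in range(cfg.n_founders)]
    for _ in range(cfg.n_generations_ancient):
        new_pop = []
        for _ in range(cfg.n_founders):
            i, j = rng.choice(cfg.n_founders, size=2, replace=False)
            new_pop.append(mate(population[i], population[j], cfg, rng))
        population = new_pop

    n_close = int(round(cfg.close_mating_fraction * cfg.n_bulls))
    bulls: list[Individual] = []
    for b in range(cfg.n_bulls):
        if b < n_close:
            sire_i, dam_i, dam2_i = rng.choice(len(population), size=3, replace=False)
            daughter = mate(population[sire_i], population[dam2_i], cfg, rng)
            bulls.append(mate(population[sire_i], daughter, cfg, rng))
        else:
            i, j = rng.choice(len(population), size=2, replace=False)
            bulls.append(mate(population[i], population[j], cfg, rng))

    sample_ids = [f"bull_{b:04d}" for b in range(cfg.n_bulls)]
    dosage = np.empty((cfg.n_bulls, n_snps), dtype=np.int8)
    seg_rows = []
    genome_bp = cfg.n_chrom * cfg.chrom_length_bp
    ibd_bp = np.zeros(cfg.n_bulls, dtype=np.int64)
    for b, ind in enumerate(bulls):
        for c in range(1, cfg.n_chrom + 1):
            sl = chrom_slices[c]
            cpos = pos_all[sl]
            hap_p, hap_m = ind[c - 1]
            al_p = _hap_alleles(hap_p, cpos, founder_alleles, sl.start)
            al_m = _hap_alleles(hap_m, cpos, founder_alleles, sl.start)
            dosage[b, sl] = al_p + al_m
            for start, end in _ibd_segments_chrom(hap_p, hap_m, cfg.chrom_length_bp):
                length = end - start + 1
                ibd_bp[b] += length
                seg_rows.append((sample_ids[b], c, start, end, length))
    segments = pd.DataFrame(
        seg_rows, columns=["sample_id", "chrom", "start_bp", "end_bp", "length_bp"]
    )
    if not segments.empty:
        # generation-of-origin estimated from the length clock E(L) = 100/(2 gcA)
        segments["gca_estimate"] = 100.0 / (2.0 * segments["length_bp"] / 1e6)
    else:
        segments["gca_estimate"] = pd.Series(dtype=float)
    truth = SimTruth(
        ibd_fraction=pd.Series(
            ibd_bp / genome_bp, index=pd.Index(sample_ids, name="sample_id"),
            name="ibd_fraction",
        ),
        ibd_segments=segments,
        config=cfg,
    )
    genotypes = GenotypeMatrix(
        samples=sample_ids, markers=markers, dosage=dosage, strict=True
    )
    return genotypes, truth


def true_ibd_state(truth: SimTruth, markers: pd.DataFrame) -> np.ndarray:
    """0/1 (bulls x markers): 1 iff the marker lies in a true IBD segment."""
    samples = list(truth.ibd_fraction.index)
    out = np.zeros((len(samples), len(markers)), dtype=np.int8)
    row = {s: i for i, s in enumerate(samples)}
    chroms = markers["chrom"].to_numpy()
    pos = markers["pos_bp"].to_numpy()
    for seg in truth.ibd_segments.itertuples(index=False):
        cmask = chroms == seg.chrom
        idx = np.nonzero(cmask & (pos >= seg.start_bp) & (pos <= seg.end_bp))[0]
        out[row[seg.sample_id], idx] = 1
    return out


def simulate_phenotypes(
    g: GenotypeMatrix, truth: SimTruth, cfg: SimConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Repeated records per bull under the generative animal model.

    Also fills in the realized breeding values, permanent-environment
    values and per-record expected values on ``truth``.
    """
    rng_eff = cfg.rng("effects")
    rng_res = cfg.rng("residuals")
    sa2, spe2, se2 = cfg.vc_true
    q = g.n_samples

    polymorphic = (g.maf() > 0)
    if polymorphic.sum() < 2:
        raise ValueError("too few polymorphic markers to build the realized GRM")
    grm = build_grm(g.subset_markers(polymorphic))
    a = np.zeros(q)
    if sa2 > 0:
        mat = grm.matrix.copy()
        chol = None
        jitter = 0.0
        for _ in range(4):
            try:
                chol = np.linalg.cholesky(mat)
                break
            except np.linalg.LinAlgError:
                jitter = max(jitter * 10.0, 1e-8 * np.trace(mat) / q)
                mat[np.diag_indices_from(mat)] += jitter
        if chol is None:
            raise ValueError("realized GRM is not positive semidefinite even after ridging")
        a = chol @ rng_eff.normal(size=q) * np.sqrt(sa2)
    pe = rng_eff.normal(0.0, np.sqrt(spe2), size=q) if spe2 > 0 else np.zeros(q)

    def level_effects(n_levels: int, prefix: str) -> tuple[list[str], np.ndarray]:
        labels = [f"{prefix}{k + 1:02d}" for k in range(n_levels)]
        return labels, rng_eff.normal(0.0, cfg.fixed_effect_sd, size=n_levels)

    ys_labels, ys_eff = level_effects(cfg.n_year_season, "ys")
    ce_labels, ce_eff = level_effects(cfg.n_center, "c")
    iv_labels, iv_eff = level_effects(cfg.n_interval, "iv")
    ns_labels, ns_eff = level_effects(cfg.n_sample_levels, "ns")

    locus_bonus = np.zeros(q)
    if cfg.locus_effects:
        state = true_ibd_state(truth, g.markers)
        for marker_index, effect in cfg.locus_effects:
            if not 0 <= marker_index < g.n_markers:
                raise ValueError(f"locus index {marker_index} outside the marker map")
            locus_bonus += effect * state[:, marker_index]

    ibd = truth.ibd_fraction.to_numpy()
    lo_rec, hi_rec = cfg.records_per_bull_range
    counts = rng_res.integers(lo_rec, hi_rec + 1, size=q)
    rows = []
    expected_all = []
    for b, sample in enumerate(g.samples):
        n_rec = int(counts[b])
        ys = rng_res.integers(cfg.n_year_season, size=n_rec)
        ce = rng_res.integers(cfg.n_center, size=n_rec)
        iv = rng_res.integers(cfg.n_interval, size=n_rec)
        ns = rng_res.integers(cfg.n_sample_levels, size=n_rec)
        age = rng_res.uniform(*cfg.age_range_months, size=n_rec)
        expected = (
            cfg.mu + ys_eff[ys] + ce_eff[ce] + iv_eff[iv] + ns_eff[ns]
            + cfg.b_age_true * age
            + cfg.b2_true * ibd[b] + locus_bonus[b] + a[b] + pe[b]
        )
        value = expected + rng_res.normal(0.0, np.sqrt(se2), size=n_rec)
        expected_all.append(expected)
        for k in range(n_rec):
            rows.append(
                (sample, cfg.trait, value[k], ys_labels[ys[k]], ce_labels[ce[k]],
                 iv_labels[iv[k]], ns_labels[ns[k]], age[k])
            )
    ph = pd.DataFrame(
        rows,
        columns=["bull_id", "trait", "value", "year_season", "center",
                 "interval", "n_sample", "age_months"],
    )
    truth.breeding_values = pd.Series(a, index=truth.ibd_fraction.index, name="breeding_value")
    truth.pe_values = pd.Series(pe, index=truth.ibd_fraction.index, name="pe")
    truth.record_expected = np.concatenate(expected_all)
    return ph, truth


def preset_config(name: str, seed: int, **overrides) -> SimConfig:
    """Named study scenarios.

    ``default``      burn-in plus close matings, genome-wide depression and
                     two injected deleterious recessive loci;
    ``null``         same population structure with every depression effect
                     zeroed (for calibration checks);
    ``recent-only``  no burn-in, close matings only: autozygosity is all
                     recent, so its depression loads on the long ROH classes.
    """
    presets = {
        "default": dict(
            locus_effects=((1000, -3.0), (5200, -3.0)),
        ),
        "null": dict(b2_true=0.0, locus_effects=()),
        "recent-only": dict(
            n_generations_ancient=0, close_mating_fraction=0.3,
            locus_effects=(),
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    params = dict(presets[name])
    params.update(overrides)
    return SimConfig(seed=seed, **params)
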