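"""Genotype, marker-map and phenotype I/O plus marker/phenotype quality control.

Genotypes are held as an individuals x markers allele-dosage matrix
(0/1/2 copies of ``allele_b``; every downstream statistic is symmetric in
the allele coding).  The on-disk interchange format is the PLINK 1 binary
triple (``.bed``/``.bim``/``.fam``, SNP-major, v1.00 magic) or a plain
tab-separated dosage table with a marker-map sidecar.

Datasets are assumed fully imputed: in strict mode (the default) missing
genotypes are rejected outright.  A permissive mode keeps them coded as -1
and excludes them from homozygosity sums downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

AUTOSOMES = tuple(range(1, 30))

#: closed phenotype ranges per trait: ejaculate volume (mL), sperm
#: concentration (1e8 per mL), sperm motility (proportion of motile sperm)
TRAIT_RANGES = {"EV": (1.0, 25.0), "SC": (1.0, 30.0), "SM": (0.1, 0.98)}

PHENOTYPE_COLUMNS = (
    "bull_id", "trait", "value", "year_season", "center",
    "interval", "n_sample", "age_months",
)
MARKER_COLUMNS = ("marker_id", "chrom", "pos_bp", "allele_a", "allele_b")

_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))
# PLINK 2-bit genotype codes -> dosage of allele_b (A2); 0b01 is missing
_CODE_TO_DOSAGE = np.array([0, -1, 1, 2], dtype=np.int8)
_DOSAGE_TO_CODE = np.array([0b00, 0b10, 0b11], dtype=np.uint8)


class GenotypeFormatError(ValueError):
    """Raised for malformed genotype files (bad magic, truncated bed...)."""


def make_marker_map(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a marker map (sorted, unique, autosomal)."""
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"marker map lacks columns {missing}")
    out = df.loc[:, list(MARKER_COLUMNS)].copy()
    out["chrom"] = out["chrom"].astype(int)
    out["pos_bp"] = out["pos_bp"].astype(np.int64)
    if (out["pos_bp"] < 1).any():
        raise ValueError("marker positions must be 1-based positive integers")
    if out["marker_id"].duplicated().any():
        dup = out.loc[out["marker_id"].duplicated(), "marker_id"].iloc[0]
        raise ValueError(f"duplicate marker id {dup!r}")
    out = out.reset_index(drop=True)
    if not out["chrom"].is_monotonic_increasing:
        raise ValueError("markers must be sorted by (chrom, pos_bp)")
    same_chrom = out["chrom"].diff() == 0
    if (same_chrom & (out["pos_bp"].diff() <= 0)).any():
        raise ValueError("marker positions must be strictly increasing within a chromosome")
    return out


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix with its marker map.

    ``dosage[i, j]`` counts copies of ``allele_b`` of marker j in sample i;
    -1 marks a missing call (only allowed with ``strict=False``).
    """

    samples: list[str]
    markers: pd.DataFrame
    dosage: np.ndarray
    strict: bool = True

    def __post_init__(self) -> None:
        self.samples = [str(s) for s in self.samples]
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")
        self.markers = make_marker_map(self.markers)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.dosage, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("dosage values must be in {-1, 0, 1, 2}")
        if self.strict and (self.dosage == -1).any():
            raise ValueError("missing genotypes present but strict mode is on")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def allele_freq_b(self) -> np.ndarray:
        """Frequency of allele_b per marker, from non-missing calls."""
        d = np.ma.masked_equal(self.dosage, -1)
        return np.asarray(d.mean(axis=0) / 2.0)

    def maf(self) -> np.ndarray:
        p = self.allele_freq_b()
        return np.minimum(p, 1.0 - p)

    def genotype_counts(self) -> np.ndarray:
        """Per-marker (n0, n1, n2) genotype counts, shape (n_markers, 3)."""
        return np.stack([(self.dosage == k).sum(axis=0) for k in (0, 1, 2)], axis=1)

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=self.markers.loc[mask].reset_index(drop=True),
            dosage=self.dosage[:, mask],
            strict=self.strict,
        )

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.samples)}
        rows = [index[s] for s in ids]
        return GenotypeMatrix(
            samples=list(ids),
            markers=self.markers.copy(),
            dosage=self.dosage[rows],
            strict=self.strict,
        )


# ---------------------------------------------------------------------------
# PLINK 1 binary

def read_plink(prefix: str | Path, strict: bool = True) -> GenotypeMatrix:
    """Read a PLINK 1 binary ``prefix.bed/.bim/.fam`` triple (SNP-major).

    Markers on non-autosomal chromosome codes (outside 1..29) are dropped
    with a warning; markers are returned sorted by (chrom, pos).
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "marker_id", "cm", "pos_bp", "allele_a", "allele_b"],
        dtype={"marker_id": str, "allele_a": str, "allele_b": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise GenotypeFormatError(
            f"{prefix}.bed: bad magic bytes {raw[:3]!r} (expected SNP-major PLINK v1.00)"
        )
    n_snps, n_samples = len(bim), len(fam)
    bytes_per_snp = (n_samples + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != n_snps * bytes_per_snp:
        raise GenotypeFormatError(
            f"{prefix}.bed: {body.size} data bytes, expected {n_snps * bytes_per_snp}"
        )
    blocks = body.reshape(n_snps, bytes_per_snp)
    codes = np.empty((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    for k, shift in enumerate((0, 2, 4, 6)):
        codes[:, k::4] = (blocks >> shift) & 0b11
    dosage = _CODE_TO_DOSAGE[codes[:, :n_samples]].T  # samples x markers

    chrom_num = pd.to_numeric(bim["chrom"], errors="coerce")
    keep = chrom_num.isin(AUTOSOMES).to_numpy()
    if not keep.all():
        warnings.warn(
            f"dropped {(~keep).sum()} non-autosomal markers "
            f"(chromosome codes outside 1..29)",
            stacklevel=2,
        )
    bim = bim.loc[keep].assign(chrom=chrom_num[keep].astype(int))
    dosage = dosage[:, keep]
    order = np.lexsort((bim["pos_bp"].to_numpy(), bim["chrom"].to_numpy()))
    markers = bim.iloc[order].loc[:, ["marker_id", "chrom", "pos_bp", "allele_a", "allele_b"]]
    return GenotypeMatrix(
        samples=fam["iid"].tolist(),
        markers=markers.reset_index(drop=True),
        dosage=dosage[:, order],
        strict=strict,
    )


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``g`` as a SNP-major PLINK 1 binary triple."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bim = g.markers.assign(cm=0)[["chrom", "marker_id", "cm", "pos_bp", "allele_a", "allele_b"]]
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {"fid": g.samples, "iid": g.samples, "father": 0, "mother": 0, "sex": 0, "pheno": -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    d = g.dosage.T  # markers x samples
    codes = np.where(d == -1, np.uint8(0b01), _DOSAGE_TO_CODE[np.clip(d, 0, 2)])
    n_snps, n_samples = codes.shape
    pad = (-n_samples) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((n_snps, pad), dtype=np.uint8)], axis=1
        )
    quads = codes.reshape(n_snps, -1, 4)
    packed = (
        quads[:, :, 0] | (quads[:, :, 1] << 2) | (quads[:, :, 2] << 4) | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    prefix.with_suffix(".bed").write_bytes(_BED_MAGIC + packed.tobytes())


# ---------------------------------------------------------------------------
# plain-text alternatives

def write_dosage_tsv(g: GenotypeMatrix, dosage_path: str | Path, map_path: str | Path) -> None:
    df = pd.DataFrame(g.dosage, index=pd.Index(g.samples, name="sample_id"),
                      columns=g.markers["marker_id"])
    df.to_csv(dosage_path, sep="\t")
    g.markers.to_csv(map_path, sep="\t", index=False)


def read_dosage_tsv(dosage_path: str | Path, map_path: str | Path,
                    strict: bool = True) -> GenotypeMatrix:
    df = pd.read_csv(dosage_path, sep="\t", index_col=0)
    markers = make_marker_map(pd.read_csv(map_path, sep="\t"))
    df = df.loc[:, markers["marker_id"]]
    return GenotypeMatrix(
        samples=[str(s) for s in df.index],
        markers=markers,
        dosage=df.to_numpy(dtype=np.int8),
        strict=strict,
    )


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    ph = pd.read_csv(
        path, sep="\t",
        dtype={c: str for c in ("bull_id", "trait", "year_season", "center",
                                "interval", "n_sample")},
    )
    missing = [c for c in PHENOTYPE_COLUMNS if c not in ph.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    ph["value"] = ph["value"].astype(float)
    ph["age_months"] = ph["age_months"].astype(float)
    return ph.loc[:, list(PHENOTYPE_COLUMNS)]


def write_phenotypes(ph: pd.DataFrame, path: str | Path) -> None:
    ph.loc[:, list(PHENOTYPE_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation BED (0-based half-open) as 1-based closed intervals."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    bed = bed.iloc[:, :4] if bed.shape[1] >= 4 else bed.iloc[:, :3]
    bed.columns = ["chrom", "start", "end", "name"][: bed.shape[1]]
    if "name" not in bed.columns:
        bed["name"] = [f"feature_{i}" for i in range(len(bed))]
    chrom = bed["chrom"].astype(str).str.replace("^chr", "", regex=True)
    chrom_num = pd.to_numeric(chrom, errors="coerce")
    drop = chrom_num.isna()
    if drop.any():
        warnings.warn(f"dropped {drop.sum()} BED features on non-numeric chromosomes",
                      stacklevel=2)
    out = pd.DataFrame(
        {
            "chrom": chrom_num[~drop].astype(int),
            "start_bp": bed.loc[~drop, "start"].astype(np.int64) + 1,
            "end_bp": bed.loc[~drop, "end"].astype(np.int64),
            "name": bed.loc[~drop, "name"].astype(str),
        }
    ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# quality control

def hwe_test(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson 1-df chi-square test of Hardy-Weinberg equilibrium.

    ``counts`` has one (n0, n1, n2) genotype-count row per marker; expected
    counts come from the sample allele frequency.  Monomorphic markers fit
    HWE perfectly by convention (chi2 = 0, p = 1).  No continuity
    correction is applied.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    n = counts.sum(axis=1)
    if (n <= 0).any():
        raise ValueError("each marker needs at least one genotyped sample")
    p = (counts[:, 1] + 2.0 * counts[:, 2]) / (2.0 * n)
    expected = np.stack(
        [n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2], axis=1
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (counts - expected) ** 2 / expected
    terms[expected == 0] = 0.0  # monomorphic: observed necessarily matches
    chi2 = terms.sum(axis=1)
    return chi2, stats.chi2.sf(chi2, df=1)


def filter_markers_qc(
    g: GenotypeMatrix, maf_min: float = 0.01, hwe_p_min: float = 1e-6
) -> GenotypeMatrix:
    """Retain markers with MAF >= ``maf_min`` and HWE chi-square p >= ``hwe_p_min``.

    The input matrix is left unchanged; allele frequencies come from the
    analyzed sample itself.  An all-monomorphic input yields an empty
    marker set (not an error).
    """
    if (g.dosage == -1).any():
        raise ValueError("marker QC requires a complete (no-missing) genotype matrix")
    _, hwe_p = hwe_test(g.genotype_counts())
    keep = (g.maf() >= maf_min) & (hwe_p >= hwe_p_min)
    return g.subset_markers(keep)


def filter_phenotypes(ph: pd.DataFrame) -> pd.DataFrame:
    """Drop phenotype records outside the closed per-trait plausibility ranges."""
    unknown = set(ph["trait"].unique()) - set(TRAIT_RANGES)
    if unknown:
        raise ValueError(f"unknown trait labels {sorted(unknown)}; expected {sorted(TRAIT_RANGES)}")
    if ph.empty:
        return ph.copy()
    lo = ph["trait"].map({t: r[0] for t, r in TRAIT_RANGES.items()})
    hi = ph["trait"].map({t: r[1] for t, r in TRAIT_RANGES.items()})
    keep = (ph["value"] >= lo) & (ph["value"] <= hi)
    return ph.loc[keep].reset_index(drop=True)
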