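"""Genomic inbreeding coefficients: excess-of-homozygosity F_SNP, ROH-based
F_ROH with length-class decomposition, and the haplotype-age relation.

F_SNP for animal i is (OH_i - EH) / (s - EH), where OH_i counts homozygous
genotypes of the animal over the s markers and EH = sum_j [1 - 2 m_j (1 - m_j)]
is the population expectation under Hardy-Weinberg proportions at the sample
minor-allele frequencies m_j.  It is 1 at complete homozygosity and can be
negative when observed homozygosity falls below expectation.  All markers are
used, including those at very low MAF.

F_ROH for animal i is sum_k L_ROH_ik / L_g: the fraction of the SNP-covered
autosomal genome (L_g) lying in called ROH segments.  Splitting the numerator
by segment-length class gives the five class coefficients, which add up to
F_ROH exactly.

The expected length of an IBD haplotype whose common ancestor lived gcA
generations ago is E(L) = 100 / (2 gcA) Mb, so segment length carries a clock:
long ROH indicate recent inbreeding, short ROH ancient inbreeding.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import GenotypeMatrix
from .roh import CLASS_LABELS, classify_lengths

#: column names for the per-class coefficients in an inbreeding table
CLASS_F_COLUMNS = ("f_roh_1_2", "f_roh_2_4", "f_roh_4_8", "f_roh_8_16", "f_roh_gt16")

MEASURE_COLUMNS = ("f_snp", "f_roh") + CLASS_F_COLUMNS


def f_snp(g: GenotypeMatrix) -> pd.Series:
    """Excess-of-homozygosity inbreeding coefficient per sample.

    MAFs are computed from the analyzed sample itself.  Raises if every
    marker is monomorphic (EH equals s and the coefficient is undefined).
    In permissive mode, missing calls are excluded from both the observed
    and the expected homozygosity sums of the affected sample.
    """
    if g.n_markers < 1:
        raise ValueError("F_SNP requires at least one marker")
    m = g.maf()
    eh_terms = 1.0 - 2.0 * m * (1.0 - m)
    missing = g.dosage == -1
    oh = ((g.dosage == 0) | (g.dosage == 2)).sum(axis=1).astype(float)
    if missing.any():
        eh = np.where(missing, 0.0, eh_terms[np.newaxis, :]).sum(axis=1)
        s = (~missing).sum(axis=1).astype(float)
    else:
        eh = np.full(g.n_samples, eh_terms.sum())
        s = np.full(g.n_samples, float(g.n_markers))
    denom = s - eh
    if np.any(denom <= 0):
        raise ValueError(
            "F_SNP undefined: expected homozygosity equals the marker count "
            "(all markers monomorphic)"
        )
    return pd.Series((oh - eh) / denom, index=pd.Index(g.samples, name="sample_id"),
                     name="f_snp")


def genome_length(markers: pd.DataFrame) -> int:
    """Autosomal genome length covered by SNPs: sum over chromosomes of
    (last SNP position - first SNP position + 1).

    Chromosomes carrying fewer than two SNPs are excluded with a warning.
    """
    if markers.empty:
        raise ValueError("cannot compute genome length from an empty marker map")
    spans = markers.groupby("chrom")["pos_bp"].agg(["min", "max", "count"])
    thin = spans["count"] < 2
    if thin.any():
        warnings.warn(
            f"excluded {int(thin.sum())} chromosome(s) with <2 SNPs from genome length",
            stacklevel=2,
        )
    spans = spans.loc[~thin]
    if spans.empty:
        raise ValueError("no chromosome has >= 2 SNPs; genome length undefined")
    return int((spans["max"] - spans["min"] + 1).sum())


def chromosome_spans(markers: pd.DataFrame) -> pd.Series:
    spans = markers.groupby("chrom")["pos_bp"].agg(["min", "max"])
    return spans["max"] - spans["min"] + 1


def _check_segments(segments: pd.DataFrame, markers: pd.DataFrame | None) -> None:
    if markers is None or segments.empty:
        return
    spans = chromosome_spans(markers)
    seg_len = segments["length_bp"]
    limit = segments["chrom"].map(spans)
    bad = seg_len > limit
    if bad.any():
        row = segments.loc[bad].iloc[0]
        raise ValueError(
            f"segment of {row.length_bp} bp on chromosome {row.chrom} exceeds the "
            f"chromosome's mapped span of {limit[bad].iloc[0]} bp"
        )


def f_roh(
    segments: pd.DataFrame,
    l_g: int,
    samples: list[str],
    markers: pd.DataFrame | None = None,
) -> pd.Series:
    """Per-sample F_ROH = total ROH bp / L_g; samples without segments get 0."""
    if l_g <= 0:
        raise ValueError("genome length must be positive")
    _check_segments(segments, markers)
    out = pd.Series(0.0, index=pd.Index(samples, name="sample_id"), name="f_roh")
    if not segments.empty:
        totals = segments.groupby("sample_id")["length_bp"].sum()
        totals = totals[totals.index.isin(out.index)]
        out.loc[totals.index] = totals / float(l_g)
    return out


def f_roh_classes(
    segments: pd.DataFrame, l_g: int, samples: list[str]
) -> pd.DataFrame:
    """Per-sample, per-length-class F_ROH values (columns ``CLASS_F_COLUMNS``)."""
    if l_g <= 0:
        raise ValueError("genome length must be positive")
    out = pd.DataFrame(
        0.0, index=pd.Index(samples, name="sample_id"), columns=list(CLASS_F_COLUMNS)
    )
    if segments.empty:
        return out
    seg = segments.assign(length_class=classify_lengths(segments["length_bp"].to_numpy()))
    for cls, col in zip(CLASS_LABELS, CLASS_F_COLUMNS):
        totals = seg.loc[seg["length_class"] == cls].groupby("sample_id")["length_bp"].sum()
        totals = totals[totals.index.isin(out.index)]
        out.loc[totals.index, col] = totals / float(l_g)
    return out


def inbreeding_table(g: GenotypeMatrix, segments: pd.DataFrame) -> pd.DataFrame:
    """Per-sample table of F_SNP, F_ROH and the five class coefficients.

    ``g`` is the full (pre-QC) marker set: both the excess-of-homozygosity
    MAFs and the SNP-covered genome length L_g are taken from it.
    """
    l_g = genome_length(g.markers)
    table = pd.concat(
        [
            f_snp(g),
            f_roh(segments, l_g, g.samples, markers=g.markers),
            f_roh_classes(segments, l_g, g.samples),
        ],
        axis=1,
    )
    table.attrs["l_g"] = l_g
    return table


def expected_ibd_length(gca: float) -> float:
    """Expected IBD-haplotype length (Mb) given ``gca`` generations to the
    common ancestor: E(L) = 100 / (2 gcA)."""
    if gca <= 0:
        raise ValueError("generations to common ancestor must be positive")
    return 100.0 / (2.0 * gca)


def generations_for_length(length_mb: float) -> float:
    """Inverse clock: generations to the common ancestor of an IBD haplotype
    of the given expected length (Mb)."""
    if length_mb <= 0:
        raise ValueError("haplotype length must be positive")
    return 100.0 / (2.0 * length_mb)


def f_correlogram(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix among the inbreeding measures.

    Uses pairwise-complete samples; a zero-variance measure yields NaN in
    its row/column (undefined correlation).
    """
    cols = [c for c in MEASURE_COLUMNS if c in table.columns]
    if len(table) < 3:
        raise ValueError("correlogram requires at least 3 samples")
    corr = table[cols].corr(method="pearson")
    zero_var = table[cols].std(ddof=1) == 0
    corr.loc[zero_var, :] = np.nan
    corr.loc[:, zero_var] = np.nan
    return corr
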