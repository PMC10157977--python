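"""Per-SNP mapping of inbreeding-depression loci and proportion-based FDR.

For every autosomal SNP, the repeated-records animal model is refitted
with two extra covariates in place of the genome-wide inbreeding
coefficient: the additive dosage of the SNP (0/1/2, adjusting for the
effect of carrying one more copy of the same allele) and the ROH state
of the SNP (1 if the SNP lies inside any called ROH segment of that
bull, 0 otherwise).  The ROH-state coefficient therefore measures the
effect of local homozygosity-by-descent after correcting for the
additive allele effect.

Variance components are held fixed at the base-model (no-inbreeding)
estimates across all SNP fits; the per-SNP solutions are exact GLS
solutions at those components, obtained by Schur-complement updates of
the base design so the whole genome scans in seconds.  The test suite
verifies their identity with full joint GLS refits.

Multiple testing is summarized by the proportion-based false discovery
rate FDR = P (1 - N) / (N (1 - P)), where P is the p-value threshold and
N the proportion of tested SNPs significant at P.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix
from .lmm import GRM, FitResult, VarianceComponents, _Workspace, build_design

STATUS_OK = "ok"
STATUS_NA = "NA_no_variation"

#: half-width of the gene lookup window around a called region
GENE_WINDOW_BP = 500_000


def roh_state_matrix(
    segments: pd.DataFrame, markers: pd.DataFrame, samples: list[str]
) -> np.ndarray:
    """0/1 matrix (samples x markers): 1 iff the SNP lies inside any called
    ROH segment of that sample (closed interval on both ends)."""
    out = np.zeros((len(samples), len(markers)), dtype=np.int8)
    if segments.empty:
        return out
    row = {s: i for i, s in enumerate(samples)}
    chroms = markers["chrom"].to_numpy()
    pos = markers["pos_bp"].to_numpy()
    offsets = {}
    for chrom in np.unique(chroms):
        idx = np.nonzero(chroms == chrom)[0]
        offsets[int(chrom)] = (idx[0], pos[idx])
    for seg in segments.itertuples(index=False):
        if seg.sample_id not in row or int(seg.chrom) not in offsets:
            continue
        off, cpos = offsets[int(seg.chrom)]
        lo = int(np.searchsorted(cpos, seg.start_bp, side="left"))
        hi = int(np.searchsorted(cpos, seg.end_bp, side="right"))
        out[row[seg.sample_id], off + lo : off + hi] = 1
    return out


def run_scan(
    ph: pd.DataFrame,
    grm: GRM,
    g: GenotypeMatrix,
    roh_states: np.ndarray,
    base_fit: FitResult | VarianceComponents,
    trait: str | None = None,
) -> pd.DataFrame:
    """Scan every marker for an ROH-state effect at fixed variance components.

    ``base_fit`` is the converged base-model fit of the same trait (or its
    variance components); an unconverged fit is refused.  Markers whose
    ROH-state column shows no variation across bulls (or is collinear with
    the additive dosage) are reported with status ``NA_no_variation``.
    """
    if isinstance(base_fit, FitResult):
        if not base_fit.converged:
            raise ValueError("base-model variance components did not converge; refusing scan")
        vc = base_fit.vc
    else:
        vc = base_fit
    if trait is not None:
        ph = ph.loc[ph["trait"] == trait]
    y, X, _, bull_idx, _ = build_design(ph, grm.sample_ids, covariates=None)
    ws = _Workspace(y, X, bull_idx, grm.matrix)
    theta = vc.as_array()
    state = ws.evaluate(theta, derivatives=False)
    B0, XVy, C = state["B"], state["XVy"], state["C"]
    se_ = theta[2]
    D = ws.D
    S = (np.diag(D) - (D[:, None] * C * D[None, :]) / se_) / se_   # Z'V^-1 Z
    T0 = (ws.ZX.T - (ws.ZX.T @ C) * (D / se_)[None, :]) / se_      # X'V^-1 Z
    w = (ws.Zy - D * (C @ ws.Zy) / se_) / se_                      # Z'V^-1 y

    order = {s: i for i, s in enumerate(g.samples)}
    rows = [order[s] for s in grm.sample_ids]
    A1 = g.dosage[rows].astype(float).T          # markers x bulls, additive codes
    A2 = np.asarray(roh_states)[rows].astype(float).T
    q, m = len(grm.sample_ids), A1.shape[0]

    SA1 = A1 @ S
    SA2 = A2 @ S
    c11 = np.einsum("mq,mq->m", A1, SA1)
    c12 = np.einsum("mq,mq->m", A1, SA2)
    c22 = np.einsum("mq,mq->m", A2, SA2)
    t1 = A1 @ T0.T                               # m x p
    t2 = A2 @ T0.T
    r1 = A1 @ w
    r2 = A2 @ w
    Bt1 = t1 @ B0
    Bt2 = t2 @ B0
    m11 = c11 - np.einsum("mp,mp->m", Bt1, t1)
    m12 = c12 - np.einsum("mp,mp->m", Bt1, t2)
    m22 = c22 - np.einsum("mp,mp->m", Bt2, t2)
    rhs1 = r1 - Bt1 @ XVy
    rhs2 = r2 - Bt2 @ XVy

    det = m11 * m22 - m12**2
    scale = np.maximum(np.abs(m11) * np.abs(m22), 1e-300)
    roh_varies = np.ptp(A2, axis=1) > 0
    snp_varies = np.ptp(A1, axis=1) > 0
    joint_ok = roh_varies & snp_varies & (det > 1e-10 * scale) & (m22 > 0)

    b_add = np.full(m, np.nan)
    b_roh = np.full(m, np.nan)
    var_roh = np.full(m, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        b_add[joint_ok] = (m22 * rhs1 - m12 * rhs2)[joint_ok] / det[joint_ok]
        b_roh[joint_ok] = (m11 * rhs2 - m12 * rhs1)[joint_ok] / det[joint_ok]
        var_roh[joint_ok] = m11[joint_ok] / det[joint_ok]
    # monomorphic SNP but variable ROH state: fit the ROH state alone
    roh_only = roh_varies & ~joint_ok & (m22 > 0)
    b_roh[roh_only] = rhs2[roh_only] / m22[roh_only]
    var_roh[roh_only] = 1.0 / m22[roh_only]

    ok = roh_varies & (joint_ok | roh_only)
    n_cov = np.where(joint_ok, 2, 1)
    df = np.maximum(q - X.shape[1] - n_cov, 1)
    se_roh = np.sqrt(var_roh)
    with np.errstate(invalid="ignore"):
        t_roh = b_roh / se_roh
    p_roh = np.where(ok, 2.0 * stats.t.sf(np.abs(t_roh), df=df), np.nan)

    out = pd.DataFrame(
        {
            "marker_id": g.markers["marker_id"].to_numpy(),
            "chrom": g.markers["chrom"].to_numpy(),
            "pos_bp": g.markers["pos_bp"].to_numpy(),
            "b_add": b_add,
            "b_roh": np.where(ok, b_roh, np.nan),
            "se_roh": np.where(ok, se_roh, np.nan),
            "p_roh": p_roh,
            "status": np.where(ok, STATUS_OK, STATUS_NA),
        }
    )
    return out.sort_values(["chrom", "pos_bp"], kind="stable").reset_index(drop=True)


def fdr(p_threshold: float, n_prop: float) -> float:
    """Proportion-based FDR: P (1 - N) / (N (1 - P)).

    P is the p-value threshold and N the proportion of significant SNPs
    among those tested.
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p-value threshold must lie in (0, 1)")
    if not 0 < n_prop <= 1:
        raise ValueError("proportion of significant SNPs must lie in (0, 1]")
    return p_threshold * (1.0 - n_prop) / (n_prop * (1.0 - p_threshold))


def min_fdr_threshold(
    scan: pd.DataFrame, candidate_thresholds: list[float]
) -> tuple[float, float]:
    """The candidate p-value threshold with the smallest proportion-based FDR.

    N is the proportion of ok-status SNPs with p below the threshold;
    candidates with no significant SNP are skipped with a warning.  Ties
    are broken toward the smaller threshold.
    """
    if not candidate_thresholds:
        raise ValueError("candidate threshold list is empty")
    p = scan.loc[scan["status"] == STATUS_OK, "p_roh"].to_numpy()
    if p.size == 0:
        raise ValueError("scan contains no testable SNPs")
    best: tuple[float, float] | None = None
    for thr in sorted(candidate_thresholds):
        n_prop = float(np.mean(p < thr))
        if n_prop == 0:
            warnings.warn(f"no significant SNPs at threshold {thr}; skipped", stacklevel=2)
            continue
        value = fdr(thr, n_prop)
        if best is None or value < best[1]:
            best = (thr, value)
    if best is None:
        raise ValueError("no candidate threshold yielded any significant SNP")
    return best


def call_regions(
    scan: pd.DataFrame,
    p_threshold: float,
    merge_gap_bp: int = 1_000_000,
    gene_bed: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge significant SNPs into regions and look up genes around them.

    Consecutive significant SNPs on a chromosome are merged while their
    spacing stays within ``merge_gap_bp``.  Region bounds are the min/max
    significant SNP positions; the gene window extends the region by
    500 kb on both sides, and genes from ``gene_bed`` (1-based closed)
    overlapping the window are listed.
    """
    sig = scan.loc[(scan["status"] == STATUS_OK) & (scan["p_roh"] < p_threshold)]
    sig = sig.sort_values(["chrom", "pos_bp"], kind="stable")
    rows = []
    for chrom, grp in sig.groupby("chrom"):
        pos = grp["pos_bp"].to_numpy()
        pvals = grp["p_roh"].to_numpy()
        breaks = np.nonzero(np.diff(pos) > merge_gap_bp)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for a, b in zip(starts, ends):
            start_bp, end_bp = int(pos[a]), int(pos[b])
            win_lo = max(1, start_bp - GENE_WINDOW_BP)
            win_hi = end_bp + GENE_WINDOW_BP
            genes = ""
            if gene_bed is not None:
                hit = gene_bed.loc[
                    (gene_bed["chrom"] == chrom)
                    & (gene_bed["start_bp"] <= win_hi)
                    & (gene_bed["end_bp"] >= win_lo)
                ]
                genes = ",".join(hit["name"].tolist())
            rows.append(
                (int(chrom), start_bp, end_bp, int(b - a + 1),
                 float(pvals[a : b + 1].min()), win_lo, win_hi, genes)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start_bp", "end_bp", "n_significant_snps", "min_p",
            "window_start_bp", "window_end_bp", "genes",
        ],
    )
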