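"""ROH-state association scan, proportion-based FDR and region calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import dense_v_matrix
from rohdepress import lmm, scan


def _markers(n, chrom=1, spacing=100_000):
    return pd.DataFrame(
        {"marker_id": [f"m{chrom}_{k}" for k in range(n)], "chrom": chrom,
         "pos_bp": 1_000_000 + spacing * np.arange(n), "allele_a": "A", "allele_b": "B"}
    )


def test_roh_state_closed_interval_boundaries():
    markers = _markers(5)
    segments = pd.DataFrame(
        {"sample_id": ["s1"], "chrom": [1], "start_bp": [1_100_000],
         "end_bp": [1_300_000], "length_bp": [200_001]}
    )
    states = scan.roh_state_matrix(segments, markers, ["s1", "s2"])
    np.testing.assert_array_equal(states[0], [0, 1, 1, 1, 0])
    np.testing.assert_array_equal(states[1], 0)  # no segments -> all-zero row


def test_roh_state_one_bp_outside_segment_is_zero():
    markers = _markers(2, spacing=1)
    segments = pd.DataFrame(
        {"sample_id": ["s1"], "chrom": [1], "start_bp": [900_000],
         "end_bp": [1_000_000], "length_bp": [100_001]}
    )
    states = scan.roh_state_matrix(segments, markers, ["s1"])
    np.testing.assert_array_equal(states[0], [1, 0])


# ---------------------------------------------------------------------------
# scan itself

def test_scan_equals_joint_gls_refit(small_instance):
    """Schur-updated per-SNP solutions equal full dense GLS refits."""
    g, ph, grm = small_instance["g"], small_instance["ph"], small_instance["grm"]
    base, states = small_instance["base"], small_instance["states"]
    res = scan.run_scan(ph, grm, g, states, base)
    y, X0, _, bidx, _ = lmm.build_design(ph, grm.sample_ids)
    Vi = np.linalg.inv(dense_v_matrix(len(y), bidx, grm, base.vc))
    order = {s: i for i, s in enumerate(g.samples)}
    rows = [order[s] for s in grm.sample_ids]
    joint = ((res["status"] == scan.STATUS_OK) & res["b_add"].notna()).to_numpy()
    rng = np.random.default_rng(17)
    for j in rng.choice(np.nonzero(joint)[0], size=40, replace=False):
        snp = g.dosage[rows, j].astype(float)[bidx]
        rst = np.asarray(states)[rows, j].astype(float)[bidx]
        Xf = np.column_stack([X0, snp, rst])
        A = Xf.T @ Vi @ Xf
        b = np.linalg.solve(A, Xf.T @ Vi @ y)
        cov = np.linalg.inv(A)
        row = res.iloc[int(j)]
        np.testing.assert_allclose(row.b_add, b[-2], atol=1e-8)
        np.testing.assert_allclose(row.b_roh, b[-1], atol=1e-8)
        np.testing.assert_allclose(row.se_roh, np.sqrt(cov[-1, -1]), atol=1e-8)


def test_scan_flags_constant_roh_state(small_instance):
    g, ph, grm = small_instance["g"], small_instance["ph"], small_instance["grm"]
    states = np.zeros_like(np.asarray(small_instance["states"]))
    res = scan.run_scan(ph, grm, g, states, small_instance["base"])
    assert (res["status"] == scan.STATUS_NA).all()
    assert res["p_roh"].isna().all()


def test_scan_refuses_unconverged_variance_components(small_instance):
    base = small_instance["base"]
    bad = lmm.FitResult(
        coefficients=base.coefficients, vc=base.vc, vc_se=None, loglik=0.0,
        converged=False, n_records=1, n_bulls=1, n_iter=0,
    )
    with pytest.raises(ValueError, match="converge"):
        scan.run_scan(
            small_instance["ph"], small_instance["grm"], small_instance["g"],
            small_instance["states"], bad,
        )


def test_scan_detects_injected_locus(default_sim, default_scan):
    """Each injected deleterious locus shows an adverse ROH-state effect
    within 2 SE of its true size and ranks in the scan's smallest p-values."""
    cfg, g = default_sim["cfg"], default_sim["g"]
    ok = default_scan.loc[default_scan["status"] == scan.STATUS_OK]
    for idx, effect in cfg.locus_effects:
        mid = g.markers["marker_id"].iloc[idx]
        row = default_scan.set_index("marker_id").loc[mid]
        assert abs(row.b_roh - effect) < 2 * row.se_roh
        assert (ok["p_roh"] < row.p_roh).mean() < 0.01


def test_scan_type_one_error_calibrated_under_null(null_scan):
    """With no depression effects, ~5% of SNPs reach p < 0.05 (binomial 99%)."""
    ok = null_scan.loc[null_scan["status"] == scan.STATUS_OK, "p_roh"]
    frac = float((ok < 0.05).mean())
    half = 2.576 * np.sqrt(0.05 * 0.95 / len(ok))
    assert 0.05 - half < frac < 0.05 + half
    assert (ok > 0).all() and (ok <= 1).all()


# ---------------------------------------------------------------------------
# FDR

def test_fdr_worked_values():
    np.testing.assert_allclose(scan.fdr(0.01, 0.5), 0.01 * 0.5 / (0.5 * 0.99), rtol=1e-12)
    assert scan.fdr(0.2, 0.2) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        scan.fdr(0.0, 0.5)
    with pytest.raises(ValueError):
        scan.fdr(0.01, 0.0)


@settings(max_examples=100, derandomize=True)
@given(
    st.floats(1e-8, 0.5), st.floats(1e-6, 1.0), st.floats(1.0, 3.0)
)
def test_fdr_monotone_in_threshold_and_proportion(p, n, factor):
    """FDR increases with the p threshold and decreases with the proportion
    of significant SNPs."""
    assert scan.fdr(min(p * factor, 0.9), n) >= scan.fdr(p, n)
    assert scan.fdr(p, min(n * factor, 1.0)) <= scan.fdr(p, n)


def _scan_frame(pvals):
    n = len(pvals)
    return pd.DataFrame(
        {
            "marker_id": [f"m{k}" for k in range(n)], "chrom": 1,
            "pos_bp": 1_000_000 + 100_000 * np.arange(n),
            "b_add": 0.0, "b_roh": 0.0, "se_roh": 1.0,
            "p_roh": pvals, "status": scan.STATUS_OK,
        }
    )


def test_min_fdr_threshold_selection_and_ties():
    # uniform grid: N(P) = P exactly at 0.1 and 0.5, so both FDRs are 1
    frame = _scan_frame((np.arange(1000) + 0.5) / 1000)
    p_star, fdr_star = scan.min_fdr_threshold(frame, [0.05])
    assert p_star == 0.05
    p_star, fdr_star = scan.min_fdr_threshold(frame, [0.5, 0.1])
    assert p_star == 0.1 and fdr_star == pytest.approx(1.0)
    with pytest.warns(UserWarning, match="skipped"):
        p_star, _ = scan.min_fdr_threshold(frame, [1e-9, 0.05])
    assert p_star == 0.05


# ---------------------------------------------------------------------------
# region calling

def test_region_merging_depends_on_gap():
    sig_pos = [4_210_000, 4_400_000, 4_660_000,
               5_020_000, 5_300_000, 5_600_000, 5_900_000, 6_200_000, 6_500_000,
               6_740_000]
    frame = pd.DataFrame(
        {
            "marker_id": [f"m{k}" for k in range(len(sig_pos))], "chrom": 1,
            "pos_bp": sig_pos, "b_add": 0.0, "b_roh": -1.0, "se_roh": 0.1,
            "p_roh": 1e-6, "status": scan.STATUS_OK,
        }
    )
    one = scan.call_regions(frame, p_threshold=1e-4, merge_gap_bp=1_000_000)
    assert len(one) == 1
    assert (one.loc[0, "start_bp"], one.loc[0, "end_bp"]) == (4_210_000, 6_740_000)
    two = scan.call_regions(frame, p_threshold=1e-4, merge_gap_bp=300_000)
    assert len(two) == 2


def test_region_calling_empty_and_single_snp():
    frame = _scan_frame(np.full(10, 0.5))
    assert scan.call_regions(frame, 1e-4).empty
    frame.loc[3, "p_roh"] = 1e-9
    regions = scan.call_regions(frame, 1e-4)
    assert len(regions) == 1
    row = regions.iloc[0]
    assert row.start_bp == row.end_bp == frame.loc[3, "pos_bp"]
    assert row.window_start_bp == row.start_bp - 500_000
    assert row.window_end_bp == row.end_bp + 500_000


def test_region_calling_idempotent_and_order_invariant():
    rng = np.random.default_rng(3)
    frame = _scan_frame(rng.random(200) ** 3)
    shuffled = frame.sample(frac=1.0, random_state=1)
    a = scan.call_regions(frame, 0.01)
    b = scan.call_regions(shuffled, 0.01)
    pd.testing.assert_frame_equal(a, b)


def test_region_gene_lookup_uses_500kb_window():
    frame = _scan_frame(np.full(10, 0.5))
    frame.loc[5, "p_roh"] = 1e-9
    pos = frame.loc[5, "pos_bp"]
    genes = pd.DataFrame(
        {
            "chrom": [1, 1, 2],
            "start_bp": [pos - 600_000, pos + 499_000, pos],
            "end_bp": [pos - 501_000, pos + 600_000, pos + 10],
            "name": ["too_far", "in_window", "wrong_chrom"],
        }
    )
    regions = scan.call_regions(frame, 1e-4, gene_bed=genes)
    assert regions.loc[0, "genes"] == "in_window"
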