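"""GRM construction and the AI-REML repeated-records animal model."""

import numpy as np
import pandas as pd
import pytest

from conftest import dense_v_matrix
from rohdepress import inbreeding, lmm, simdata
from rohdepress.io import GenotypeMatrix


def _matrix(dosage):
    dosage = np.asarray(dosage, dtype=np.int8)
    n = dosage.shape[1]
    markers = pd.DataFrame(
        {"marker_id": [f"m{j}" for j in range(n)], "chrom": 1,
         "pos_bp": 1_000_000 + 50_000 * np.arange(n), "allele_a": "A", "allele_b": "B"}
    )
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(dosage.shape[0])], markers=markers, dosage=dosage
    )


def test_grm_hand_worked_example():
    """Two opposite homozygotes at two SNPs: p = 0.5, scale = 1,
    G = [[2, -2], [-2, 2]] up to the stabilizing ridge."""
    grm = lmm.build_grm(_matrix([[0, 0], [2, 2]]))
    np.testing.assert_allclose(
        grm.matrix, [[2, -2], [-2, 2]] + 1e-6 * np.eye(2), atol=1e-12
    )


def test_grm_duplicate_individuals_and_symmetry():
    rng = np.random.default_rng(0)
    dosage = rng.choice([0, 1, 2], size=(6, 50))
    dosage[5] = dosage[0]
    grm = lmm.build_grm(_matrix(dosage))
    np.testing.assert_allclose(grm.matrix, grm.matrix.T, atol=1e-12)
    np.testing.assert_allclose(grm.matrix[0, 5], grm.matrix[0, 0] - 1e-6, atol=1e-12)


def test_grm_rejects_monomorphic_markers():
    dosage = np.array([[0, 0], [2, 0]])
    with pytest.raises(ValueError, match="monomorphic"):
        lmm.build_grm(_matrix(dosage))


def test_grm_diagonal_tracks_mean_inbreeding(default_sim, default_grm):
    """Mean G diagonal ~ 1 + mean excess homozygosity on inbred data."""
    g = default_sim["g"]
    f = inbreeding.f_snp(g)
    mean_diag = np.diag(default_grm.matrix).mean()
    assert abs(mean_diag - (1.0 + f.mean())) < 0.05


# ---------------------------------------------------------------------------
# REML engine

def test_reml_matches_balanced_anova_closed_form():
    """Balanced one-way design with G = I: residual variance equals MSE and
    the bull-level variance (a + pe jointly) equals (MSB - MSE)/m."""
    rng = np.random.default_rng(7)
    nb, m = 30, 6
    y = (rng.normal(0, 2, nb)[:, None] + rng.normal(0, 1.5, (nb, m))).ravel()
    bull_idx = np.repeat(np.arange(nb), m)
    theta, state, hist, *_ = lmm._reml(
        y, np.ones((len(y), 1)), bull_idx, np.eye(nb), lmm._default_start(y)
    )
    bm = y.reshape(nb, m).mean(axis=1)
    msb = m * np.sum((bm - y.mean()) ** 2) / (nb - 1)
    mse = np.sum((y.reshape(nb, m) - bm[:, None]) ** 2) / (nb * (m - 1))
    np.testing.assert_allclose(theta[2], mse, rtol=1e-6)
    np.testing.assert_allclose(theta[0] + theta[1], (msb - mse) / m, rtol=1e-5)
    lls = [h[1] for h in hist]
    assert all(b >= a - 1e-8 for a, b in zip(lls, lls[1:]))


def test_reml_degenerates_to_ols_without_bull_variance():
    """Data with no bull-level variance: VC hit the boundary and the
    intercept equals the grand mean (the OLS solution)."""
    rng = np.random.default_rng(8)
    nb, m = 40, 5
    y = rng.normal(3.0, 1.0, nb * m)
    bull_idx = np.repeat(np.arange(nb), m)
    theta, state, *_ = lmm._reml(
        y, np.ones((len(y), 1)), bull_idx, np.eye(nb), lmm._default_start(y)
    )
    assert theta[0] + theta[1] < 0.05 * theta[2]
    np.testing.assert_allclose(state["beta"][0], y.mean(), rtol=1e-3)


def test_gls_solution_matches_dense_solve(small_instance):
    ph, grm = small_instance["ph"], small_instance["grm"]
    vc = small_instance["base"].vc
    y, X, _, bidx, _ = lmm.build_design(ph, grm.sample_ids)
    V = dense_v_matrix(len(y), bidx, grm, vc)
    Vi = np.linalg.inv(V)
    expected = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    beta, _ = lmm.gls_coefficients(y, X, bidx, grm.matrix, vc)
    np.testing.assert_allclose(beta, expected, atol=1e-8)


def test_singular_design_names_collinear_columns(small_instance):
    ph = small_instance["ph"].copy()
    grm = small_instance["grm"]
    dup = pd.DataFrame(
        {"age_copy": ph.groupby("bull_id")["age_months"].mean()}
    )
    ph["age_months"] = ph["bull_id"].map(dup["age_copy"])  # per-bull age
    with pytest.raises(ValueError, match="collinear"):
        lmm.build_design(ph, grm.sample_ids, covariates=dup)


def test_record_for_unknown_bull_rejected(small_instance):
    ph = small_instance["ph"].copy()
    ph.loc[0, "bull_id"] = "ghost"
    with pytest.raises(ValueError, match="absent"):
        lmm.build_design(ph, small_instance["grm"].sample_ids)


# ---------------------------------------------------------------------------
# inbreeding-depression regression recovery

SCALED = dict(n_chrom=3, n_bulls=200, records_per_bull_range=(10, 10),
              b2_true=-5.0, locus_effects=())


def _fit_b2(seed):
    cfg = simdata.SimConfig(seed=seed, **SCALED)
    g, truth = simdata.simulate_genotypes(cfg)
    ph, truth = simdata.simulate_phenotypes(g, truth, cfg)
    grm = lmm.build_grm(g.subset_markers(g.maf() > 0.01))
    fit = lmm.fit_animal_model(ph, grm, covariates=truth.ibd_fraction.to_frame())
    return fit.coefficient("ibd_fraction")


def test_known_depression_effect_recovered():
    """True genome-wide effect of -5 per unit IBD recovered within 2 SE."""
    c = _fit_b2(seed=1)
    assert abs(c.estimate - (-5.0)) < 2 * c.se
    assert c.p < 0.05


def test_depression_estimator_unbiased_and_se_calibrated():
    """Across seeded replicates the estimator is unbiased (within twice the
    standard error of the replicate mean) and the reported SE matches the
    empirical spread within 30%."""
    results = [_fit_b2(seed) for seed in range(1, 21)]
    est = np.array([c.estimate for c in results])
    ses = np.array([c.se for c in results])
    bias = est.mean() - (-5.0)
    assert abs(bias) < 2 * est.std(ddof=1) / np.sqrt(len(est))
    assert abs(est.std(ddof=1) - ses.mean()) < 0.3 * ses.mean()


def test_model2_single_class_equals_model1_on_that_covariate(small_instance):
    ph, grm = small_instance["ph"], small_instance["grm"]
    q = len(grm.sample_ids)
    rng = np.random.default_rng(5)
    active = pd.Series(rng.random(q), index=grm.sample_ids)
    classes = pd.DataFrame(
        {col: (active if col == "f_roh_gt16" else np.zeros(q))
         for col in inbreeding.CLASS_F_COLUMNS},
        index=pd.Index(grm.sample_ids, name="sample_id"),
    )
    fit2 = lmm.fit_model2(ph, grm, classes)
    fit1 = lmm.fit_animal_model(ph, grm, covariates=classes[["f_roh_gt16"]])
    c2 = fit2.coefficient("f_roh_gt16")
    c1 = fit1.coefficient("f_roh_gt16")
    np.testing.assert_allclose(c2.estimate, c1.estimate, rtol=1e-6)
    # the four zero-variance classes are flagged NA, not dropped
    for col in inbreeding.CLASS_F_COLUMNS:
        if col != "f_roh_gt16":
            assert np.isnan(fit2.coefficient(col).estimate)


def test_model2_attributes_effect_to_long_roh_class(recent_only_fits):
    """With purely recent autozygosity, depression loads on the >16 Mb class:
    its coefficient is adverse and significant while the other estimable
    classes stay within 2 SE of zero."""
    fit2 = recent_only_fits["fit2"]
    long_cls = fit2.coefficient("f_roh_gt16")
    assert long_cls.estimate < 0 and long_cls.p < 0.05
    for col in ("f_roh_1_2", "f_roh_2_4", "f_roh_4_8", "f_roh_8_16"):
        c = fit2.coefficient(col)
        if not np.isnan(c.estimate):
            assert abs(c.estimate) < 2 * c.se


# ---------------------------------------------------------------------------
# heritability / repeatability

def test_heritability_repeatability_formulas():
    h2, r = lmm.heritability_repeatability(lmm.VarianceComponents(1, 1, 2))
    assert (h2, r) == (0.25, 0.5)
    h2, _ = lmm.heritability_repeatability(lmm.VarianceComponents(0, 3, 1))
    assert h2 == 0.0
    with pytest.raises(ValueError):
        lmm.heritability_repeatability(lmm.VarianceComponents(0, 0, 0))


def test_heritability_never_exceeds_repeatability(default_base_fit):
    h2, r = lmm.heritability_repeatability(default_base_fit.vc)
    assert 0 <= h2 <= r <= 1
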