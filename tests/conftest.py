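"""Shared fixtures: seeded synthetic scenarios and independent oracles.

The three study-scale scenarios (default, null, recent-only) are simulated
once per session and shared across module and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rohdepress import inbreeding, io, lmm, roh, scan, simdata


def brute_force_roh(pos: np.ndarray, het: np.ndarray, par: roh.ROHParams) -> list[tuple[int, int]]:
    """O(n^2) enumeration of containment-maximal constraint-satisfying intervals.

    Independent of the production caller: checks every SNP interval against
    the five ROH rules directly, then removes intervals contained in another
    satisfying interval.
    """
    n = len(pos)
    satisfying = []
    for i in range(n):
        for j in range(i + par.min_snps - 1, n):
            span = pos[j] - pos[i] + 1
            if span < par.min_length_bp:
                continue
            if het[i : j + 1].sum() > par.max_het:
                continue
            if span > par.max_density_bp_per_snp * (j - i + 1):
                continue
            if j > i and np.max(np.diff(pos[i : j + 1])) > par.max_gap_bp:
                continue
            satisfying.append((i, j))
    return [
        (i, j)
        for (i, j) in satisfying
        if not any(ii <= i and jj >= j and (ii, jj) != (i, j) for (ii, jj) in satisfying)
    ]


@pytest.fixture(scope="session")
def roh_oracle():
    return brute_force_roh


def random_roh_fixture(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, roh.ROHParams]:
    """A random single-chromosome genotype string plus ROH parameters,
    sized to exercise the gap, het, span, count and density rules."""
    n = int(rng.integers(10, 61))
    spacing = rng.choice([20_000, 60_000, 90_000, 110_000, 200_000, 550_000], size=n - 1)
    pos = np.concatenate([[100_000], 100_000 + np.cumsum(spacing)])
    het = rng.random(n) < rng.choice([0.05, 0.15, 0.4])
    par = roh.ROHParams(
        min_length_bp=int(rng.choice([500_000, 1_000_000, 2_000_000])),
        min_snps=int(rng.choice([4, 8, 15])),
        max_density_bp_per_snp=int(rng.choice([80_000, 100_000, 150_000])),
        max_het=int(rng.choice([0, 1, 2])),
        max_gap_bp=int(rng.choice([300_000, 500_000, 1_000_000])),
    )
    return pos.astype(np.int64), het, par


def genotypes_from_string(pos: np.ndarray, het: np.ndarray, chrom: int = 1,
                          sample: str = "s1") -> io.GenotypeMatrix:
    """One-sample genotype matrix with hom/het pattern ``het`` at ``pos``."""
    markers = pd.DataFrame(
        {
            "marker_id": [f"m{chrom}_{k}" for k in range(len(pos))],
            "chrom": chrom,
            "pos_bp": pos,
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    dosage = np.where(het, 1, 2).astype(np.int8)[np.newaxis, :]
    return io.GenotypeMatrix(samples=[sample], markers=markers, dosage=dosage)


# ---------------------------------------------------------------------------
# session-scale scenarios

@pytest.fixture(scope="session")
def default_sim():
    cfg = simdata.preset_config("default", seed=1)
    g, truth = simdata.simulate_genotypes(cfg)
    ph, truth = simdata.simulate_phenotypes(g, truth, cfg)
    return {"cfg": cfg, "g": g, "truth": truth, "ph": ph}


@pytest.fixture(scope="session")
def default_roh(default_sim):
    return roh.detect_roh(default_sim["g"])


@pytest.fixture(scope="session")
def default_inbreeding(default_sim, default_roh):
    return inbreeding.inbreeding_table(default_sim["g"], default_roh)


@pytest.fixture(scope="session")
def default_grm(default_sim):
    return lmm.build_grm(io.filter_markers_qc(default_sim["g"]))


@pytest.fixture(scope="session")
def default_base_fit(default_sim, default_grm):
    return lmm.fit_animal_model(default_sim["ph"], default_grm)


@pytest.fixture(scope="session")
def default_scan(default_sim, default_roh, default_grm, default_base_fit):
    g = default_sim["g"]
    states = scan.roh_state_matrix(default_roh, g.markers, g.samples)
    return scan.run_scan(default_sim["ph"], default_grm, g, states, default_base_fit)


@pytest.fixture(scope="session")
def null_scan():
    cfg = simdata.preset_config("null", seed=1)
    g, truth = simdata.simulate_genotypes(cfg)
    ph, truth = simdata.simulate_phenotypes(g, truth, cfg)
    segments = roh.detect_roh(g)
    grm = lmm.build_grm(io.filter_markers_qc(g))
    base = lmm.fit_animal_model(ph, grm)
    states = scan.roh_state_matrix(segments, g.markers, g.samples)
    return scan.run_scan(ph, grm, g, states, base)


@pytest.fixture(scope="session")
def recent_only_fits():
    cfg = simdata.preset_config("recent-only", seed=1)
    g, truth = simdata.simulate_genotypes(cfg)
    ph, truth = simdata.simulate_phenotypes(g, truth, cfg)
    segments = roh.detect_roh(g)
    table = inbreeding.inbreeding_table(g, segments)
    grm = lmm.build_grm(io.filter_markers_qc(g))
    fit2 = lmm.fit_model2(ph, grm, table[list(inbreeding.CLASS_F_COLUMNS)])
    return {"cfg": cfg, "table": table, "fit2": fit2}


@pytest.fixture(scope="session")
def small_instance():
    """A <=40-bull scenario small enough for dense-matrix oracle solves."""
    cfg = simdata.SimConfig(
        seed=3, n_bulls=35, n_chrom=2, chrom_length_mb=40,
        n_generations_ancient=8, n_founders=30, records_per_bull_range=(3, 8),
    )
    g, truth = simdata.simulate_genotypes(cfg)
    ph, truth = simdata.simulate_phenotypes(g, truth, cfg)
    segments = roh.detect_roh(g)
    grm = lmm.build_grm(g.subset_markers(g.maf() > 0.01))
    base = lmm.fit_animal_model(ph, grm)
    states = scan.roh_state_matrix(segments, g.markers, g.samples)
    return {"cfg": cfg, "g": g, "ph": ph, "grm": grm, "base": base, "states": states}


def dense_v_matrix(n: int, bull_idx: np.ndarray, grm: lmm.GRM,
                   vc: lmm.VarianceComponents) -> np.ndarray:
    q = len(grm.sample_ids)
    Z = np.zeros((n, q))
    Z[np.arange(n), bull_idx] = 1.0
    K = vc.sigma_a2 * grm.matrix + vc.sigma_pe2 * np.eye(q)
    return vc.sigma_e2 * np.eye(n) + Z @ K @ Z.T
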