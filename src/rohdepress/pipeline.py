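"""End-to-end orchestration: simulate/load -> QC -> ROH -> inbreeding ->
model fits -> scan -> regions, with a machine-readable run manifest.

A run is driven by a single :class:`RunConfig` (typically parsed from
YAML).  Exactly one genotype source is allowed: either a simulation
preset or input paths.  All stage outputs are plain TSV/YAML/JSON files
in the output directory and are byte-identical across reruns with the
same configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, inbreeding, io, lmm, roh, scan, simdata

logger = logging.getLogger("rohdepress")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


_QC_KEYS = {"maf_min", "hwe_p_min"}
_ROH_KEYS = {"min_length_bp", "min_snps", "max_density_bp_per_snp", "max_het", "max_gap_bp"}
_SCAN_KEYS = {"p_threshold", "merge_gap_bp", "candidate_thresholds"}
_SIM_KEYS = {"preset"} | {
    f.name for f in simdata.SimConfig.__dataclass_fields__.values()
    if f.name not in ("seed", "trait")  # both come from the top-level config
}
_INPUT_KEYS = {"plink_prefix", "phenotypes"}


@dataclass
class RunConfig:
    out_dir: str
    seed: int
    trait: str = "SC"
    simulate: dict | None = None
    input: dict | None = None
    qc: dict = field(default_factory=dict)
    roh: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    genes_bed: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input is None):
            raise ValueError("configure exactly one of 'simulate' and 'input'")
        for name, block, allowed in (
            ("simulate", self.simulate, _SIM_KEYS),
            ("input", self.input, _INPUT_KEYS),
            ("qc", self.qc, _QC_KEYS),
            ("roh", self.roh, _ROH_KEYS),
            ("scan", self.scan, _SCAN_KEYS),
        ):
            if block is None:
                continue
            unknown = set(block) - allowed
            if unknown:
                raise ValueError(f"unknown keys in '{name}' block: {sorted(unknown)}")
        if self.input is not None and set(self.input) != _INPUT_KEYS:
            raise ValueError("'input' block needs both 'plink_prefix' and 'phenotypes'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("run config must be a YAML mapping")
        unknown = set(raw) - {f_.name for f_ in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _fit_to_files(fit: lmm.FitResult, out: Path, stem: str) -> None:
    _write_tsv(fit.coefficients, out / f"{stem}_coefficients.tsv")
    h2, r = lmm.heritability_repeatability(fit.vc)
    meta = {
        "sigma_a2": float(fit.vc.sigma_a2),
        "sigma_pe2": float(fit.vc.sigma_pe2),
        "sigma_e2": float(fit.vc.sigma_e2),
        "heritability": float(h2),
        "repeatability": float(r),
        "loglik": float(fit.loglik),
        "converged": bool(fit.converged),
        "n_iterations": int(fit.n_iter),
        "n_records": int(fit.n_records),
        "n_bulls": int(fit.n_bulls),
    }
    (out / f"{stem}_fit.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage and return the populated output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    manifest: dict = {
        "package": "rohdepress",
        "version": __version__,
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": int(cfg.seed),
        "config": asdict(cfg),
        "inputs": {},
    }

    stage = "load"
    try:
        if cfg.simulate is not None:
            stage = "simulate"
            sim_kwargs = dict(cfg.simulate)
            preset = sim_kwargs.pop("preset", "default")
            sim_cfg = simdata.preset_config(preset, seed=cfg.seed, trait=cfg.trait,
                                            **sim_kwargs)
            g, truth = simdata.simulate_genotypes(sim_cfg)
            ph, truth = simdata.simulate_phenotypes(g, truth, sim_cfg)
            io.write_plink(g, out / "genotypes")
            io.write_phenotypes(ph, out / "phenotypes.tsv")
            _write_tsv(truth.ibd_fraction.to_frame(), out / "truth_ibd_fraction.tsv",
                       index=True)
            _write_tsv(truth.ibd_segments, out / "truth_ibd_segments.tsv")
        else:
            g = io.read_plink(cfg.input["plink_prefix"])
            ph = io.read_phenotypes(cfg.input["phenotypes"])
            for key, path in cfg.input.items():
                p = Path(path if key != "plink_prefix" else path + ".bed")
                manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(p)}

        stage = "phenotype_qc"
        ph = io.filter_phenotypes(ph)
        ph = ph.loc[ph["trait"] == cfg.trait].reset_index(drop=True)
        if ph.empty:
            raise ValueError(f"no records for trait {cfg.trait!r} after QC")

        stage = "marker_qc"
        g_qc = io.filter_markers_qc(g, **cfg.qc)
        grm = lmm.build_grm(g_qc)

        stage = "roh"
        params = roh.ROHParams(**cfg.roh)
        segments = roh.detect_roh(g, params)
        roh.write_roh_tsv(segments, out / "roh_segments.tsv")

        stage = "inbreeding"
        table = inbreeding.inbreeding_table(g, segments)
        _write_tsv(table.reset_index(), out / "inbreeding.tsv")

        stage = "fit_base"
        base_fit = lmm.fit_animal_model(ph, grm, trait=cfg.trait)
        _fit_to_files(base_fit, out, "base")

        stage = "fit_model1"
        for measure in ("f_roh", "f_snp"):
            fit = lmm.fit_animal_model(ph, grm, trait=cfg.trait,
                                       covariates=table[[measure]])
            _fit_to_files(fit, out, f"model1_{measure}")

        stage = "fit_model2"
        fit2 = lmm.fit_model2(ph, grm, table[list(inbreeding.CLASS_F_COLUMNS)],
                              trait=cfg.trait)
        _fit_to_files(fit2, out, "model2")

        stage = "scan"
        states = scan.roh_state_matrix(segments, g.markers, g.samples)
        result = scan.run_scan(ph, grm, g, states, base_fit, trait=cfg.trait)
        _write_tsv(result, out / "scan.tsv")
        ok = result["status"] == scan.STATUS_OK
        manhattan = result.loc[ok, ["chrom", "pos_bp"]].assign(
            neg_log10_p=-np.log10(result.loc[ok, "p_roh"])
        )
        _write_tsv(manhattan, out / "manhattan.tsv")
        candidates = cfg.scan.get(
            "candidate_thresholds", [1e-3, 1e-4, 1e-5, 1e-6]
        )
        try:
            best_p, best_fdr = scan.min_fdr_threshold(result, candidates)
            manifest["min_fdr"] = {"p_threshold": best_p, "fdr": best_fdr}
        except ValueError:
            manifest["min_fdr"] = None

        stage = "regions"
        gene_bed = io.read_gene_bed(cfg.genes_bed) if cfg.genes_bed else None
        regions = scan.call_regions(
            result,
            p_threshold=cfg.scan.get("p_threshold", 1e-4),
            merge_gap_bp=cfg.scan.get("merge_gap_bp", 1_000_000),
            gene_bed=gene_bed,
        )
        _write_tsv(regions, out / "regions.tsv")
    except Exception as exc:
        logger.error("pipeline stage %r failed: %s", stage, exc)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
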