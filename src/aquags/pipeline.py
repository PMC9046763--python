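"""Pipeline configuration and end-to-end orchestration.

Stages run in the fixed order qc -> grm -> [gwas] -> [fit | cv | density].
Every artifact directory gets a manifest recording input checksums, the
global seed and the package version, so a rerun with the same configuration
and seed reproduces all artifacts (bit-identically for the deterministic
stages, identically-given-seed for the stochastic ones). All randomness
flows from one global seed, deterministically offset per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .evaluate import density_experiment, make_folds, run_cv
from .grm import vanraden_grm
from .gwas import candidate_windows, lmm_gwas
from .io import (
    read_genotypes,
    read_gff3_genes,
    read_phenotypes,
    write_dosage_tsv,
    write_grm_tsv,
)
from .models import GibbsSettings, fit_bayes, fit_gblup
from .qc import run_qc

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "STAGE_SEED_OFFSETS"]

logger = logging.getLogger(__name__)

# per-stage deterministic offsets from the global seed (kept below 2**31)
STAGE_SEED_OFFSETS = {"simulate": 0, "fit": 1_000, "cv": 2_000, "density": 3_000}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Plain-text (YAML) serializable run configuration."""

    genotypes: str = ""
    phenotypes: str = ""
    annotation: str | None = None
    output_dir: str = "aquags_out"
    # QC
    min_ind_call_rate: float = 0.9
    min_snp_call_rate: float = 0.9
    min_maf: float = 0.05
    prune_r2: float | None = None
    prune_window: int = 50
    # models
    models: list[str] = field(default_factory=lambda: ["GBLUP"])
    traits: list[str] | None = None
    iterations: int = 50_000
    burn_in: int = 5_000
    thin: int = 5
    pi: float = 0.95
    # stages
    run_gwas: bool = False
    run_cv_stage: bool = False
    run_density: bool = False
    k_folds: int = 5
    n_repeats: int = 40
    density_strategy: str = "gwas_ranked"
    density_sizes: list[int] | None = None
    flank_bp: int = 100_000
    suggestive_neglog10: float = 4.0
    seed: int = 0
    log_level: str = "INFO"

    def validate(self, check_paths: bool = True) -> None:
        for name in ("min_ind_call_rate", "min_snp_call_rate"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigError(f"{name}={v} outside (0, 1]")
        if not (0.0 < self.min_maf <= 0.5):
            raise ConfigError(f"min_maf={self.min_maf} outside (0, 0.5]")
        if self.prune_r2 is not None and not (0.0 < self.prune_r2 <= 1.0):
            raise ConfigError(f"prune_r2={self.prune_r2} outside (0, 1]")
        if not (0.0 <= self.pi < 1.0):
            raise ConfigError(f"pi={self.pi} outside [0, 1)")
        if self.burn_in >= self.iterations:
            raise ConfigError("burn_in must be < iterations")
        if self.k_folds < 2:
            raise ConfigError("k_folds must be >= 2")
        if check_paths:
            for p in (self.genotypes, self.phenotypes, self.annotation):
                if p and not Path(p).exists():
                    raise ConfigError(f"path does not exist: {p}")

    # -------------------------------------------------------- serialization
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def gibbs_settings(self, seed_offset: int = 0) -> GibbsSettings:
        return GibbsSettings(
            iterations=self.iterations, burn_in=self.burn_in, thin=self.thin,
            pi=self.pi, seed=(self.seed + STAGE_SEED_OFFSETS["fit"] + seed_offset) % (2**31),
        )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out: Path, config: PipelineConfig, stage_status: dict) -> None:
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            name: _sha256(p)
            for name, p in {
                "genotypes": config.genotypes,
                "phenotypes": config.phenotypes,
                "annotation": config.annotation,
            }.items()
            if p and Path(p).exists()
        },
        "stages": stage_status,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_pipeline(config: PipelineConfig) -> int:
    """Execute the configured stages; returns 0 on success, 1 on stage failure.

    Partial artifacts are retained on failure and the manifest marks the
    failing stage.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    status: dict[str, str] = {}
    try:
        panel = read_genotypes(config.genotypes)
        pheno = read_phenotypes(config.phenotypes, panel=None)
        logger.info("inputs: %d individuals x %d SNPs, %d trait columns",
                    panel.n_individuals, panel.n_snps, pheno.shape[1])

        panel, qc_report = run_qc(
            panel,
            min_ind_call_rate=config.min_ind_call_rate,
            min_snp_call_rate=config.min_snp_call_rate,
            min_maf=config.min_maf,
            prune_r2=config.prune_r2,
            prune_window=config.prune_window,
        )
        (out / "qc_report.json").write_text(json.dumps(qc_report.to_dict(), indent=2))
        write_dosage_tsv(panel, out / "panel.qc")
        pheno = pheno.reindex(panel.individual_ids)
        status["qc"] = "ok"

        grm = vanraden_grm(panel)
        write_grm_tsv(grm, out / "grm.tsv")
        status["grm"] = "ok"

        traits = config.traits or [c for c in pheno.columns]
        for trait in traits:
            if trait not in pheno.columns:
                raise ConfigError(f"trait {trait!r} not in phenotype file")

        if config.run_gwas:
            genes = read_gff3_genes(config.annotation) if config.annotation else None
            for trait in traits:
                y = pheno[trait].to_numpy(dtype=float)
                res = lmm_gwas(y, panel, grm)
                res.table.assign(trait=trait).to_csv(
                    out / f"gwas_{trait}.tsv", sep="\t", index=False
                )
                (out / f"gwas_{trait}_thresholds.json").write_text(json.dumps({
                    "n_tests": res.n_tests,
                    "bonferroni_p": res.bonferroni_p,
                    "suggestive_p": res.suggestive_p,
                    "lambda_gc": res.lambda_gc,
                }, indent=2))
                if genes is not None:
                    hits = res.suggestive_hits()
                    windows = candidate_windows(hits, genes, flank_bp=config.flank_bp)
                    rows = [
                        {"snp": w.snp_id, "chrom": w.chromosome, "start": w.start,
                         "end": w.end, "gene_id": g["gene_id"], "gene_name": g["name"]}
                        for w in windows for g in (w.genes or [{"gene_id": "", "name": ""}])
                    ]
                    import pandas as pd
                    pd.DataFrame(rows).to_csv(out / f"candidates_{trait}.tsv", sep="\t", index=False)
            status["gwas"] = "ok"

        for t_idx, trait in enumerate(traits):
            y = pheno[trait].to_numpy(dtype=float)
            for model in config.models:
                if model.upper() == "GBLUP":
                    fit = fit_gblup(y, grm)
                else:
                    fit = fit_bayes(y, panel, model, config.gibbs_settings(seed_offset=t_idx))
                (out / f"fit_{model}_{trait}.json").write_text(json.dumps(fit.summary(), indent=2))
                import pandas as pd
                pd.DataFrame({"id": fit.train_ids, "gebv": fit.gebv}).to_csv(
                    out / f"gebv_{model}_{trait}.tsv", sep="\t", index=False
                )
        status["fit"] = "ok"

        if config.run_cv_stage or config.run_density:
            plan = make_folds(
                panel.n_individuals, config.k_folds, config.n_repeats,
                base_seed=(config.seed + STAGE_SEED_OFFSETS["cv"]) % (2**31),
            )
            import pandas as pd
            pd.DataFrame(plan.assignments).to_csv(out / "fold_plan.tsv", sep="\t", index=False)
            if config.run_cv_stage:
                for trait in traits:
                    y = pheno[trait].to_numpy(dtype=float)
                    report = run_cv(y, panel, config.models, plan,
                                    settings=config.gibbs_settings(), trait=trait, grm=grm)
                    report.cells.to_csv(out / f"cv_cells_{trait}.tsv", sep="\t", index=False)
                    report.summary.to_csv(out / f"cv_summary_{trait}.tsv", sep="\t", index=False)
                status["cv"] = "ok"
            if config.run_density:
                for trait in traits:
                    y = pheno[trait].to_numpy(dtype=float)
                    curve = density_experiment(
                        y, panel, plan, config.density_strategy,
                        sizes=config.density_sizes,
                        seed=(config.seed + STAGE_SEED_OFFSETS["density"]) % (2**31),
                        trait=trait,
                    )
                    curve.to_frame().to_csv(out / f"density_{trait}.tsv", sep="\t", index=False)
                status["density"] = "ok"
    except Exception as exc:  # noqa: BLE001 - report failing stage in manifest
        status["failed"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(out, config, status)
        logger.error("pipeline failed: %s", exc)
        return 1
    _write_manifest(out, config, status)
    return 0
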