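"""Synthetic genotype/phenotype generator for a closed aquaculture breeding cohort.

The generator emulates the statistical structure the downstream analyses
assume: a few hundred individuals genotyped at biallelic SNPs spread over
pseudo-chromosomes, and several strongly correlated, moderately heritable
polygenic growth traits (body weight, total length, body depth). Defaults
mirror a rock bream breeding population of 455 fish with ~16 K QC-filtered
SNPs, heritabilities 0.38 / 0.33 / 0.24 and phenotypic correlations in the
0.76-0.88 range.

The additive model is generative: per-allele substitution effects are drawn
at a random subset of QTL, breeding values are ``g = Z_c alpha`` on centered
dosages, and environmental deviations are scaled so that Var(g)/Var(y) hits
each target heritability in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .panel import GenotypePanel

__all__ = ["SimConfig", "SimTruth", "SimConfigError", "simulate_genotypes", "simulate_phenotypes"]

# Study-scale defaults: trait means/SDs on the gram/cm scale of the three
# growth traits (body weight, total length, body depth).
DEFAULT_TRAIT_NAMES = ("BW", "TL", "BD")
DEFAULT_TRAIT_MEANS = (130.71, 18.12, 7.07)
DEFAULT_TRAIT_SDS = (32.88, 1.41, 0.59)
DEFAULT_H2 = (0.38, 0.33, 0.24)
DEFAULT_GENETIC_CORR = (
    (1.00, 0.88, 0.79),
    (0.88, 1.00, 0.76),
    (0.79, 0.76, 1.00),
)
DEFAULT_PHENOTYPIC_CORR = (
    (1.00, 0.88, 0.85),
    (0.88, 1.00, 0.81),
    (0.85, 0.81, 1.00),
)


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


def _as_corr(mat, k: int, name: str) -> np.ndarray:
    c = np.asarray(mat, dtype=float)
    if c.shape != (k, k):
        raise SimConfigError(f"{name} must be {k}x{k}, got {c.shape}")
    if not np.allclose(c, c.T, atol=1e-10):
        raise SimConfigError(f"{name} must be symmetric")
    if not np.allclose(np.diag(c), 1.0, atol=1e-10):
        raise SimConfigError(f"{name} must have unit diagonal")
    if np.linalg.eigvalsh(c).min() < -1e-8:
        raise SimConfigError(f"{name} is not positive semidefinite")
    return c


@dataclass
class SimConfig:
    """Parameters of the synthetic population.

    ``heritabilities`` are narrow-sense targets per trait;
    ``genetic_correlation`` shapes the QTL-effect covariance across traits;
    ``phenotypic_correlation_target``, when given, sets the environmental
    cross-trait covariance needed to approach it (must stay feasible).
    """

    n_individuals: int = 455
    n_snps: int = 16162
    n_chromosomes: int = 24
    chrom_length_bp: int = 25_000_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int | None = None  # default: n_snps // 4 (polygenic)
    heritabilities: Sequence[float] = DEFAULT_H2
    genetic_correlation: Sequence[Sequence[float]] | None = None
    phenotypic_correlation_target: Sequence[Sequence[float]] | None = None
    trait_names: Sequence[str] = DEFAULT_TRAIT_NAMES
    trait_means: Sequence[float] = DEFAULT_TRAIT_MEANS
    trait_sds: Sequence[float] = DEFAULT_TRAIT_SDS
    missing_rate: float = 0.0
    ld_blocks: bool = False
    ld_r: float = 0.9  # per-SNP copying probability when ld_blocks is on
    seed: int = 0

    n_traits: int = field(init=False)

    def __post_init__(self) -> None:
        self.heritabilities = np.asarray(self.heritabilities, dtype=float)
        self.n_traits = self.heritabilities.size
        if self.n_qtl is None:
            self.n_qtl = max(1, self.n_snps // 4)
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimConfigError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if self.n_individuals < 1 or self.n_snps < 1 or self.n_chromosomes < 1:
            raise SimConfigError("counts must be positive")
        if np.any(self.heritabilities < 0) or np.any(self.heritabilities > 1):
            raise SimConfigError("heritabilities must lie in [0, 1]")
        if self.n_qtl < 1 and np.any(self.heritabilities > 0):
            raise SimConfigError("n_qtl must be >= 1 when any heritability > 0")
        if self.n_qtl > self.n_snps:
            raise SimConfigError("n_qtl cannot exceed n_snps")
        if not (0.0 <= self.missing_rate < 1.0):
            raise SimConfigError("missing_rate must be in [0, 1)")
        k = self.n_traits
        if self.genetic_correlation is None:
            self.genetic_correlation = np.asarray(DEFAULT_GENETIC_CORR)[:k, :k] if k <= 3 else np.eye(k)
        self.genetic_correlation = _as_corr(self.genetic_correlation, k, "genetic_correlation")
        if self.phenotypic_correlation_target is None and k <= 3 and tuple(self.trait_names) == DEFAULT_TRAIT_NAMES[:k]:
            self.phenotypic_correlation_target = np.asarray(DEFAULT_PHENOTYPIC_CORR)[:k, :k]
        if self.phenotypic_correlation_target is not None:
            self.phenotypic_correlation_target = _as_corr(
                self.phenotypic_correlation_target, k, "phenotypic_correlation_target"
            )
        if len(self.trait_names) != k or len(self.trait_means) != k or len(self.trait_sds) != k:
            raise SimConfigError("trait_names/means/sds must match number of heritabilities")


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort, for parameter-recovery tests."""

    true_effects: np.ndarray  # (n_snps, n_traits); zero rows off-QTL
    true_breeding_values: np.ndarray  # (n_individuals, n_traits)
    realized_h2: np.ndarray  # per trait
    qtl_indices: np.ndarray


def _genome_map(cfg: SimConfig, rng: np.random.Generator):
    """Assign SNPs to near-equal chromosome blocks with sorted unique positions."""
    counts = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    counts[: cfg.n_snps % cfg.n_chromosomes] += 1
    chroms, positions = [], []
    for c, k in enumerate(counts, start=1):
        pos = np.sort(rng.choice(np.arange(1, cfg.chrom_length_bp + 1), size=k, replace=False))
        chroms.extend([f"chr{c}"] * k)
        positions.append(pos)
    return np.asarray(chroms, dtype=object), np.concatenate(positions) if positions else np.empty(0, int)


def simulate_genotypes(cfg: SimConfig) -> GenotypePanel:
    """Draw a dosage panel: per-SNP allele frequency uniform on ``maf_range``,
    genotypes binomial(2, p) under Hardy-Weinberg equilibrium.

    With ``ld_blocks`` each of the two haplotypes copies its previous-SNP
    allele state with probability ``ld_r`` (within a chromosome), producing
    decaying linkage disequilibrium; default is linkage equilibrium.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_individuals, cfg.n_snps
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    chroms, positions = _genome_map(cfg, rng)

    if not cfg.ld_blocks:
        dosages = rng.binomial(2, p[None, :], size=(n, m)).astype(float)
    else:
        hap = np.zeros((2, n, m), dtype=np.int8)
        new_chrom = np.r_[True, chroms[1:] != chroms[:-1]]
        for j in range(m):
            fresh = rng.random((2, n)) < p[j]
            if new_chrom[j]:
                hap[:, :, j] = fresh
            else:
                copy = rng.random((2, n)) < cfg.ld_r
                hap[:, :, j] = np.where(copy, hap[:, :, j - 1], fresh)
        dosages = hap.sum(axis=0).astype(float)

    if cfg.missing_rate > 0:
        dosages[rng.random((n, m)) < cfg.missing_rate] = np.nan

    return GenotypePanel(
        dosages=dosages,
        individual_ids=[f"ind{i:04d}" for i in range(1, n + 1)],
        snp_ids=[f"snp{j:06d}" for j in range(1, m + 1)],
        chromosomes=chroms,
        positions_bp=positions,
    )


def simulate_phenotypes(
    panel: GenotypePanel, cfg: SimConfig
) -> tuple[np.ndarray, SimTruth]:
    """Generate correlated polygenic traits on the panel.

    QTL effects are multivariate normal across traits with correlation
    ``genetic_correlation``; per trait the effect vector is rescaled so the
    realized genetic variance equals ``h2 * trait_sd**2`` exactly.
    Environmental deviations are multivariate normal with variances
    ``(1 - h2) * trait_sd**2``; their cross-trait covariance is solved from
    ``phenotypic_correlation_target`` when provided (independent otherwise).

    Returns the ``(n, n_traits)`` phenotype matrix and a :class:`SimTruth`.
    """
    if panel.missing_mask.any():
        raise SimConfigError("panel has missing genotypes; impute before simulating phenotypes")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))
    n, m = panel.n_individuals, panel.n_snps
    k = cfg.n_traits
    var_p = np.asarray(cfg.trait_sds, dtype=float) ** 2
    h2 = cfg.heritabilities

    qtl = np.sort(rng.choice(m, size=cfg.n_qtl, replace=False))
    chol = np.linalg.cholesky(cfg.genetic_correlation + 1e-10 * np.eye(k))
    raw = rng.standard_normal((cfg.n_qtl, k)) @ chol.T

    Zc = panel.dosages - panel.dosages.mean(axis=0)
    g = np.zeros((n, k))
    effects = np.zeros((m, k))
    for t in range(k):
        target_vg = h2[t] * var_p[t]
        if target_vg == 0.0:
            continue
        g_raw = Zc[:, qtl] @ raw[:, t]
        v = g_raw.var()
        if v <= 0:
            raise SimConfigError("degenerate genetic variance (no polymorphic QTL?)")
        scale = np.sqrt(target_vg / v)
        effects[qtl, t] = raw[:, t] * scale
        g[:, t] = g_raw * scale

    # environmental covariance solved against the realized genetic covariance
    env_cov = np.diag((1.0 - h2) * var_p)
    if cfg.phenotypic_correlation_target is not None and k > 1:
        gcov = np.cov(g, rowvar=False) if k > 1 else np.atleast_2d(g.var())
        for s in range(k):
            for t in range(s + 1, k):
                target = cfg.phenotypic_correlation_target[s, t] * np.sqrt(var_p[s] * var_p[t])
                env_cov[s, t] = env_cov[t, s] = target - gcov[s, t]
        eig = np.linalg.eigvalsh(env_cov)
        if eig.min() < -1e-8:
            names = list(cfg.trait_names)
            # name the most offending pair for the error message
            off = np.abs(env_cov - np.diag(np.diag(env_cov)))
            s, t = np.unravel_index(np.argmax(off), off.shape)
            raise SimConfigError(
                "phenotypic_correlation_target infeasible given genetic correlation "
                f"and heritabilities (implied environmental covariance not PSD; "
                f"offending pair {names[s]}/{names[t]})"
            )

    # draw environmental deviations (exact zero when h2 == 1 everywhere)
    if np.allclose(env_cov, 0.0):
        e = np.zeros((n, k))
    else:
        L = np.linalg.cholesky(env_cov + 1e-12 * np.eye(k))
        e = rng.standard_normal((n, k)) @ L.T

    y = np.asarray(cfg.trait_means, dtype=float)[None, :] + g + e
    var_y = y.var(axis=0)
    realized = np.where(var_y > 0, g.var(axis=0) / np.where(var_y > 0, var_y, 1.0), 0.0)
    truth = SimTruth(
        true_effects=effects,
        true_breeding_values=g,
        realized_h2=np.clip(realized, 0.0, 1.0),
        qtl_indices=qtl,
    )
    return y, truth
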