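"""Genotype quality control: call-rate filters, MAF filter, mean-dosage
imputation and windowed r-squared tag-SNP pruning.

Thresholds use >=/keep semantics throughout: an individual or SNP is kept
when its statistic meets the threshold (call rate >= min, MAF >= min), and a
SNP is pruned only when r^2 with a retained window SNP strictly exceeds the
pruning threshold. MAF is computed from non-missing calls only.

The pipeline order is fixed: individuals -> SNP call rate/MAF -> impute ->
prune.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .panel import GenotypePanel

__all__ = [
    "QcError",
    "EmptyPanelError",
    "QcReport",
    "filter_individuals",
    "filter_snps",
    "impute_missing",
    "prune_tag_snps",
    "run_qc",
]

logger = logging.getLogger(__name__)


class QcError(ValueError):
    pass


class EmptyPanelError(QcError):
    """A filter removed every individual or every SNP."""


@dataclass
class QcReport:
    n_individuals_removed: int = 0
    n_snps_removed_callrate: int = 0
    n_snps_removed_maf: int = 0
    n_snps_removed_prune: int = 0
    thresholds: dict = field(default_factory=dict)

    def merged(self, other: "QcReport") -> "QcReport":
        return QcReport(
            n_individuals_removed=self.n_individuals_removed + other.n_individuals_removed,
            n_snps_removed_callrate=self.n_snps_removed_callrate + other.n_snps_removed_callrate,
            n_snps_removed_maf=self.n_snps_removed_maf + other.n_snps_removed_maf,
            n_snps_removed_prune=self.n_snps_removed_prune + other.n_snps_removed_prune,
            thresholds={**self.thresholds, **other.thresholds},
        )

    def to_dict(self) -> dict:
        return asdict(self)


def filter_individuals(panel: GenotypePanel, min_call_rate: float = 0.9):
    """Drop individuals whose non-missing fraction falls below ``min_call_rate``."""
    if not (0.0 < min_call_rate <= 1.0):
        raise QcError("min_call_rate must be in (0, 1]")
    keep = panel.individual_call_rates() >= min_call_rate
    if not keep.any():
        raise EmptyPanelError("individual call-rate filter removed all individuals")
    out = panel.subset(individuals=np.flatnonzero(keep))
    report = QcReport(
        n_individuals_removed=int((~keep).sum()),
        thresholds={"min_individual_call_rate": min_call_rate},
    )
    logger.info("individual filter: %d -> %d", panel.n_individuals, out.n_individuals)
    return out, report


def filter_snps(panel: GenotypePanel, min_call_rate: float = 0.9, min_maf: float = 0.05):
    """Drop SNPs with call rate < ``min_call_rate`` or MAF < ``min_maf``.

    MAF is computed on non-missing dosages; boundary values are kept
    (keep-if >= semantics). Map order of survivors is preserved.
    """
    if not (0.0 < min_call_rate <= 1.0) or not (0.0 < min_maf <= 1.0):
        raise QcError("thresholds must be in (0, 1]")
    cr_ok = panel.snp_call_rates() >= min_call_rate
    with np.errstate(invalid="ignore"):
        maf = panel.maf()
    maf_ok = np.nan_to_num(maf, nan=0.0) >= min_maf
    keep = cr_ok & maf_ok
    if not keep.any():
        raise EmptyPanelError("SNP filters removed all SNPs")
    out = panel.subset(snps=np.flatnonzero(keep))
    report = QcReport(
        n_snps_removed_callrate=int((~cr_ok).sum()),
        n_snps_removed_maf=int((cr_ok & ~maf_ok).sum()),
        thresholds={"min_snp_call_rate": min_call_rate, "min_maf": min_maf},
    )
    logger.info("SNP filter: %d -> %d", panel.n_snps, out.n_snps)
    return out, report


def impute_missing(panel: GenotypePanel) -> GenotypePanel:
    """Replace missing dosages by the SNP's mean observed dosage.

    Mean imputation preserves each SNP's allele frequency; downstream code
    accepts the resulting real-valued dosages.
    """
    miss = panel.missing_mask
    if not miss.any():
        return panel
    all_missing = miss.all(axis=0)
    if all_missing.any():
        bad = [panel.snp_ids[j] for j in np.flatnonzero(all_missing)[:5]]
        raise QcError(f"SNP(s) with all calls missing cannot be imputed: {bad}")
    dosages = panel.dosages.copy()
    col_means = np.nanmean(dosages, axis=0)
    rows, cols = np.nonzero(miss)
    dosages[rows, cols] = col_means[cols]
    return panel.with_dosages(dosages)


def prune_tag_snps(panel: GenotypePanel, r2_threshold: float = 0.8, window_snps: int = 50):
    """Greedy left-to-right tag-SNP selection within each chromosome.

    A SNP is dropped when its squared Pearson correlation of dosages with any
    *retained* SNP inside the trailing window exceeds ``r2_threshold``. The
    panel must be imputed (no missing calls).
    """
    if panel.missing_mask.any():
        raise QcError("prune_tag_snps requires an imputed panel (no missing calls)")
    if not (0.0 < r2_threshold <= 1.0):
        raise QcError("r2_threshold must be in (0, 1]")
    if window_snps < 2:
        raise QcError("window_snps must be >= 2")

    X = panel.dosages - panel.dosages.mean(axis=0)
    norm = np.sqrt((X**2).sum(axis=0))
    keep = np.zeros(panel.n_snps, dtype=bool)
    for chrom in dict.fromkeys(panel.chromosomes):
        idx = np.flatnonzero(panel.chromosomes == chrom)
        kept: list[int] = []
        for j in idx:
            window = kept[-(window_snps - 1):]
            drop = False
            for i in window:
                denom = norm[i] * norm[j]
                if denom == 0.0:
                    r2 = 1.0 if norm[i] == norm[j] else 0.0  # constant columns
                else:
                    r = float(X[:, i] @ X[:, j]) / denom
                    r2 = r * r
                if r2 > r2_threshold:
                    drop = True
                    break
            if not drop:
                kept.append(j)
                keep[j] = True
    if not keep.any():
        raise EmptyPanelError("pruning removed all SNPs")
    out = panel.subset(snps=np.flatnonzero(keep))
    report = QcReport(
        n_snps_removed_prune=int((~keep).sum()),
        thresholds={"prune_r2": r2_threshold, "prune_window_snps": window_snps},
    )
    logger.info("prune: %d -> %d", panel.n_snps, out.n_snps)
    return out, report


def run_qc(
    panel: GenotypePanel,
    min_ind_call_rate: float = 0.9,
    min_snp_call_rate: float = 0.9,
    min_maf: float = 0.05,
    prune_r2: float | None = None,
    prune_window: int = 50,
):
    """Fixed-order QC pipeline: individuals -> SNPs -> impute -> (optional) prune."""
    panel, rep1 = filter_individuals(panel, min_ind_call_rate)
    panel, rep2 = filter_snps(panel, min_snp_call_rate, min_maf)
    panel = impute_missing(panel)
    report = rep1.merged(rep2)
    if prune_r2 is not None:
        panel, rep3 = prune_tag_snps(panel, prune_r2, prune_window)
        report = report.merged(rep3)
    return panel, report
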