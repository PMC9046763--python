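"""Genotype panel container: an individuals x SNPs dosage matrix plus a genome map.

Dosages count copies of the alternate allele (0, 1, 2); missing calls are
``numpy.nan``. Downstream steps (mean imputation, centering) may produce
real-valued dosages, which the container accepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["GenotypePanel", "PanelError"]


class PanelError(ValueError):
    """Raised when a panel violates its structural invariants."""


@dataclass
class GenotypePanel:
    """Dosage matrix with per-SNP genome coordinates.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_snps)`` float array over ``{0, 1, 2, nan}`` (or
        real values after imputation).
    individual_ids, snp_ids
        Unique string identifiers, row- and column-aligned with ``dosages``.
    chromosomes
        Chromosome name per SNP.
    positions_bp
        1-based physical position per SNP; strictly increasing within each
        chromosome block.
    """

    dosages: np.ndarray
    individual_ids: list[str]
    snp_ids: list[str]
    chromosomes: np.ndarray
    positions_bp: np.ndarray
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        if not self._validated:
            self.validate()
            self._validated = True

    # ------------------------------------------------------------------ shape
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def validate(self) -> None:
        n, m = self.dosages.shape
        if len(self.individual_ids) != n:
            raise PanelError(
                f"{len(self.individual_ids)} individual ids for {n} rows"
            )
        if len(self.snp_ids) != m or len(self.chromosomes) != m or len(self.positions_bp) != m:
            raise PanelError("SNP metadata length does not match dosage columns")
        if len(set(self.individual_ids)) != n:
            raise PanelError("duplicate individual ids")
        if len(set(self.snp_ids)) != m:
            raise PanelError("duplicate SNP ids")
        if self.positions_bp.size and self.positions_bp.min() < 1:
            raise PanelError("positions must be 1-based (>= 1)")
        # positions strictly increasing within each chromosome block
        for chrom in dict.fromkeys(self.chromosomes):
            pos = self.positions_bp[self.chromosomes == chrom]
            if np.any(np.diff(pos) <= 0):
                raise PanelError(f"positions not strictly increasing on {chrom}")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise PanelError("dosages outside [0, 2]")

    # --------------------------------------------------------------- summaries
    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.dosages)

    def individual_call_rates(self) -> np.ndarray:
        return 1.0 - self.missing_mask.mean(axis=1)

    def snp_call_rates(self) -> np.ndarray:
        return 1.0 - self.missing_mask.mean(axis=0)

    def allele_freqs(self) -> np.ndarray:
        """Alternate-allele frequency per SNP from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freqs()
        return np.minimum(p, 1.0 - p)

    # ----------------------------------------------------------------- subsets
    def subset(
        self,
        individuals: Sequence[int] | np.ndarray | None = None,
        snps: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypePanel":
        """Positional subset; preserves order of the given indices."""
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        snp = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        return GenotypePanel(
            dosages=self.dosages[np.ix_(ind, snp)].copy(),
            individual_ids=[self.individual_ids[i] for i in ind],
            snp_ids=[self.snp_ids[j] for j in snp],
            chromosomes=self.chromosomes[snp].copy(),
            positions_bp=self.positions_bp[snp].copy(),
            _validated=True,
        )

    def with_dosages(self, dosages: np.ndarray) -> "GenotypePanel":
        """Same map/ids, new dosage matrix (e.g. after imputation)."""
        if dosages.shape != self.dosages.shape:
            raise PanelError("replacement dosage shape mismatch")
        return replace(self, dosages=np.asarray(dosages, dtype=float), _validated=True)
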