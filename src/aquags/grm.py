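"""VanRaden genomic relationship matrix (method 1).

G = Z Z' / (2 * sum_j p_j (1 - p_j)) with Z the dosage matrix column-centered
by twice the observed alternate-allele frequency. Frequencies are taken from
the panel itself (no base-population frequencies are assumed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import GenotypePanel

__all__ = ["GRM", "GrmError", "vanraden_grm"]


class GrmError(ValueError):
    pass


@dataclass
class GRM:
    """Realized additive relationship matrix."""

    values: np.ndarray  # (n, n) symmetric
    individual_ids: list[str]
    denominator: float  # 2 * sum p_j (1 - p_j)
    allele_freqs: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise GrmError("GRM must be square")
        if len(self.individual_ids) != n:
            raise GrmError("individual_ids length mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise GrmError("GRM must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, indices: np.ndarray) -> "GRM":
        idx = np.asarray(indices)
        return GRM(
            values=self.values[np.ix_(idx, idx)].copy(),
            individual_ids=[self.individual_ids[i] for i in idx],
            denominator=self.denominator,
            allele_freqs=self.allele_freqs,
        )


def vanraden_grm(panel: GenotypePanel, allow_monomorphic: bool = False) -> GRM:
    """Build G from an imputed, polymorphic panel.

    Raises :class:`GrmError` when the panel still has missing calls or
    contains monomorphic SNPs (run QC first), or when the denominator
    degenerates to zero. ``allow_monomorphic=True`` instead lets fixed SNPs
    drop out naturally (zero centered column, zero denominator share) — used
    internally when subsetting individuals re-fixes a few alleles.
    """
    if panel.missing_mask.any():
        raise GrmError("panel has missing genotypes; impute before building the GRM")
    p = panel.allele_freqs()
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any() and not allow_monomorphic:
        bad = [panel.snp_ids[j] for j in np.flatnonzero(mono)[:5]]
        raise GrmError(f"monomorphic SNP(s) present (run QC first): {bad}")
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise GrmError("zero VanRaden denominator")
    Z = panel.dosages - 2.0 * p[None, :]
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)  # symmetrize numerical noise
    return GRM(values=G, individual_ids=list(panel.individual_ids), denominator=denom, allele_freqs=p)
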