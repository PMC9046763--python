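"""Mixed-model genome-wide association: structure PCA, EMMAX-style
single-SNP Wald tests against a genomic relationship matrix, significance
thresholds, per-SNP variance explained, and candidate-window gene lookup.

The association model per SNP j is

    y = W a + x_j b_j + u + eps,   u ~ N(0, Vg G), eps ~ N(0, Ve I).

The variance ratio Vg/Ve is estimated once under the null (no SNP) by REML
on the eigendecomposition of G and then held fixed for every SNP
(EMMAX-style approximation); ``exact_ratio=True`` re-optimizes it per SNP.
beta and its standard error come from generalized least squares in the
rotated (whitened) space; the Wald statistic (beta/se)^2 is referred to
chi-square with 1 df.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .grm import GRM
from .models.gblup import RATIO_BOUNDS, reml_profile
from .panel import GenotypePanel

__all__ = [
    "GwasResult",
    "CandidateWindow",
    "GwasError",
    "genotype_pca",
    "lmm_gwas",
    "significance_thresholds",
    "snp_pve",
    "candidate_windows",
]

logger = logging.getLogger(__name__)

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549...


class GwasError(ValueError):
    pass


@dataclass
class GwasResult:
    """Per-SNP association results in genome order plus global summaries."""

    table: pd.DataFrame  # snp, chrom, pos, beta, se, p, neglog10p, zero_var flag
    n_tests: int
    bonferroni_p: float
    suggestive_p: float
    lambda_gc: float
    ratio: float = np.nan  # null-model Vg/Ve

    def __post_init__(self) -> None:
        if self.n_tests != len(self.table):
            raise GwasError("n_tests must equal the number of table rows")

    def ranked_indices(self) -> np.ndarray:
        """Panel-column order by ascending p; ties broken by genome order."""
        return np.lexsort((np.arange(self.n_tests), self.table["p"].to_numpy()))

    def suggestive_hits(self) -> pd.DataFrame:
        hits = self.table[self.table["p"] < self.suggestive_p]
        return hits.sort_values("p", kind="stable")


@dataclass
class CandidateWindow:
    snp_id: str
    chromosome: str
    start: int
    end: int
    genes: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise GwasError("window start must be >= 1")
        if self.end < self.start:
            raise GwasError("window end precedes start")


# --------------------------------------------------------------------- PCA
def genotype_pca(panel: GenotypePanel, k: int = 3):
    """Principal components of the column-standardized dosage matrix.

    Returns ``(scores, explained)`` where ``scores`` is n x k (columns
    orthogonal) and ``explained`` the fraction of total variance per
    component, non-increasing.
    """
    if panel.missing_mask.any():
        raise GwasError("PCA requires an imputed panel")
    X = panel.dosages - panel.dosages.mean(axis=0)
    sd = X.std(axis=0)
    poly = sd > 0
    X = X[:, poly] / sd[poly]
    rank = min(X.shape)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    nonzero = int((s > s[0] * 1e-12).sum()) if s.size else 0
    # the column-centered matrix loses one rank
    effective = min(nonzero, X.shape[0] - 1)
    if k > effective:
        raise GwasError(f"k={k} exceeds matrix rank {effective}")
    scores = U[:, :k] * s[:k]
    explained = (s[:k] ** 2) / float((s**2).sum())
    return scores, explained


# --------------------------------------------------------------- LMM / GWAS
def _null_ratio(y, d, U, W):
    yt = U.T @ y
    Wt = U.T @ W
    lo, hi = np.log(RATIO_BOUNDS[0]), np.log(RATIO_BOUNDS[1])
    res = minimize_scalar(
        reml_profile, bounds=(lo, hi), args=(d, yt, Wt), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.exp(res.x))


def lmm_gwas(
    y: np.ndarray,
    panel: GenotypePanel,
    grm: GRM,
    covariates: np.ndarray | None = None,
    exact_ratio: bool = False,
) -> GwasResult:
    """Univariate mixed-model association scan with Wald tests.

    ``exact_ratio`` switches from the single null-model variance ratio
    (default, EMMAX-style) to a per-SNP REML ratio re-optimization.
    """
    y = np.asarray(y, dtype=float).ravel()
    n, m = panel.n_individuals, panel.n_snps
    if y.size != n or grm.n != n:
        raise GwasError("phenotype, panel and GRM dimensions are inconsistent")
    if panel.missing_mask.any():
        raise GwasError("GWAS requires an imputed panel")

    W = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        W = np.hstack([W, C])
    p_fixed = W.shape[1]

    d, U = np.linalg.eigh(grm.values)
    d = np.clip(d, 0.0, None)
    lam = _null_ratio(y, d, U, W)

    yt = U.T @ y
    Wt = U.T @ W
    Xt = U.T @ panel.dosages

    def _scan(lam_j, cols):
        sw = 1.0 / np.sqrt(lam_j * d + 1.0)
        yw = yt * sw
        Ww = Wt * sw[:, None]
        Xw = Xt[:, cols] * sw[:, None]
        WtW = Ww.T @ Ww
        coef_y = np.linalg.solve(WtW, Ww.T @ yw)
        yr = yw - Ww @ coef_y
        coef_x = np.linalg.solve(WtW, Ww.T @ Xw)
        Xr = Xw - Ww @ coef_x
        xx = (Xr**2).sum(axis=0)
        xy = Xr.T @ yr
        yy = float(yr @ yr)
        return xx, xy, yy

    if not exact_ratio:
        xx, xy, yy = _scan(lam, slice(None))
    else:
        xx = np.empty(m)
        xy = np.empty(m)
        yy_arr = np.empty(m)
        for j in range(m):
            x_full = np.hstack([W, panel.dosages[:, j:j + 1]])
            lam_j = _null_ratio(y, d, U, x_full)
            a, b, c = _scan(lam_j, [j])
            xx[j], xy[j], yy_arr[j] = a[0], b[0], c
        yy = yy_arr  # per-SNP

    df_resid = n - p_fixed - 1
    zero_var = xx <= max(1e-12, 1e-12 * float(np.max(xx, initial=1.0)))
    xx_safe = np.where(zero_var, 1.0, xx)
    beta = xy / xx_safe
    rss = yy - beta * xy
    rss = np.clip(rss, 0.0, None)
    sigma2 = rss / df_resid
    se = np.sqrt(np.where(sigma2 > 0, sigma2, np.inf) / xx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = (beta / se) ** 2
    chi2 = np.where(zero_var, 0.0, np.nan_to_num(chi2, nan=0.0, posinf=np.inf))
    p = stats.chi2.sf(chi2, 1)
    p = np.where(zero_var, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    beta = np.where(zero_var, 0.0, beta)
    se = np.where(zero_var, np.nan, se)
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} SNP(s) with zero variance after rotation; p set to 1")

    lambda_gc = float(np.median(chi2) / CHI2_1_MEDIAN)
    bonf, sugg = significance_thresholds(m)
    table = pd.DataFrame(
        {
            "snp": panel.snp_ids,
            "chrom": panel.chromosomes,
            "pos": panel.positions_bp,
            "beta": beta,
            "se": se,
            "p": p,
            "neglog10p": -np.log10(p),
            "zero_var": zero_var,
        }
    )
    logger.info("GWAS: %d SNPs, lambda_gc=%.3f, null Vg/Ve=%.4g", m, lambda_gc, lam)
    return GwasResult(
        table=table, n_tests=m, bonferroni_p=bonf, suggestive_p=sugg,
        lambda_gc=lambda_gc, ratio=lam,
    )


def significance_thresholds(
    n_tests: int, alpha: float = 0.05, suggestive_neglog10: float = 4.0
) -> tuple[float, float]:
    """Bonferroni genome-wide threshold alpha/n_tests and the suggestive
    threshold 10**(-suggestive_neglog10)."""
    if n_tests < 1:
        raise GwasError("n_tests must be >= 1")
    return alpha / n_tests, 10.0 ** (-suggestive_neglog10)


def snp_pve(beta: float, maf: float, var_y: float) -> float:
    """Phenotypic variance explained by one SNP: 2 p (1-p) beta^2 / var(y),
    clipped to [0, 1]."""
    if not (0.0 < maf <= 0.5):
        raise GwasError("maf must be in (0, 0.5]")
    if var_y <= 0:
        raise GwasError("var_y must be positive")
    return float(np.clip(2.0 * maf * (1.0 - maf) * beta**2 / var_y, 0.0, 1.0))


# ----------------------------------------------------------- gene windows
def candidate_windows(
    hits: pd.DataFrame,
    genes: pd.DataFrame,
    flank_bp: int = 100_000,
    chrom_lengths: dict[str, int] | None = None,
) -> list[CandidateWindow]:
    """Scan +/- ``flank_bp`` around each hit SNP for overlapping genes.

    ``hits`` needs columns snp/chrom/pos; ``genes`` columns
    chrom/start/end/gene_id (plus optional name/strand), 1-based inclusive.
    A gene is reported when its span overlaps the window by >= 1 bp. Windows
    are clipped to [1, chromosome length] when lengths are supplied.
    """
    out: list[CandidateWindow] = []
    known_chroms = set(genes["chrom"].astype(str)) if len(genes) else set()
    for _, row in hits.iterrows():
        chrom = str(row["chrom"])
        pos = int(row["pos"])
        start = max(1, pos - flank_bp)
        end = pos + flank_bp
        if chrom_lengths and chrom in chrom_lengths:
            end = min(end, int(chrom_lengths[chrom]))
        overlapping: list[dict] = []
        if chrom not in known_chroms:
            warnings.warn(f"chromosome {chrom!r} absent from annotation; empty gene list")
        else:
            sub = genes[genes["chrom"].astype(str) == chrom]
            mask = (sub["start"] <= end) & (sub["end"] >= start)
            for _, g in sub[mask].iterrows():
                overlapping.append(
                    {
                        "gene_id": str(g.get("gene_id", "")),
                        "name": str(g.get("name", "")),
                        "strand": str(g.get("strand", ".")),
                        "start": int(g["start"]),
                        "end": int(g["end"]),
                    }
                )
        out.append(
            CandidateWindow(
                snp_id=str(row["snp"]), chromosome=chrom, start=start, end=end,
                genes=overlapping,
            )
        )
    return out
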