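"""Cross-validated predictability and the marker-density experiment.

Predictability is the Pearson correlation between GEBVs and observed
phenotypes in a held-out test fold. The default design is fivefold
cross-validation repeated 40 times; with 455 individuals each repeat splits
into training sets of 364 and test folds of 91, and the same fold plan is
shared by every model so results are directly comparable.

The density experiment refits GBLUP on nested SNP subsets chosen by one of
three cumulative strategies: GWAS-ranked (ascending p), random, or evenly
spaced along the genome. GWAS ranking is leakage-safe by default — it is
recomputed inside each training set — with an opt-in global-ranking mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grm import GRM, vanraden_grm
from .gwas import GwasResult, lmm_gwas
from .models import GibbsSettings, fit_bayes, fit_gblup, predict_gebv
from .panel import GenotypePanel

__all__ = [
    "EvalError",
    "FoldPlan",
    "CvReport",
    "DensityCurve",
    "make_folds",
    "predictability",
    "run_cv",
    "select_snps",
    "density_experiment",
    "FIGURE_PANEL_SIZES",
]

logger = logging.getLogger(__name__)

# Reporting grid of panel sizes (0.05 K ... full panel).
FIGURE_PANEL_SIZES = (50, 100, 200, 300, 500, 800, 1000, 2000, 3000, 5000, 8000, 10000, 13000, 16162)


class EvalError(ValueError):
    pass


@dataclass
class FoldPlan:
    """Repeated k-fold assignments shared across models.

    ``assignments[r, i]`` is the fold label of individual ``i`` in repeat
    ``r``. Fold sizes differ by at most one; repeat ``r`` is seeded as
    ``base_seed + r`` for auditability.
    """

    n_individuals: int
    k_folds: int
    n_repeats: int
    assignments: np.ndarray
    base_seed: int

    def test_indices(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments[repeat] == fold)

    def train_indices(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments[repeat] != fold)


def make_folds(n: int, k: int = 5, n_repeats: int = 40, base_seed: int = 0) -> FoldPlan:
    """Per repeat, a uniformly random permutation split into k near-equal folds."""
    if k < 2:
        raise EvalError("k must be >= 2")
    if n < k:
        raise EvalError(f"cannot split n={n} individuals into k={k} folds")
    assignments = np.empty((n_repeats, n), dtype=np.int64)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    labels = np.repeat(np.arange(k), sizes)
    for r in range(n_repeats):
        rng = np.random.default_rng(base_seed + r)
        perm = rng.permutation(n)
        assignments[r, perm] = labels
    return FoldPlan(n_individuals=n, k_folds=k, n_repeats=n_repeats,
                    assignments=assignments, base_seed=base_seed)


def predictability(gebv: np.ndarray, y_test: np.ndarray) -> float:
    """Pearson correlation between predicted GEBVs and observed phenotypes."""
    gebv = np.asarray(gebv, dtype=float).ravel()
    y_test = np.asarray(y_test, dtype=float).ravel()
    if gebv.size != y_test.size or gebv.size < 3:
        raise EvalError("vectors must have equal length >= 3")
    if gebv.std() == 0 or y_test.std() == 0:
        raise EvalError("zero-variance input")
    return float(np.corrcoef(gebv, y_test)[0, 1])


@dataclass
class CvReport:
    """Per-cell predictabilities plus mean/SD summaries.

    ``cells`` has columns model, trait, repeat, fold, r (NaN for failed
    cells); ``summary`` aggregates mean and SD per (model, trait) — and per
    (panel_size, strategy) when produced by the density experiment.
    """

    cells: pd.DataFrame
    n_failed: int = 0
    panel_size: int | None = None
    strategy: str | None = None

    @property
    def summary(self) -> pd.DataFrame:
        ok = self.cells.dropna(subset=["r"])
        return (
            ok.groupby(["model", "trait"], as_index=False)["r"]
            .agg(mean_r="mean", sd_r=lambda s: s.std(ddof=1))
        )

    def mean_r(self, model: str | None = None) -> float:
        ok = self.cells.dropna(subset=["r"])
        if model is not None:
            ok = ok[ok["model"] == model]
        return float(ok["r"].mean())


def _fit_predict_gblup(y, full_grm: GRM, train, test):
    fit = fit_gblup(y[train], full_grm.subset(train))
    lam = fit.ratio
    G_tr = full_grm.values[np.ix_(train, train)]
    G_ts = full_grm.values[np.ix_(test, train)]
    rhs = np.linalg.solve(lam * G_tr + np.eye(train.size), fit.resid)
    return lam * (G_ts @ rhs)


def _fit_predict_bayes(y, panel: GenotypePanel, model, train, test, settings: GibbsSettings):
    train_panel = panel.subset(individuals=train)
    fit = fit_bayes(y[train], train_panel, model, settings)
    Z_new = panel.dosages[test] - 2.0 * fit.center_freqs[None, :]
    return Z_new @ fit.marker_effects


def run_cv(
    y: np.ndarray,
    panel: GenotypePanel,
    models: list[str],
    fold_plan: FoldPlan,
    settings: GibbsSettings | None = None,
    trait: str = "trait",
    grm: GRM | None = None,
) -> CvReport:
    """Repeated k-fold CV of one trait under one or more models.

    Test *phenotypes* are never passed to any fitting or ranking routine —
    fits receive only the training slice of ``y``. Test genotypes may enter
    the GRM (marker centering), matching standard genomic-prediction
    practice. A failed cell is recorded as NaN and the run continues.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size != panel.n_individuals or y.size != fold_plan.n_individuals:
        raise EvalError("phenotype / panel / fold plan sizes are inconsistent")
    needs_grm = any(m.upper() == "GBLUP" for m in models)
    if needs_grm and grm is None:
        grm = vanraden_grm(panel)
    rows = []
    n_failed = 0
    for r in range(fold_plan.n_repeats):
        for f in range(fold_plan.k_folds):
            train = fold_plan.train_indices(r, f)
            test = fold_plan.test_indices(r, f)
            for model in models:
                try:
                    if model.upper() == "GBLUP":
                        pred = _fit_predict_gblup(y, grm, train, test)
                    else:
                        cell_settings = settings or GibbsSettings.desk()
                        pred = _fit_predict_bayes(y, panel, model, train, test, cell_settings)
                    r_cell = predictability(pred, y[test])
                except Exception as exc:  # noqa: BLE001 - cell isolation is deliberate
                    logger.warning("CV cell failed (%s, rep %d, fold %d): %s", model, r, f, exc)
                    r_cell = np.nan
                    n_failed += 1
                rows.append({"model": model, "trait": trait, "repeat": r, "fold": f, "r": r_cell})
    return CvReport(cells=pd.DataFrame(rows), n_failed=n_failed)


# ------------------------------------------------------------- SNP subsets
def select_snps(
    panel: GenotypePanel,
    strategy: str,
    size: int,
    ranking: GwasResult | np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Choose a SNP subset of the given size; subsets are nested across sizes.

    gwas_ranked: first ``size`` SNPs by ascending p (ties by genome order);
    random: seeded uniform sample, cumulative by construction; evenly_spaced:
    genome-order indices ``floor(j*(m-1)/(size-1))``, deduplicated then padded
    with the nearest unused indices.
    """
    m = panel.n_snps
    if size < 1 or size > m:
        raise EvalError(f"size must be in [1, {m}], got {size}")
    if strategy == "gwas_ranked":
        if ranking is None:
            raise EvalError("gwas_ranked requires a GwasResult or a ranked index array")
        order = ranking.ranked_indices() if isinstance(ranking, GwasResult) else np.asarray(ranking)
        if order.size != m:
            raise EvalError("ranking length does not match panel")
        return np.sort(order[:size])
    if strategy == "random":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(m)
        return np.sort(perm[:size])
    if strategy == "evenly_spaced":
        if size == 1:
            return np.array([0])
        ideal = (np.arange(size) * (m - 1)) // (size - 1)
        chosen = list(dict.fromkeys(ideal.tolist()))
        used = set(chosen)
        j = 0
        while len(chosen) < size:
            # pad from unused indices nearest to already-chosen ones
            candidate = None
            for c in chosen:
                for delta in (1, -1):
                    x = c + delta * (j + 1)
                    if 0 <= x < m and x not in used:
                        candidate = x
                        break
                if candidate is not None:
                    break
            if candidate is None:
                j += 1
                continue
            chosen.append(candidate)
            used.add(candidate)
        return np.sort(np.asarray(chosen[:size]))
    raise EvalError(f"unknown strategy {strategy!r}")


@dataclass
class DensityCurve:
    """Mean +/- SD predictability as a function of panel size."""

    strategy: str
    panel_sizes: list[int]
    mean_r: list[float]
    sd_r: list[float]
    nested_subsets: bool = True
    reports: list[CvReport] = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.panel_sizes) != sorted(set(self.panel_sizes)):
            raise EvalError("panel_sizes must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"strategy": self.strategy, "panel_size": self.panel_sizes,
             "mean_r": self.mean_r, "sd_r": self.sd_r}
        )


def density_experiment(
    y: np.ndarray,
    panel: GenotypePanel,
    fold_plan: FoldPlan,
    strategy: str,
    sizes: list[int] | None = None,
    rank_on_full_data: bool = False,
    seed: int = 0,
    trait: str = "trait",
) -> DensityCurve:
    """GBLUP predictability across cumulative SNP subsets of increasing size.

    For ``gwas_ranked`` the ranking is, by default, recomputed within each
    training set (no test-phenotype leakage); ``rank_on_full_data=True``
    ranks once on all individuals instead. Random subsets are nested across
    sizes; evenly spaced subsets follow the genome-order spacing rule.
    """
    y = np.asarray(y, dtype=float).ravel()
    m = panel.n_snps
    if sizes is None:
        sizes = [s for s in FIGURE_PANEL_SIZES if s < m] + [m]
    sizes = sorted(set(int(s) for s in sizes))
    if sizes[0] < 1 or sizes[-1] > m:
        raise EvalError("sizes out of range")

    cells = [
        (r, f, fold_plan.train_indices(r, f), fold_plan.test_indices(r, f))
        for r in range(fold_plan.n_repeats)
        for f in range(fold_plan.k_folds)
    ]

    # one ranking per CV cell (leakage-safe) or one global ranking
    rankings: dict[tuple[int, int], np.ndarray] = {}
    if strategy == "gwas_ranked":
        if rank_on_full_data:
            full_grm = vanraden_grm(panel)
            order = lmm_gwas(y, panel, full_grm).ranked_indices()
            rankings = {(c[0], c[1]): order for c in cells}
        else:
            for r, f, train, _ in cells:
                train_panel = panel.subset(individuals=train)
                g_tr = vanraden_grm(train_panel, allow_monomorphic=True)
                rankings[(r, f)] = lmm_gwas(y[train], train_panel, g_tr).ranked_indices()

    mean_r, sd_r, reports = [], [], []
    for size in sizes:
        rows = []
        for r, f, train, test in cells:
            if strategy == "gwas_ranked":
                idx = np.sort(rankings[(r, f)][:size])
            else:
                idx = select_snps(panel, strategy, size, seed=seed)
            sub = panel.subset(snps=idx)
            sub_grm = vanraden_grm(sub, allow_monomorphic=True)
            try:
                pred = _fit_predict_gblup(y, sub_grm, train, test)
                r_cell = predictability(pred, y[test])
            except Exception as exc:  # noqa: BLE001
                logger.warning("density cell failed (size %d): %s", size, exc)
                r_cell = np.nan
            rows.append({"model": "GBLUP", "trait": trait, "repeat": r, "fold": f, "r": r_cell})
        report = CvReport(cells=pd.DataFrame(rows), panel_size=size, strategy=strategy)
        reports.append(report)
        vals = report.cells["r"].dropna()
        mean_r.append(float(vals.mean()))
        sd_r.append(float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
        logger.info("density %s size=%d mean r=%.3f", strategy, size, mean_r[-1])
    return DensityCurve(strategy=strategy, panel_sizes=sizes, mean_r=mean_r, sd_r=sd_r,
                        nested_subsets=(strategy != "evenly_spaced"), reports=reports)
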