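"""Bayesian whole-genome regression (BayesA/B/C/L/RR) via single-site Gibbs.

The marker matrix is centered by the training panel's observed allele
frequencies (the same centering the VanRaden GRM uses), so GEBVs are
directly comparable with GBLUP's. Reported Vg is the *genomic* variance —
the variance across individuals of the fitted genetic values Z alpha,
averaged over post-burn-in thinned draws — which matches GBLUP's sigma_g^2
scale and is robust to linkage disequilibrium among markers.

Prior hyperparameters follow common whole-genome-regression defaults:
scaled-inverse-chi-square priors with ``prior_df`` degrees of freedom whose
mode splits half the phenotypic variance between the genomic and residual
parts (the genomic share divided by the summed marker variance, and by
(1 - pi) for the spike models); the BayesL rate parameter lambda^2 carries a
gamma(1.1, rate) hyperprior whose mode implies the same genomic share.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from ..panel import GenotypePanel
from ._gibbs import MODEL_CODES, gibbs_sample
from .common import ModelError, ModelFit, VarianceComponents

__all__ = ["GibbsSettings", "fit_bayes"]


@dataclass
class GibbsSettings:
    """MCMC run settings.

    Defaults are the study-faithful chain (50,000 iterations, 5,000 burn-in,
    thinning 5, pi = 0.95); :meth:`desk` gives a shorter preset for
    interactive work and tests.
    """

    iterations: int = 50_000
    burn_in: int = 5_000
    thin: int = 5
    pi: float = 0.95
    prior_df: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ModelError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ModelError("thin must be >= 1")
        if not (0.0 <= self.pi < 1.0):
            raise ModelError("pi must lie in [0, 1)")
        if self.prior_df <= 0:
            raise ModelError("prior_df must be positive")

    @classmethod
    def desk(cls, seed: int = 0, **kw) -> "GibbsSettings":
        kw.setdefault("iterations", 6_000)
        kw.setdefault("burn_in", 1_000)
        kw.setdefault("thin", 5)
        return cls(seed=seed, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


def _prior_scales(vary: float, msx: float, model: str, settings: GibbsSettings):
    """Scaled-inv-chi2 scales so prior modes split 0.5*var(y) genomic/residual."""
    df = settings.prior_df
    vg0 = 0.5 * vary
    ve0 = 0.5 * vary
    S_e = ve0 * (df + 2.0) / df
    if model in ("BayesB", "BayesC"):
        share = max(1.0 - settings.pi, 1e-3)
    else:
        share = 1.0
    mode_alpha = vg0 / max(msx * share, 1e-12)
    S_alpha = mode_alpha * (df + 2.0) / df
    # BayesL: Var(alpha_j) ~ 2*sigma_e^2/lambda^2 -> mode of lambda^2
    lam2_mode = 2.0 * ve0 * msx / max(vg0, 1e-12)
    lasso_shape = 1.1
    lasso_rate = (lasso_shape - 1.0) / lam2_mode
    return S_alpha, S_e, lasso_shape, lasso_rate


def fit_bayes(
    y: np.ndarray,
    panel: GenotypePanel,
    model: str,
    settings: GibbsSettings | None = None,
    covariates: np.ndarray | None = None,
) -> ModelFit:
    """Fit one Bayesian-alphabet model to one trait by Gibbs sampling.

    ``model`` is one of BayesA, BayesB, BayesC, BayesL, BayesRR
    (case-insensitive). The panel must be imputed/QC'd; deterministic given
    ``settings.seed``.
    """
    canonical = {k.lower(): k for k in MODEL_CODES}
    key = str(model).lower()
    if key not in canonical:
        raise ModelError(f"unknown Bayesian model {model!r}; choose from {sorted(MODEL_CODES)}")
    model = canonical[key]
    settings = settings or GibbsSettings()

    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if panel.n_individuals != n:
        raise ModelError("panel rows do not match phenotype length")
    if panel.missing_mask.any():
        raise ModelError("panel has missing genotypes; impute first")
    if not np.all(np.isfinite(y)):
        raise ModelError("phenotypes must be complete")
    if y.var() == 0:
        raise ModelError("phenotype has zero variance (degenerate)")

    freqs = panel.allele_freqs()
    Z = np.ascontiguousarray(panel.dosages - 2.0 * freqs[None, :])
    W = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ModelError("covariate rows do not match phenotype length")
        W = np.hstack([W, C])

    vary = float(y.var())
    msx = float((Z**2).sum(axis=0).mean() * Z.shape[1] / n)  # sum_j var(z_j)
    S_alpha, S_e, lasso_shape, lasso_rate = _prior_scales(vary, msx, model, settings)

    alpha, incl, beta, vg_draws, ve_draws = gibbs_sample(
        Z,
        y,
        W,
        MODEL_CODES[model],
        settings.iterations,
        settings.burn_in,
        settings.thin,
        settings.pi,
        settings.prior_df,
        S_alpha,
        settings.prior_df,
        S_e,
        lasso_shape,
        lasso_rate,
        int(settings.seed) % (2**31),
    )

    vg = float(vg_draws.mean())
    ve = float(ve_draws.mean())
    gebv = Z @ alpha
    return ModelFit(
        model_name=model,
        varcomp=VarianceComponents(
            Vg=vg,
            Ve=max(ve, np.finfo(float).tiny),
            sd_Vg=float(vg_draws.std(ddof=1)) if vg_draws.size > 1 else None,
            sd_Ve=float(ve_draws.std(ddof=1)) if ve_draws.size > 1 else None,
        ),
        fixed_effects=beta,
        gebv=gebv,
        marker_effects=alpha,
        inclusion_prob=incl if model in ("BayesB", "BayesC") else None,
        mcmc=settings.to_dict(),
        train_ids=list(panel.individual_ids),
        snp_ids=list(panel.snp_ids),
        center_freqs=freqs,
    )
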