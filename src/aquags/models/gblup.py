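"""GBLUP: REML variance components and BLUP breeding values via the
eigendecomposition of the genomic relationship matrix.

Model: y = X b + u + e with u ~ N(0, Vg * G) and e ~ N(0, Ve * I). Writing
lambda = Vg / Ve and G = U D U', the covariance is Ve * U (lambda*D + I) U',
so the restricted likelihood profiles down to a one-dimensional search over
lambda (done on the log scale with bounded Brent minimization). Fixed
effects come from generalized least squares at the optimum and
u_hat = lambda * G (lambda*G + I)^{-1} (y - X b_hat).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from ..grm import GRM, GrmError
from .common import ModelError, ModelFit, VarianceComponents

__all__ = ["fit_gblup", "reml_profile"]

RATIO_BOUNDS = (1e-6, 1e6)


def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ModelError("covariate rows do not match phenotype length")
        X = np.hstack([X, C])
    return X


def reml_profile(log_lam: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    """Negative restricted log-likelihood (up to a constant) at log(lambda)."""
    lam = np.exp(log_lam)
    w = lam * d + 1.0  # eigenvalues of V / Ve
    n, p = Xt.shape
    Wi = 1.0 / w
    XtW = Xt * Wi[:, None]
    XWX = Xt.T @ XtW
    XWy = XtW.T @ yt
    beta = np.linalg.solve(XWX, XWy)
    r = yt - Xt @ beta
    rss = float(r @ (Wi * r))
    ve = rss / (n - p)
    sign, logdet_xwx = np.linalg.slogdet(XWX)
    if sign <= 0:
        return np.inf
    return 0.5 * (np.sum(np.log(w)) + logdet_xwx + (n - p) * np.log(ve))


def fit_gblup(
    y: np.ndarray,
    grm: GRM,
    covariates: np.ndarray | None = None,
    ratio_bounds: tuple[float, float] = RATIO_BOUNDS,
    tol: float = 1e-8,
) -> ModelFit:
    """REML fit of the GBLUP mixed model for one trait.

    Parameters
    ----------
    y
        Complete phenotype vector aligned with ``grm.individual_ids``.
    grm
        Genomic relationship matrix of the phenotyped individuals.
    covariates
        Optional fixed-effect columns (an intercept is always included).

    Returns a :class:`ModelFit`; ``boundary`` is flagged when the variance
    ratio sticks to either end of its search interval.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if grm.n != n:
        raise ModelError(f"GRM order {grm.n} does not match phenotype length {n}")
    if not np.all(np.isfinite(y)):
        raise ModelError("phenotypes must be complete (no NaN) for fitting")
    if n < 30:
        raise ModelError("need at least 30 phenotyped individuals")
    if y.var() == 0:
        raise ModelError("phenotype has zero variance")

    d, U = np.linalg.eigh(grm.values)
    if d.min() < -1e-6 * max(1.0, d.max()):
        raise GrmError("GRM is not positive semidefinite")
    d = np.clip(d, 0.0, None)
    X = _design(n, covariates)
    yt = U.T @ y
    Xt = U.T @ X

    lo, hi = np.log(ratio_bounds[0]), np.log(ratio_bounds[1])
    res = minimize_scalar(
        reml_profile,
        bounds=(lo, hi),
        args=(d, yt, Xt),
        method="bounded",
        options={"xatol": tol},
    )
    log_lam = float(res.x)
    boundary = bool((log_lam - lo) < 1e-3 or (hi - log_lam) < 1e-3)
    lam = float(np.exp(log_lam))

    w = lam * d + 1.0
    Wi = 1.0 / w
    XtW = Xt * Wi[:, None]
    XWX = Xt.T @ XtW
    beta = np.linalg.solve(XWX, XtW.T @ yt)
    r_rot = yt - Xt @ beta
    ve = float(r_rot @ (Wi * r_rot)) / (n - X.shape[1])
    vg = lam * ve

    resid = y - X @ beta
    # u = lambda * G (lambda G + I)^{-1} resid, via the eigenbasis
    u = U @ ((lam * d / w) * (U.T @ resid))

    return ModelFit(
        model_name="GBLUP",
        varcomp=VarianceComponents(Vg=vg, Ve=max(ve, np.finfo(float).tiny)),
        fixed_effects=beta,
        gebv=u,
        boundary=boundary,
        train_ids=list(grm.individual_ids),
        resid=resid,
        ratio=lam,
    )
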