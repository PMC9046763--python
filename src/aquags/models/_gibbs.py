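"""Single-site Gibbs sampler core for the Bayesian alphabet, compiled with numba.

One kernel covers the five marker-effect priors; ``model_code`` selects the
conditional updates:

====  =======  =====================================================
code  model    marker-effect prior
====  =======  =====================================================
0     BayesRR  normal, one common variance
1     BayesA   normal, per-marker scaled-inverse-chi2 variances
2     BayesB   spike at zero (prob. pi) + per-marker-variance slab
3     BayesC   spike at zero (prob. pi) + common-variance slab
4     BayesL   Laplace (exponential mixture of normals), lambda^2
               with a gamma hyperprior
====  =======  =====================================================

The residual vector is maintained incrementally, so one marker update costs
two length-n dot products. Genomic variance per stored draw is computed for
free as var(y - W beta - e) = var(Z alpha).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["gibbs_sample", "MODEL_CODES"]

MODEL_CODES = {"BayesRR": 0, "BayesA": 1, "BayesB": 2, "BayesC": 3, "BayesL": 4}


@njit(cache=True)
def gibbs_sample(
    Z,              # (n, m) centered marker matrix, float64, Fortran or C
    y,              # (n,) phenotypes
    W,              # (n, p) fixed-effect design (intercept first)
    model_code,     # int
    iters, burn, thin,
    pi,             # prior probability of a null effect (BayesB/C)
    df_alpha, S_alpha,
    df_e, S_e,
    lasso_shape, lasso_rate,
    seed,
):
    np.random.seed(seed)
    n, m = Z.shape
    p = W.shape[1]

    zz = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Z[i, j] * Z[i, j]
        zz[j] = s
    ww = np.empty(p)
    for k in range(p):
        s = 0.0
        for i in range(n):
            s += W[i, k] * W[i, k]
        ww[k] = s

    beta = np.zeros(p)
    alpha = np.zeros(m)
    incl = np.ones(m, dtype=np.bool_)
    e = y.copy()

    ybar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    vary = 0.0
    for i in range(n):
        vary += (y[i] - ybar) ** 2
    vary /= n

    sigma2e = 0.5 * vary if vary > 0 else 1.0
    # gamma hyperprior on the per-marker-variance scale (BayesA/B), mode at
    # the initial S_alpha
    scale_shape = 1.1
    scale_rate = (scale_shape - 1.0) / S_alpha
    adapt_scale = model_code == 1  # heavy-tailed all-in model needs it most
    mode_a = df_alpha * S_alpha / (df_alpha + 2.0)
    s2 = np.full(m, mode_a)          # per-marker variances (A/B)
    s2c = mode_a                     # common variance (RR/C)
    tau2 = np.ones(m)                # BayesL local scales
    lam2 = lasso_shape / lasso_rate  # BayesL lambda^2 (prior mean)

    n_store = 0
    alpha_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    beta_sum = np.zeros(p)
    max_draws = (iters - burn + thin - 1) // thin
    vg_draws = np.zeros(max_draws)
    ve_draws = np.zeros(max_draws)

    log_prior_odds = 0.0
    spike = model_code == 2 or model_code == 3
    if spike:
        log_prior_odds = np.log(max(1.0 - pi, 1e-300)) - np.log(max(pi, 1e-300))

    for it in range(iters):
        # ---- fixed effects (flat prior)
        for k in range(p):
            if ww[k] <= 0.0:
                continue
            b = 0.0
            for i in range(n):
                b += W[i, k] * e[i]
            b += ww[k] * beta[k]
            mean = b / ww[k]
            new = mean + np.sqrt(sigma2e / ww[k]) * np.random.standard_normal()
            diff = beta[k] - new
            for i in range(n):
                e[i] += W[i, k] * diff
            beta[k] = new

        # ---- marker effects
        for j in range(m):
            if zz[j] <= 0.0:
                alpha[j] = 0.0
                incl[j] = False
                continue
            if model_code == 0:
                v = s2c
            elif model_code == 1 or model_code == 2:
                v = s2[j]
            elif model_code == 3:
                v = s2c
            else:
                v = sigma2e * tau2[j]
            if v < 1e-300:
                v = 1e-300

            b = zz[j] * alpha[j]
            for i in range(n):
                b += Z[i, j] * e[i]
            C = zz[j] + sigma2e / v

            old = alpha[j]
            if spike:
                lo = log_prior_odds + 0.5 * (np.log(sigma2e) - np.log(v) - np.log(C)) \
                    + b * b / (2.0 * sigma2e * C)
                if lo > 35.0:
                    p_in = 1.0
                elif lo < -35.0:
                    p_in = 0.0
                else:
                    p_in = 1.0 / (1.0 + np.exp(-lo))
                incl[j] = np.random.random() < p_in
                if incl[j]:
                    new = b / C + np.sqrt(sigma2e / C) * np.random.standard_normal()
                else:
                    new = 0.0
            else:
                incl[j] = True
                new = b / C + np.sqrt(sigma2e / C) * np.random.standard_normal()

            if new != old:
                diff = old - new
                for i in range(n):
                    e[i] += Z[i, j] * diff
                alpha[j] = new

        # ---- marker-variance hyperparameters
        if model_code == 1 or model_code == 2:  # BayesA / BayesB
            inv_sum = 0.0
            for j in range(m):
                if model_code == 1 or incl[j]:
                    s2[j] = (alpha[j] * alpha[j] + df_alpha * S_alpha) / np.random.chisquare(df_alpha + 1.0)
                else:
                    s2[j] = df_alpha * S_alpha / np.random.chisquare(df_alpha)
                inv_sum += 1.0 / s2[j]
            # adaptive scale: S | s2 ~ Gamma(a0 + m*df/2, b0 + (df/2) * sum 1/s2_j)
            if adapt_scale:
                S_alpha = np.random.gamma(
                    scale_shape + 0.5 * df_alpha * m,
                    1.0 / (scale_rate + 0.5 * df_alpha * inv_sum),
                )
        elif model_code == 0:  # BayesRR
            ssa = 0.0
            for j in range(m):
                ssa += alpha[j] * alpha[j]
            s2c = (ssa + df_alpha * S_alpha) / np.random.chisquare(df_alpha + m)
        elif model_code == 3:  # BayesC
            ssa = 0.0
            m_in = 0
            for j in range(m):
                if incl[j]:
                    ssa += alpha[j] * alpha[j]
                    m_in += 1
            s2c = (ssa + df_alpha * S_alpha) / np.random.chisquare(df_alpha + m_in)
        else:  # BayesL
            sum_tau2 = 0.0
            for j in range(m):
                aj = abs(alpha[j])
                if aj < 1e-10:
                    aj = 1e-10
                mu_ig = np.sqrt(lam2 * sigma2e) / aj
                if mu_ig > 1e8:
                    mu_ig = 1e8
                inv_tau2 = np.random.wald(mu_ig, lam2)
                if inv_tau2 < 1e-12:
                    inv_tau2 = 1e-12
                tau2[j] = 1.0 / inv_tau2
                sum_tau2 += tau2[j]
            lam2 = np.random.gamma(lasso_shape + m, 1.0 / (lasso_rate + 0.5 * sum_tau2))

        # ---- residual variance
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        sigma2e = (sse + df_e * S_e) / np.random.chisquare(n + df_e)
        if sigma2e < 1e-12:
            sigma2e = 1e-12

        # ---- storage
        if it >= burn and (it - burn) % thin == 0:
            # genetic value g_i = y_i - W beta - e_i (free from the residual)
            vg = 0.0
            mean_g = 0.0
            for i in range(n):
                fx = 0.0
                for k in range(p):
                    fx += W[i, k] * beta[k]
                g = y[i] - fx - e[i]
                mean_g += g
            mean_g /= n
            for i in range(n):
                fx = 0.0
                for k in range(p):
                    fx += W[i, k] * beta[k]
                g = y[i] - fx - e[i]
                vg += (g - mean_g) ** 2
            vg /= n
            vg_draws[n_store] = vg
            ve_draws[n_store] = sigma2e
            for j in range(m):
                alpha_sum[j] += alpha[j]
                if incl[j]:
                    incl_sum[j] += 1.0
            for k in range(p):
                beta_sum[k] += beta[k]
            n_store += 1

    alpha_mean = alpha_sum / n_store
    incl_mean = incl_sum / n_store
    beta_mean = beta_sum / n_store
    return alpha_mean, incl_mean, beta_mean, vg_draws[:n_store], ve_draws[:n_store]
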