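"""GEBV prediction for unphenotyped individuals.

Bayesian fits predict ``Z_new @ alpha_hat`` with new genotypes centered by
the *training* allele frequencies. GBLUP predicts the conditional mean
through the train/test blocks of a joint GRM:

    u_test = lambda * G_ts,tr (lambda * G_tr + I)^{-1} (y_tr - X_tr b_hat)
"""

from __future__ import annotations

import numpy as np

from ..grm import GRM
from ..panel import GenotypePanel
from .common import ModelError, ModelFit

__all__ = ["predict_gebv"]


def _predict_gblup(fit: ModelFit, joint: GRM) -> np.ndarray:
    ids = list(joint.individual_ids)
    pos = {iid: i for i, iid in enumerate(ids)}
    missing = [iid for iid in fit.train_ids if iid not in pos]
    if missing:
        raise ModelError(f"joint GRM lacks training individuals: {missing[:5]}")
    train_idx = np.array([pos[iid] for iid in fit.train_ids])
    test_idx = np.array([i for i in range(joint.n) if ids[i] not in set(fit.train_ids)])
    if test_idx.size == 0:
        raise ModelError("joint GRM contains no new individuals")
    lam = fit.ratio
    G_tr = joint.values[np.ix_(train_idx, train_idx)]
    G_ts = joint.values[np.ix_(test_idx, train_idx)]
    n_tr = train_idx.size
    rhs = np.linalg.solve(lam * G_tr + np.eye(n_tr), fit.resid)
    return lam * (G_ts @ rhs)


def _predict_bayes(fit: ModelFit, panel: GenotypePanel) -> np.ndarray:
    if fit.snp_ids is None or fit.center_freqs is None:
        raise ModelError("fit carries no marker information")
    col = {sid: j for j, sid in enumerate(panel.snp_ids)}
    missing = [sid for sid in fit.snp_ids if sid not in col]
    if missing:
        raise ModelError(
            f"new panel is missing {len(missing)} training SNP(s), e.g. {missing[:5]}"
        )
    order = np.array([col[sid] for sid in fit.snp_ids])
    dos = panel.dosages[:, order]
    if not np.all(np.isfinite(dos)):
        raise ModelError("new panel has missing genotypes; impute first")
    Z_new = dos - 2.0 * fit.center_freqs[None, :]
    return Z_new @ fit.marker_effects


def predict_gebv(fit: ModelFit, new_panel_or_grm: GenotypePanel | GRM) -> np.ndarray:
    """Predict GEBVs for individuals not in the training set.

    For a GBLUP fit pass a joint :class:`GRM` over training + test
    individuals (test GEBVs are returned in the joint matrix's order); for a
    Bayesian fit pass a :class:`GenotypePanel` of the new individuals on the
    training SNP set.
    """
    if fit.model_name == "GBLUP":
        if not isinstance(new_panel_or_grm, GRM):
            raise ModelError("GBLUP prediction requires a joint GRM of training + test individuals")
        return _predict_gblup(fit, new_panel_or_grm)
    if not isinstance(new_panel_or_grm, GenotypePanel):
        raise ModelError("Bayesian prediction requires a GenotypePanel of new individuals")
    return _predict_bayes(fit, new_panel_or_grm)
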