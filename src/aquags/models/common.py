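"""Shared model-fit containers for whole-genome regression.

All six models ("GBLUP" plus the Bayesian alphabet: BayesA, BayesB, BayesC,
BayesL, BayesRR) report additive genetic variance Vg, residual variance Ve,
narrow-sense heritability h2 = Vg / (Vg + Ve), fixed effects, and genomic
estimated breeding values (GEBVs) for the training individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["MODEL_NAMES", "ModelError", "VarianceComponents", "ModelFit", "heritability"]

MODEL_NAMES = ("GBLUP", "BayesA", "BayesB", "BayesC", "BayesL", "BayesRR")


class ModelError(ValueError):
    pass


def heritability(vg, ve: float | None = None) -> float:
    """Narrow-sense heritability h2 = Vg / (Vg + Ve).

    Accepts either the two components or a :class:`VarianceComponents`.
    """
    if ve is None:
        vg, ve = vg.Vg, vg.Ve
    if vg < 0 or ve < 0:
        raise ModelError(f"variance components must be non-negative (Vg={vg}, Ve={ve})")
    total = vg + ve
    if total <= 0:
        raise ModelError("Vg + Ve must be positive")
    return vg / total


@dataclass
class VarianceComponents:
    Vg: float
    Ve: float
    sd_Vg: Optional[float] = None
    sd_Ve: Optional[float] = None

    def __post_init__(self) -> None:
        if self.Vg < 0:
            raise ModelError(f"Vg must be >= 0, got {self.Vg}")
        if self.Ve <= 0:
            raise ModelError(f"Ve must be > 0, got {self.Ve}")

    @property
    def h2(self) -> float:
        return heritability(self.Vg, self.Ve)


@dataclass
class ModelFit:
    """Result of fitting one whole-genome regression model to one trait.

    ``h2`` is derived from the stored components in the constructor so the
    identity h2 == Vg/(Vg+Ve) holds exactly. Bayesian fits carry posterior
    mean marker effects (and, for BayesB/C, posterior inclusion
    probabilities) plus the training-panel centering frequencies needed to
    compute GEBVs for new genotypes.
    """

    model_name: str
    varcomp: VarianceComponents
    fixed_effects: np.ndarray
    gebv: np.ndarray
    h2: float = field(init=False)
    marker_effects: Optional[np.ndarray] = None
    inclusion_prob: Optional[np.ndarray] = None
    mcmc: Optional[dict] = None
    boundary: bool = False
    # internals needed for out-of-sample prediction
    train_ids: Optional[list] = None
    snp_ids: Optional[list] = None
    center_freqs: Optional[np.ndarray] = None  # Bayesian: training allele freqs
    resid: Optional[np.ndarray] = None  # GBLUP: y - X b_hat on training set
    ratio: Optional[float] = None  # GBLUP: Vg / Ve

    def __post_init__(self) -> None:
        if self.model_name not in MODEL_NAMES:
            raise ModelError(f"unknown model {self.model_name!r}")
        self.h2 = heritability(self.varcomp.Vg, self.varcomp.Ve)
        if self.inclusion_prob is not None:
            ip = np.asarray(self.inclusion_prob)
            if ip.size and (ip.min() < 0 or ip.max() > 1):
                raise ModelError("inclusion probabilities must lie in [0, 1]")

    def summary(self) -> dict:
        out = {
            "model": self.model_name,
            "Vg": self.varcomp.Vg,
            "Ve": self.varcomp.Ve,
            "h2": self.h2,
            "fixed_effects": np.asarray(self.fixed_effects).tolist(),
            "n_train": int(np.asarray(self.gebv).size),
            "boundary": self.boundary,
        }
        if self.mcmc:
            out["mcmc"] = self.mcmc
        return out
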