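"""Heritability from fitted variance components.

Additive heritability and additive-plus-dominance heritability are the
ratios

    h2_A  = sigma2_A / (sigma2_A + sigma2_e)
    h2_AD = (sigma2_A + sigma2_D) / (sigma2_A + sigma2_D + sigma2_e)

computed from the mixed-model fits with the additive (A) and dominance
(D) genomic relationship matrices.  For Gibbs fits, h2 is computed per
posterior draw and summarised by the posterior mean, which avoids the
bias of taking a ratio of posterior means.

A caveat for joint A+D fits: A and D built from the same markers are
correlated, so the split between sigma2_A and sigma2_D is imprecise even
when their sum (and hence h2_AD) is well determined.  On nearly fully
homozygous panels the dominance term can absorb noise and inflate h2_AD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_data import GenotypeMatrix
from .prediction_models import ModelFit, VarianceComponents, fit_gblup
from .relationship_matrices import additive_kinship, dominance_kinship

__all__ = ["HeritabilityEstimate", "h2_additive", "h2_additive_dominant",
           "estimate_heritability"]


def h2_additive(vc: VarianceComponents) -> float:
    """sigma2_A / (sigma2_A + sigma2_e)."""
    total = vc.sigma2_A + vc.sigma2_e
    if total <= 0:
        raise ValueError("sigma2_A + sigma2_e must be positive")
    return vc.sigma2_A / total


def h2_additive_dominant(vc: VarianceComponents) -> float:
    """(sigma2_A + sigma2_D) / (sigma2_A + sigma2_D + sigma2_e)."""
    if vc.sigma2_D is None:
        raise ValueError("sigma2_D absent; fit the additive-dominant model")
    total = vc.sigma2_A + vc.sigma2_D + vc.sigma2_e
    if total <= 0:
        raise ValueError("variance components sum to zero")
    return (vc.sigma2_A + vc.sigma2_D) / total


@dataclass
class HeritabilityEstimate:
    trait: str
    components: VarianceComponents
    engine: str
    h2_A: float | None = None
    h2_AD: float | None = None

    def __post_init__(self) -> None:
        for v in (self.h2_A, self.h2_AD):
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"h2 outside [0, 1]: {v}")


def _posterior_mean_h2(fit: ModelFit, dominant: bool) -> float:
    samples = fit.diagnostics["samples"]
    g = samples["sigma2_g"]
    e = samples["sigma2_e"]
    if dominant:
        num = g[:, 0] + g[:, 1]
    else:
        num = g[:, 0]
    return float(np.mean(num / (num + e)))


def estimate_heritability(y: pd.Series, G: GenotypeMatrix,
                          effects: str = "additive",
                          engine: str = "REML",
                          spec=None) -> HeritabilityEstimate:
    """Build kinships from ``G``, fit the mixed model, and return h2.

    ``effects="additive"`` gives h2_A from the A-only fit (Eq.-1 form);
    ``"additive_dominant"`` gives h2_AD from the joint A+D fit.
    """
    A = additive_kinship(G)
    trait = str(y.name) if y.name is not None else "trait"
    if effects == "additive":
        fit = fit_gblup(y, A, None, engine=engine, spec=spec)
        if engine == "Gibbs":
            h2 = _posterior_mean_h2(fit, dominant=False)
        else:
            h2 = h2_additive(fit.components)
        return HeritabilityEstimate(trait, fit.components, engine, h2_A=h2)
    if effects == "additive_dominant":
        D = dominance_kinship(G)
        fit = fit_gblup(y, A, D, engine=engine, spec=spec)
        if engine == "Gibbs":
            h2 = _posterior_mean_h2(fit, dominant=True)
        else:
            h2 = h2_additive_dominant(fit.components)
        return HeritabilityEstimate(trait, fit.components, engine, h2_AD=h2)
    raise ValueError(f"unknown effects {effects!r}")
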