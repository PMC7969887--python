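"""Selection of parental combinations from predicted hybrid performance.

Every candidate F1 in the cross plan is scored with a fitted model per
trait; hybrids are then assigned to five selection classes — high / low
on each of two focal traits plus an intermediate class — drawn from
quantile bands of the predicted distributions.  Crosses that are
impractical (e.g. flowering-time incompatibilities) are supplied as an
explicit exclusion list and never selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_data import GenotypeMatrix
from .hybrid_genotypes import CrossPlan, hybrid_id, synthesize_hybrids
from .prediction_models import ModelFit, predict_gblup, predict_markers
from .relationship_matrices import (
    additive_kinship,
    dominance_kinship,
    heterozygosity_design,
)
from .evaluation import pearson_accuracy

__all__ = ["SelectionClasses", "predict_all_hybrids", "select_classes",
           "evaluate_selection"]


@dataclass
class SelectionClasses:
    """Configuration of the five-class scheme.

    ``outer_quantile`` bounds the high/low classes (default outer deciles);
    the intermediate class is drawn from the middle band of both focal
    traits.  ``excluded_pairs`` lists unordered parent pairs that must
    never be selected.
    """

    trait1: str
    trait2: str
    outer_quantile: float = 0.1
    intermediate_band: tuple[float, float] = (0.4, 0.6)
    quota: int = 5
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.outer_quantile < 0.5:
            raise ValueError("outer_quantile must be in (0, 0.5)")
        lo, hi = self.intermediate_band
        if not 0 < lo < hi < 1:
            raise ValueError("intermediate_band must be within (0, 1)")

    def excluded_ids(self) -> set[str]:
        return {hybrid_id(a, b) for a, b in self.excluded_pairs}

    @property
    def class_names(self) -> list[str]:
        return [f"high_{self.trait1}", f"low_{self.trait1}",
                f"high_{self.trait2}", f"low_{self.trait2}", "intermediate"]


def predict_all_hybrids(fits: dict[str, ModelFit], G_parents: GenotypeMatrix,
                        plan: CrossPlan, kinship_parents=None) -> pd.DataFrame:
    """Score every planned hybrid with each trait's fitted model.

    Hybrid genotypes are synthesized from the parents by the expectation
    rule; kinship models get relationship blocks between hybrids and the
    training individuals, marker models score the hybrid designs directly.
    Returns a hybrid x trait DataFrame.
    """
    from .genotype_data import GenotypeMatrix as _GM

    G_hyb = synthesize_hybrids(G_parents, plan)
    out = {}
    for trait, fit in fits.items():
        if fit.beta_add is not None:
            X_het = (heterozygosity_design(G_hyb)
                     if fit.beta_het is not None else None)
            pred = predict_markers(fit, G_hyb.calls.astype(float), X_het,
                                   ids=G_hyb.individuals)
        elif fit.alpha is not None:
            # build kinship over training individuals + hybrids; training
            # individuals must be rows of G_parents.  When the candidate
            # space overlaps the training set (e.g. the test F1s are both
            # trained on and re-predicted), relabel the candidate copy.
            G_train = G_parents.take_individuals(fit.train_ids)
            overlap = set(G_train.individuals) & set(G_hyb.individuals)
            rename = {i: (f"{i}@cand" if i in overlap else i)
                      for i in G_hyb.individuals}
            G_cand = _GM([rename[i] for i in G_hyb.individuals],
                         G_hyb.markers.copy(), G_hyb.calls)
            G_union = G_train.concat_individuals(G_cand)
            p_train = (G_train.calls + 1).mean(axis=0) / 2.0
            A = additive_kinship(G_union, freqs=p_train, freq_source="train")
            D = None
            if fit.components is not None and fit.components.sigma2_D is not None:
                D = dominance_kinship(G_union, freqs=p_train,
                                      freq_source="train")
            pred = predict_gblup(fit, A, D, list(G_cand.individuals))
            pred.index = G_hyb.individuals
        else:
            raise ValueError(f"fit for {trait!r} supports no hybrid scoring")
        out[trait] = pred
    return pd.DataFrame(out)


def select_classes(predictions: pd.DataFrame, classes: SelectionClasses
                   ) -> dict[str, CrossPlan]:
    """Assign hybrids to the five classes, disjointly, quota each.

    High/low classes take the best-ranked hybrids beyond the outer
    quantiles of the predicted distribution; the intermediate class takes
    hybrids inside the middle band on both focal traits.  Excluded pairs
    are never selected; ties break by hybrid ID order.
    """
    for t in (classes.trait1, classes.trait2):
        if t not in predictions.columns:
            raise KeyError(f"trait {t!r} absent from predictions")
    excluded = classes.excluded_ids()
    taken: set[str] = set()
    result: dict[str, CrossPlan] = {}

    def pick(candidates: pd.Index, quota: int, cls: str) -> list[str]:
        chosen = []
        for h in candidates:
            if h in excluded or h in taken:
                continue
            chosen.append(h)
            taken.add(h)
            if len(chosen) == quota:
                return chosen
        raise ValueError(
            f"class {cls!r}: only {len(chosen)}/{quota} hybrids available "
            "after exclusions")

    def ranked(trait: str, high: bool) -> pd.Index:
        s = predictions[trait]
        q = s.quantile(1 - classes.outer_quantile if high
                       else classes.outer_quantile)
        band = s[s >= q] if high else s[s <= q]
        # best first; ties by hybrid ID
        order = band.sort_index().sort_values(
            ascending=not high, kind="stable")
        return order.index

    spec = [(f"high_{classes.trait1}", classes.trait1, True),
            (f"low_{classes.trait1}", classes.trait1, False),
            (f"high_{classes.trait2}", classes.trait2, True),
            (f"low_{classes.trait2}", classes.trait2, False)]
    for cls, trait, high in spec:
        ids = pick(ranked(trait, high), classes.quota, cls)
        result[cls] = _plan_from_ids(ids)

    lo, hi = classes.intermediate_band
    s1, s2 = predictions[classes.trait1], predictions[classes.trait2]
    in_band = ((s1 >= s1.quantile(lo)) & (s1 <= s1.quantile(hi))
               & (s2 >= s2.quantile(lo)) & (s2 <= s2.quantile(hi)))
    mid = predictions.index[in_band].sort_values()
    result["intermediate"] = _plan_from_ids(
        pick(mid, classes.quota, "intermediate"))
    return result


def _plan_from_ids(hybrid_ids: list[str]) -> CrossPlan:
    pairs = []
    for h in hybrid_ids:
        p1, _, p2 = h.partition("x")
        pairs.append((p1, p2))
    return CrossPlan(tuple(pairs))


def evaluate_selection(predicted: pd.DataFrame,
                       observed: pd.DataFrame) -> pd.Series:
    """Pearson r per trait over the developed (selected) hybrids.

    Selecting parents on a trait truncates its distribution, which
    inflates the correlation for that trait relative to unselected CV
    accuracy; interpret per-trait values with that in mind.
    """
    common = predicted.index.intersection(observed.index)
    if len(common) < 3:
        raise ValueError("need at least 3 hybrids with both values")
    out = {}
    for trait in predicted.columns:
        if trait in observed.columns:
            out[trait] = pearson_accuracy(predicted.loc[common, trait],
                                          observed.loc[common, trait])
    return pd.Series(out, name="r")
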