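"""Deterministic synthesis of expected F1 hybrid genotypes.

An F1 between two inbred parents is heterozygous wherever the parents carry
opposite homozygotes.  Residual parental heterozygosity is handled by an
*expectation* rule: any cross involving a heterozygous parent is coded
heterozygous (the expected/most-probable class, not a sampled gamete).
Stochastic gamete sampling lives in :mod:`hybridgs.synthetic_data`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .genotype_data import MISSING, GenotypeMatrix

__all__ = ["CrossPlan", "infer_f1_genotype", "synthesize_hybrids",
           "all_pairs", "sample_plan", "hybrid_id"]


def hybrid_id(p1: str, p2: str) -> str:
    """Canonical hybrid label: sorted parent names joined by 'x'."""
    a, b = sorted((str(p1), str(p2)))
    return f"{a}x{b}"


@dataclass(frozen=True)
class CrossPlan:
    """Unordered parent pairs (P1 x P2 == P2 x P1), no selfs, no duplicates."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        canon = []
        seen = set()
        for p1, p2 in self.pairs:
            if p1 == p2:
                raise ValueError(f"self-cross {p1!r} not allowed")
            key = tuple(sorted((str(p1), str(p2))))
            if key in seen:
                raise ValueError(f"duplicate cross {key}")
            seen.add(key)
            canon.append(key)
        object.__setattr__(self, "pairs", tuple(canon))

    def __len__(self) -> int:
        return len(self.pairs)

    def hybrid_ids(self) -> list[str]:
        return [hybrid_id(a, b) for a, b in self.pairs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["parent1", "parent2"])


def infer_f1_genotype(g1: int, g2: int) -> int:
    """Expected F1 call from two parental calls in {-1, 0, +1}.

    AA x AA -> AA; aa x aa -> aa; AA x aa -> Aa; any heterozygous parent
    -> Aa.  Symmetric in its arguments.
    """
    if g1 == MISSING or g2 == MISSING:
        raise ValueError("missing parental call; impute parents first")
    if g1 not in (-1, 0, 1) or g2 not in (-1, 0, 1):
        raise ValueError(f"invalid calls ({g1}, {g2})")
    if g1 == 0 or g2 == 0:
        return 0
    return g1 if g1 == g2 else 0


def _f1_calls(c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
    # vectorized form of infer_f1_genotype: equal homozygotes keep their
    # class, everything else (opposite homs, any het) is heterozygous
    out = np.zeros_like(c1)
    same_hom = (c1 == c2) & (c1 != 0)
    out[same_hom] = c1[same_hom]
    return out


def synthesize_hybrids(G_parents: GenotypeMatrix, plan: CrossPlan) -> GenotypeMatrix:
    """Expected F1 genotypes, one row per planned cross.

    Parents must be fully imputed; hybrid IDs are canonical ("P1xP2" with
    lexicographically ordered parents) and markers are inherited unchanged.
    """
    if G_parents.has_missing:
        raise ValueError("parent matrix contains missing calls; impute first")
    row = {ind: i for i, ind in enumerate(G_parents.individuals)}
    calls = np.empty((len(plan), G_parents.n_markers), dtype=np.int8)
    ids = []
    for k, (p1, p2) in enumerate(plan.pairs):
        if p1 not in row or p2 not in row:
            missing = p1 if p1 not in row else p2
            raise KeyError(f"unknown parent ID {missing!r}")
        calls[k] = _f1_calls(G_parents.calls[row[p1]], G_parents.calls[row[p2]])
        ids.append(hybrid_id(p1, p2))
    return GenotypeMatrix(ids, G_parents.markers.copy(), calls)


def all_pairs(ids: list[str]) -> CrossPlan:
    """All n(n-1)/2 unordered parent pairs in lexicographic order."""
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate parent IDs")
    if len(ids) < 2:
        raise ValueError("need at least 2 parents")
    return CrossPlan(tuple(combinations(sorted(ids), 2)))


def sample_plan(ids: list[str], k: int, seed: int) -> CrossPlan:
    """k distinct unordered pairs sampled uniformly without replacement."""
    full = all_pairs(ids)
    if k > len(full):
        raise ValueError(f"k={k} exceeds {len(full)} possible pairs")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(full), size=k, replace=False))
    return CrossPlan(tuple(full.pairs[i] for i in idx))
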