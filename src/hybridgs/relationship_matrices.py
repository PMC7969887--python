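"""Genomic relationship matrices and the heterozygosity design matrix.

The additive matrix **A** follows VanRaden's method 1:

    A = W W' / (2 * sum_m p_m (1 - p_m)),   W[i, m] = dosage_im - 2 p_m

with dosage = coded call + 1 in {0, 1, 2} and p_m the alt-allele frequency.

The dominance matrix **D** uses the dominance-deviation (Vitezica-style)
parameterization: per-genotype codes {aa, Aa, AA} -> {-2p^2, 2pq, -2q^2},
scaled by sum_m (2 p_m q_m)^2.

Allele frequencies default to the supplied matrix but can be provided
explicitly (e.g. training-population frequencies when building kinships
over a train+test union); the source is recorded on the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_data import GenotypeMatrix

__all__ = ["KinshipMatrix", "additive_kinship", "dominance_kinship",
           "heterozygosity_design"]


@dataclass
class KinshipMatrix:
    """n x n genomic relationship matrix with ordered individual labels."""

    ids: list[str]
    values: np.ndarray
    flavor: str  # "additive" | "dominance" | "rkhs"
    freq_source: str = "self"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, ids: list[str]) -> "KinshipMatrix":
        pos = {ind: i for i, ind in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids])
        return KinshipMatrix(list(ids), self.values[np.ix_(idx, idx)],
                             self.flavor, self.freq_source)

    def block(self, row_ids: list[str], col_ids: list[str]) -> np.ndarray:
        pos = {ind: i for i, ind in enumerate(self.ids)}
        r = np.array([pos[i] for i in row_ids])
        c = np.array([pos[i] for i in col_ids])
        return self.values[np.ix_(r, c)]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


def _frequencies(G: GenotypeMatrix, freqs: np.ndarray | None) -> np.ndarray:
    if G.has_missing:
        raise ValueError("genotype matrix has missing calls; impute first")
    if freqs is None:
        p = (G.calls + 1).mean(axis=0) / 2.0
    else:
        p = np.asarray(freqs, dtype=np.float64)
        if p.shape != (G.n_markers,):
            raise ValueError("frequency vector length mismatch")
    return p


def additive_kinship(G: GenotypeMatrix, freqs: np.ndarray | None = None,
                     freq_source: str = "self") -> KinshipMatrix:
    """VanRaden method-1 additive genomic relationship matrix."""
    p = _frequencies(G, freqs)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic markers")
    p = p[poly]
    W = (G.calls[:, poly] + 1.0) - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    return KinshipMatrix(list(G.individuals), W @ W.T / denom,
                         "additive", freq_source)


def dominance_kinship(G: GenotypeMatrix, freqs: np.ndarray | None = None,
                      freq_source: str = "self") -> KinshipMatrix:
    """Dominance-deviation genomic relationship matrix.

    Codes {aa, Aa, AA} -> {-2p^2, 2pq, -2q^2} per marker (p = alt-allele
    frequency, q = 1 - p), denominator sum_m (2 p q)^2.
    """
    p = _frequencies(G, freqs)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic markers")
    p = p[poly]
    q = 1.0 - p
    calls = G.calls[:, poly]
    Wd = np.where(calls == -1, -2.0 * p**2,
                  np.where(calls == 0, 2.0 * p * q, -2.0 * q**2))
    denom = np.sum((2.0 * p * q) ** 2)
    return KinshipMatrix(list(G.individuals), Wd @ Wd.T / denom,
                         "dominance", freq_source)


def heterozygosity_design(G: GenotypeMatrix, center: bool = False) -> np.ndarray:
    """Heterozygosity indicator matrix, coded {0, 1, 0} = {aa, Aa, AA}.

    The column-wise centered form is used when concatenated with the coded
    genotype matrix in marker-effect models with dominance.
    """
    if G.has_missing:
        raise ValueError("genotype matrix has missing calls; impute first")
    H = (G.calls == 0).astype(np.float64)
    if center:
        H = H - H.mean(axis=0)
    return H
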