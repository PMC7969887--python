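"""Within-population cross-validation of the eight model variants.

2-fold CV with shared folds across models and traits, reported as
mean (SD) Pearson accuracy per population x trait x model.  Replicates
and MCMC chains are scaled down from a production run so the full grid
finishes on a desk machine; pass --full for longer settings.
"""

import argparse
from pathlib import Path

import pandas as pd

from hybridgs import (
    ModelSpec,
    crossvalidate,
    impute_missing,
    make_cache,
    read_genotype_tsv,
)

RES = Path(__file__).resolve().parent.parent / "results"
SEED = 7

MODELS = [
    ModelSpec("GBLUP", "additive"),
    ModelSpec("GBLUP", "additive_dominant"),
    ModelSpec("BayesB", "additive"),
    ModelSpec("BayesB", "additive_dominant"),
    ModelSpec("BayesianLasso", "additive"),
    ModelSpec("BayesianLasso", "additive_dominant"),
    ModelSpec("RKHS"),
    ModelSpec("TreeEnsemble"),
]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--full", action="store_true",
                    help="50 replicates and long chains")
    ap.add_argument("--traits", default="fruit_hardness,pericarp_color")
    args = ap.parse_args()
    reps = 50 if args.full else 5
    mcmc = ({} if args.full
            else {"n_iter": 2000, "burn_in": 500, "thin": 2,
                  "n_trees": 200})

    rows = []
    for pop, gfile, pfile in [
            ("inbreds", "inbreds.tsv", "phenotypes_inbreds.csv"),
            ("test_f1", "test_f1.tsv", "phenotypes_f1.csv")]:
        G = impute_missing(read_genotype_tsv(RES / "sim" / gfile))
        ph = pd.read_csv(RES / "sim" / pfile, index_col=0)
        cache = make_cache(G)
        for trait in args.traits.split(","):
            y = ph[trait]
            for spec in MODELS:
                spec = ModelSpec(spec.family, spec.effects,
                                 dict(spec.hyperparameters, **mcmc))
                res = crossvalidate(y, G, spec, k=2, reps=reps, seed=SEED,
                                    cache=cache)
                rows.append({"population": pop, "trait": trait,
                             "model": spec.label,
                             "mean": round(res.mean, 3),
                             "sd": round(res.sd, 3)})
                print(f"{pop:8s} {trait:16s} {spec.label:8s} "
                      f"{res.summary()}")
    pd.DataFrame(rows).to_csv(RES / "cv_accuracy.csv", index=False)


if __name__ == "__main__":
    main()
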