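"""QC-filter the simulated inbred SNP panel.

Masks a realistic fraction of calls as missing, then applies the filter
sequence (missingness 0.1, MAF 0.05, heterozygote excess 0.25, LD
pruning r2 0.95 in 1 kb windows) followed by mode imputation, and writes
the filtered panel plus a rule-by-rule report.
"""

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from hybridgs import MISSING, GenotypeMatrix, filter_pipeline, read_genotype_tsv, write_genotype_tsv

RES = Path(__file__).resolve().parent.parent / "results"
SEED = 2024


def main() -> None:
    G = read_genotype_tsv(RES / "sim" / "inbreds.tsv")
    rng = np.random.default_rng(SEED)
    calls = G.calls.copy()
    calls[rng.random(calls.shape) < 0.03] = MISSING
    raw = GenotypeMatrix(G.individuals, G.markers.copy(), calls)

    filtered, report = filter_pipeline(raw, seed=SEED)
    write_genotype_tsv(filtered, RES / "inbreds_filtered.tsv")
    (RES / "filter_report.json").write_text(
        json.dumps(asdict(report), indent=2))

    print(f"{report.markers_in} markers in, {report.markers_out} retained")
    for rule in report.rule_order:
        print(f"  removed by {rule}: {report.removed_by_rule[rule]}")


if __name__ == "__main__":
    main()
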