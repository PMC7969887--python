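import numpy as np
import pandas as pd
import pytest

from hybridgs import GenotypeMatrix, SimConfig, simulate_breeding_population


def make_markers(n, chrom="chr1", spacing=1000):
    return pd.DataFrame(
        {"id": [f"m{i}" for i in range(n)],
         "chrom": chrom,
         "pos": np.arange(1, n * spacing + 1, spacing)[:n],
         "ref": "A", "alt": "T"})


def make_matrix(calls, individuals=None, markers=None, **marker_kw):
    """Small GenotypeMatrix from a nested list of coded calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if individuals is None:
        individuals = [f"L{i + 1}" for i in range(n)]
    if markers is None:
        markers = make_markers(m, **marker_kw)
    return GenotypeMatrix(individuals, markers, calls)


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete breeding simulation shared across tests."""
    cfg = SimConfig(n_markers=500, n_lines=50, intercross_size=80,
                    n_crosses=60, seed=3)
    return simulate_breeding_population(cfg)


@pytest.fixture(scope="session")
def study_sim():
    """Study-geometry simulation (105 lines, 275 crosses) at reduced
    marker count, shared by the heavier model tests."""
    cfg = SimConfig(n_markers=800, seed=17)
    return simulate_breeding_population(cfg)


TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
chr1\t100\tv1\tA\tT\t50\tPASS\t.\tGT\t0/0\t0/1\t1/1
chr1\t200\tv2\tG\tC\t50\tPASS\t.\tGT\t./.\t0/0\t1/1
chr1\t300\tv3\tA\tG,C\t50\tPASS\t.\tGT\t0/1\t0/2\t1/1
chr1\t400\tv4\tC\tT\t50\tPASS\t.\tGT\t1/1\t1/1\t0/0
chr1\t500\tv5\tT\tA\t50\tPASS\t.\tGT\t0/0\t0/0\t0/1
"""


@pytest.fixture()
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return str(path)
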