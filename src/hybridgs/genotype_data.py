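"""Biallelic SNP genotype matrices: loading, coding, filtering, summaries.

Genotypes are coded ``{-1, 0, +1} = {aa, Aa, AA}`` where ``A`` is the VCF
alternate allele (alt-dosage orientation: alt dosage 2 -> +1, 1 -> 0,
0 -> -1).  The orientation is an arbitrary but fixed convention; every
downstream statistic (kinships, marker-effect models, accuracies) is
invariant to flipping it consistently.  Missing calls are stored as
:data:`MISSING`.

The filter functions mirror a standard variant-QC sequence for inbred-line
panels: missingness, minor-allele frequency, heterozygote excess (which on
diploidized allopolyploid data enriches subgenome-specific loci), and
window-based LD pruning, followed by imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "FilterReport",
    "read_vcf",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "filter_missing",
    "filter_maf",
    "filter_het_excess",
    "ld_prune",
    "impute_missing",
    "filter_pipeline",
    "homozygosity",
    "expected_homozygosity",
]

#: Sentinel for a missing genotype call (int8 storage).
MISSING: int = -9

_VALID_CALLS = frozenset({-1, 0, 1, MISSING})

#: Columns of the marker metadata frame.
MARKER_COLUMNS = ("id", "chrom", "pos", "ref", "alt")


class EmptyMatrixError(ValueError):
    """Raised when a filter or reader leaves no markers."""


@dataclass
class GenotypeMatrix:
    """Individuals x markers matrix of coded biallelic SNP calls.

    Parameters
    ----------
    individuals
        Ordered unique individual labels (length n).
    markers
        DataFrame with columns ``id, chrom, pos, ref, alt`` (length m);
        positions are 1-based.
    calls
        ``(n, m)`` int8 array with entries in {-1, 0, 1, MISSING}.
    """

    individuals: list[str]
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.individuals = [str(i) for i in self.individuals]
        if self.calls.shape != (len(self.individuals), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.individuals)}, {len(self.markers)})"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual IDs")
        ids = self.markers["id"]
        if ids.duplicated().any():
            raise ValueError("duplicate marker IDs")
        bad = ~np.isin(self.calls, list(_VALID_CALLS))
        if bad.any():
            raise ValueError(f"invalid call values: {np.unique(self.calls[bad])}")
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_mask().any())

    def calls_float(self) -> np.ndarray:
        """Calls as float64 with missing entries as NaN."""
        out = self.calls.astype(np.float64)
        out[self.calls == MISSING] = np.nan
        return out

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset markers, preserving order."""
        index = np.asarray(index)
        return GenotypeMatrix(
            individuals=list(self.individuals),
            markers=self.markers.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index],
        )

    def take_individuals(self, ids: list[str]) -> "GenotypeMatrix":
        pos = {ind: i for i, ind in enumerate(self.individuals)}
        try:
            rows = [pos[i] for i in ids]
        except KeyError as e:
            raise KeyError(f"unknown individual ID: {e.args[0]}") from None
        return GenotypeMatrix(
            individuals=list(ids),
            markers=self.markers.copy(),
            calls=self.calls[rows, :],
        )

    def concat_individuals(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        """Stack two matrices over the same marker set."""
        if not self.markers["id"].equals(other.markers["id"]):
            raise ValueError("marker sets differ; cannot concatenate")
        return GenotypeMatrix(
            individuals=list(self.individuals) + list(other.individuals),
            markers=self.markers.copy(),
            calls=np.vstack([self.calls, other.calls]),
        )


@dataclass
class FilterReport:
    """Bookkeeping for a sequential marker-filter pipeline."""

    markers_in: int
    markers_out: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    rule_order: list[str] = field(default_factory=list)

    def record(self, rule: str, removed: int) -> None:
        self.removed_by_rule[rule] = self.removed_by_rule.get(rule, 0) + removed
        if rule not in self.rule_order:
            self.rule_order.append(rule)
        self.markers_out -= removed

    def check(self) -> None:
        total = sum(self.removed_by_rule.values())
        if self.markers_out != self.markers_in - total:
            raise AssertionError("FilterReport counts inconsistent")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str, biallelic_only: bool = True) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF into the coded representation.

    hom-ref -> -1, het -> 0, hom-alt -> +1, missing -> MISSING.
    Multiallelic records are dropped when ``biallelic_only`` (default).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except OSError as e:  # pragma: no cover - cyvcf2 error path
        raise IOError(f"cannot read VCF {path}: {e}") from e
    individuals = list(vcf.samples)
    rows: list[np.ndarray] = []
    meta: list[tuple] = []
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    code = np.array([-1, 0, MISSING, 1], dtype=np.int8)
    for var in vcf:
        if biallelic_only and len(var.ALT) != 1:
            continue
        if not var.ALT:
            continue
        rows.append(code[var.gt_types])
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        meta.append((vid, var.CHROM, var.POS, var.REF, var.ALT[0]))
    if not rows:
        raise EmptyMatrixError(f"no biallelic SNPs in {path}")
    markers = pd.DataFrame(meta, columns=list(MARKER_COLUMNS))
    return GenotypeMatrix(individuals, markers, np.array(rows, dtype=np.int8).T)


def read_genotype_tsv(path: str) -> GenotypeMatrix:
    """Read the plain-text genotype table (rows = markers, columns = id,
    chrom, pos, ref, alt, then one column per individual; cells in
    {-1, 0, 1, NA})."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    meta_cols = [c for c in MARKER_COLUMNS if c in df.columns]
    if "id" not in meta_cols or "chrom" not in meta_cols or "pos" not in meta_cols:
        raise ValueError("genotype TSV needs id, chrom, pos columns")
    markers = df[meta_cols].copy()
    for c in ("ref", "alt"):
        if c not in markers:
            markers[c] = "N"
    ind_cols = [c for c in df.columns if c not in meta_cols]
    calls = df[ind_cols].to_numpy(dtype=float).T
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    return GenotypeMatrix(ind_cols, markers[list(MARKER_COLUMNS)], calls)


def write_genotype_tsv(G: GenotypeMatrix, path: str) -> None:
    body = pd.DataFrame(G.calls.T.astype(object), columns=G.individuals)
    body = body.mask(body == MISSING, "NA")
    pd.concat([G.markers.reset_index(drop=True), body], axis=1).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Per-marker summaries
# ---------------------------------------------------------------------------

def _nonmissing_counts(G: GenotypeMatrix) -> np.ndarray:
    return (G.calls != MISSING).sum(axis=0)


def alt_allele_frequency(G: GenotypeMatrix) -> np.ndarray:
    """Alt-allele frequency per marker over non-missing calls."""
    obs = G.calls != MISSING
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        raise ValueError("marker with no observed calls")
    dosage = (G.calls + 1).astype(np.int64)  # {-1,0,1} -> {0,1,2}
    dosage[~obs] = 0
    return dosage.sum(axis=0) / (2.0 * n_obs)


def minor_allele_frequency(G: GenotypeMatrix) -> np.ndarray:
    p = alt_allele_frequency(G)
    return np.minimum(p, 1.0 - p)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def _apply(G: GenotypeMatrix, keep: np.ndarray, rule: str,
           report: FilterReport | None) -> tuple[GenotypeMatrix, FilterReport]:
    if report is None:
        report = FilterReport(markers_in=G.n_markers, markers_out=G.n_markers)
    report.record(rule, int((~keep).sum()))
    if not keep.any():
        raise EmptyMatrixError(f"all markers removed by rule {rule!r}")
    return G.take_markers(np.flatnonzero(keep)), report


def filter_missing(G: GenotypeMatrix, max_missing_fraction: float = 0.1,
                   report: FilterReport | None = None):
    """Drop markers whose missing-call fraction exceeds the threshold."""
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    frac = (G.calls == MISSING).mean(axis=0)
    return _apply(G, frac <= max_missing_fraction, "missing", report)


def filter_maf(G: GenotypeMatrix, min_maf: float = 0.05,
               report: FilterReport | None = None):
    """Drop markers with minor-allele frequency below ``min_maf``."""
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    return _apply(G, minor_allele_frequency(G) >= min_maf, "maf", report)


def filter_het_excess(G: GenotypeMatrix, max_het: float = 0.25,
                      report: FilterReport | None = None):
    """Drop markers whose heterozygote frequency is strictly above ``max_het``.

    On diploidized allopolyploid panels, persistent heterozygote excess marks
    loci that are probably not subgenome-specific; the boundary value is
    retained (strict inequality).
    """
    if not 0 <= max_het <= 1:
        raise ValueError("max_het must be in [0, 1]")
    obs = G.calls != MISSING
    n_obs = obs.sum(axis=0)
    het = ((G.calls == 0) & obs).sum(axis=0) / np.maximum(n_obs, 1)
    return _apply(G, het <= max_het, "het_excess", report)


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared correlation over pairwise-complete calls; r2 = 0 if < 3
    complete pairs or either column is constant on the complete set."""
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        return 0.0
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def ld_prune(G: GenotypeMatrix, max_r2: float = 0.95, window_bp: int = 1000,
             report: FilterReport | None = None):
    """Window-based LD pruning, keeping the earlier-positioned marker.

    Scans each chromosome left to right; a marker is removed when its squared
    genotype correlation with any retained marker within ``window_bp``
    upstream exceeds ``max_r2``.  Requires markers sorted by
    (chromosome, position).
    """
    chrom = G.markers["chrom"].to_numpy()
    pos = G.markers["pos"].to_numpy()
    for c in pd.unique(chrom):
        p = pos[chrom == c]
        if np.any(np.diff(p) < 0):
            raise ValueError("markers must be sorted by (chromosome, position)")
    X = G.calls_float()
    keep = np.ones(G.n_markers, dtype=bool)
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        retained: list[int] = []
        for j in idx:
            drop = False
            for i in reversed(retained):
                if pos[j] - pos[i] > window_bp:
                    break
                if _pairwise_r2(X[:, i], X[:, j]) > max_r2:
                    drop = True
                    break
            if drop:
                keep[j] = False
            else:
                retained.append(j)
    return _apply(G, keep, "ld_prune", report)


def impute_missing(G: GenotypeMatrix, method: str = "mode",
                   seed: int = 0) -> GenotypeMatrix:
    """Fill missing calls per marker.

    ``mode``: most frequent observed call (ties broken toward the smaller
    coded value, deterministically).  ``marker_mean_rounded``: mean of
    observed calls rounded to the nearest coded class.  Both are
    deterministic; ``seed`` is accepted for interface stability and recorded
    use by stochastic imputers.
    """
    if method not in ("mode", "marker_mean_rounded"):
        raise ValueError(f"unknown imputation method {method!r}")
    if not G.has_missing:
        return G
    calls = G.calls.copy()
    miss = calls == MISSING
    for j in np.flatnonzero(miss.any(axis=0)):
        col = calls[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            raise ValueError(
                f"marker {G.markers['id'].iloc[j]!r} has no observed calls"
            )
        if method == "mode":
            vals, counts = np.unique(obs, return_counts=True)
            fill = vals[np.argmax(counts)]  # np.unique sorts: tie -> smaller
        else:
            fill = int(np.clip(np.rint(obs.mean()), -1, 1))
        col[col == MISSING] = fill
    return replace(G, calls=calls)


def filter_pipeline(
    G: GenotypeMatrix,
    max_missing_fraction: float = 0.1,
    min_maf: float = 0.05,
    max_het: float = 0.25,
    ld_max_r2: float = 0.95,
    ld_window_bp: int = 1000,
    impute_method: str = "mode",
    seed: int = 0,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Full QC sequence: missing -> MAF -> het-excess -> LD prune -> impute."""
    report = FilterReport(markers_in=G.n_markers, markers_out=G.n_markers)
    G, report = filter_missing(G, max_missing_fraction, report)
    G, report = filter_maf(G, min_maf, report)
    G, report = filter_het_excess(G, max_het, report)
    G, report = ld_prune(G, ld_max_r2, ld_window_bp, report)
    G = impute_missing(G, impute_method, seed)
    report.check()
    return G, report


# ---------------------------------------------------------------------------
# Homozygosity
# ---------------------------------------------------------------------------

def homozygosity(G: GenotypeMatrix) -> pd.Series:
    """Per-individual fraction of homozygous calls (over non-missing calls)."""
    obs = G.calls != MISSING
    n_obs = obs.sum(axis=1)
    if (n_obs == 0).any():
        raise ValueError("individual with no observed calls")
    hom = ((G.calls == -1) | (G.calls == 1)).sum(axis=1)
    return pd.Series(hom / n_obs, index=G.individuals, name="homozygosity")


def expected_homozygosity(selfing_generations: int) -> float:
    """Expected homozygosity after t generations of selfing from a fully
    heterozygous locus: 1 - (1/2)**t."""
    if selfing_generations < 0:
        raise ValueError("selfing_generations must be >= 0")
    return 1.0 - 0.5 ** selfing_generations
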