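"""Model evaluation: replicated k-fold cross-validation, across-population
prediction, Pearson accuracy, and PCA overlay of populations.

The CV protocol mirrors the standard genomic-selection workflow: 2-fold
cross-validation replicated 50 times, with the fold partition a function
of (seed, replicate) only, so every model x trait combination is scored
on identical folds.  Accuracy is the Pearson correlation between pooled
out-of-fold predictions and observed phenotypes, one value per
replicate, reported as mean (SD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_data import GenotypeMatrix
from .prediction_models import (
    ModelSpec,
    fit_gblup,
    fit_markers_bayesB,
    fit_markers_blasso,
    fit_rkhs,
    fit_tree_ensemble,
    gaussian_kernel,
    predict_gblup,
    predict_markers,
)
from .relationship_matrices import (
    additive_kinship,
    dominance_kinship,
    heterozygosity_design,
)

__all__ = ["CVResult", "AcrossPopResult", "pearson_accuracy",
           "fold_assignments", "crossvalidate", "across_population",
           "pca_overlay", "fit_and_predict"]


@dataclass
class CVResult:
    trait: str
    model: str
    accuracies: list[float]
    folds: int
    replicates: int
    seed: int
    n_missing: int = 0

    @property
    def valid(self) -> np.ndarray:
        return np.array([a for a in self.accuracies if np.isfinite(a)])

    @property
    def mean(self) -> float:
        return float(self.valid.mean())

    @property
    def sd(self) -> float:
        return float(self.valid.std(ddof=1)) if len(self.valid) > 1 else 0.0

    def summary(self) -> str:
        return f"{self.mean:.3f} ({self.sd:.3f})"


@dataclass
class AcrossPopResult:
    train: str
    test: str
    trait: str
    model: str
    accuracy: float


def pearson_accuracy(predicted: pd.Series, observed: pd.Series) -> float:
    """Product-moment correlation over the ID intersection."""
    common = predicted.index.intersection(observed.index)
    if len(common) < 3:
        raise ValueError("need at least 3 paired values")
    p = predicted.loc[common].to_numpy(dtype=float)
    o = observed.loc[common].to_numpy(dtype=float)
    if not (np.isfinite(p).all() and np.isfinite(o).all()):
        raise ValueError("non-finite values in accuracy computation")
    if p.std() == 0 or o.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(p, o)[0, 1])


def fold_assignments(ids: list[str], k: int, seed: int,
                     replicate: int) -> list[list[str]]:
    """Deterministic k-fold partition, a function of (seed, replicate)
    only.  Replicate i uses seed + i, so adding replicates never changes
    earlier folds."""
    rng = np.random.default_rng(seed + replicate)
    perm = rng.permutation(len(ids))
    return [[ids[i] for i in chunk] for chunk in np.array_split(perm, k)]


# ---------------------------------------------------------------------------
# Model dispatch
# ---------------------------------------------------------------------------

@dataclass
class _DesignCache:
    """Per-population designs shared across folds and models."""

    G: GenotypeMatrix
    kinships: dict = field(default_factory=dict)

    def kinship(self, flavor: str, theta: float = 1.0):
        key = (flavor, theta)
        if key not in self.kinships:
            if flavor == "additive":
                self.kinships[key] = additive_kinship(self.G)
            elif flavor == "dominance":
                self.kinships[key] = dominance_kinship(self.G)
            elif flavor == "rkhs":
                self.kinships[key] = gaussian_kernel(
                    self.G.calls.astype(float), self.G.individuals, theta)
            else:
                raise ValueError(flavor)
        return self.kinships[key]

    def row_index(self, ids: list[str]) -> np.ndarray:
        pos = {ind: i for i, ind in enumerate(self.G.individuals)}
        return np.array([pos[i] for i in ids])


def fit_and_predict(spec: ModelSpec, y_train: pd.Series, cache: _DesignCache,
                    test_ids: list[str]) -> pd.Series:
    """Train one model variant and predict the test individuals.

    ``cache`` wraps the genotype matrix over the union of training and
    test individuals (kinships and kernels are built once and reused).
    ``spec`` may also be a callable ``(y_train, cache, test_ids) ->
    Series`` for custom or reference models."""
    if callable(spec) and not isinstance(spec, ModelSpec):
        return spec(y_train, cache, test_ids)
    dominant = spec.effects == "additive_dominant"
    if spec.family == "GBLUP":
        A = cache.kinship("additive")
        D = cache.kinship("dominance") if dominant else None
        fit = fit_gblup(y_train, A, D, engine=spec.hyper("engine"),
                        spec=spec)
        return predict_gblup(fit, A, D, test_ids)
    if spec.family == "RKHS":
        K = cache.kinship("rkhs", spec.hyper("theta"))
        fit = fit_rkhs(y_train, K, spec=spec)
        return predict_gblup(fit, K, None, test_ids)
    train_rows = cache.row_index(list(y_train.index))
    test_rows = cache.row_index(test_ids)
    X = cache.G.calls.astype(np.float64)
    if spec.family == "TreeEnsemble":
        fit = fit_tree_ensemble(y_train, X[train_rows], spec=spec)
        pred = fit.model.predict(X[test_rows])
        return pd.Series(pred, index=test_ids, name=y_train.name)
    H = heterozygosity_design(cache.G) if dominant else None
    X_het_tr = H[train_rows] if dominant else None
    if spec.family == "BayesB":
        fit = fit_markers_bayesB(y_train, X[train_rows], X_het_tr, spec=spec)
    elif spec.family == "BayesianLasso":
        fit = fit_markers_blasso(y_train, X[train_rows], X_het_tr, spec=spec)
    else:  # pragma: no cover
        raise ValueError(f"unknown family {spec.family!r}")
    X_het_te = H[test_rows] if dominant else None
    return predict_markers(fit, X[test_rows], X_het_te, ids=test_ids)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def crossvalidate(y: pd.Series, G: GenotypeMatrix, spec: ModelSpec,
                  k: int = 2, reps: int = 50, seed: int = 0,
                  cache: _DesignCache | None = None) -> CVResult:
    """Replicated k-fold CV; one pooled-prediction Pearson r per replicate.

    Undefined correlations (constant predictions or constant y within a
    replicate) are recorded as missing with a warning and excluded from
    the mean/SD.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = [str(i) for i in y.index]
    if len(ids) < 2 * k:
        raise ValueError("need at least 2k individuals")
    if cache is None:
        cache = _DesignCache(G.take_individuals(ids))
    accuracies: list[float] = []
    n_missing = 0
    for rep in range(reps):
        folds = fold_assignments(ids, k, seed, rep)
        pred = pd.Series(np.nan, index=ids, dtype=float, name=y.name)
        for fold in folds:
            train_ids = [i for i in ids if i not in set(fold)]
            p = fit_and_predict(spec, y.loc[train_ids], cache, list(fold))
            pred.loc[fold] = p.loc[fold]
        try:
            accuracies.append(pearson_accuracy(pred, y))
        except ValueError as e:
            warnings.warn(f"replicate {rep}: accuracy undefined ({e})")
            accuracies.append(float("nan"))
            n_missing += 1
    label = spec.label if isinstance(spec, ModelSpec) else getattr(
        spec, "__name__", "custom")
    return CVResult(trait=str(y.name), model=label,
                    accuracies=accuracies, folds=k, replicates=reps,
                    seed=seed, n_missing=n_missing)


def make_cache(G: GenotypeMatrix) -> _DesignCache:
    """Public constructor for the shared design cache."""
    return _DesignCache(G)


# ---------------------------------------------------------------------------
# Across-population prediction
# ---------------------------------------------------------------------------

def across_population(y_train: pd.Series, G_train: GenotypeMatrix,
                      G_test: GenotypeMatrix, y_test: pd.Series,
                      spec: ModelSpec,
                      train_label: str = "train",
                      test_label: str = "test") -> AcrossPopResult:
    """Train in one population, measure Pearson accuracy in another.

    Marker sets must be identical.  Kinships over the train+test union use
    training-population allele frequencies, so the test population is
    scored relative to the training reference.
    """
    if not G_train.markers["id"].equals(G_test.markers["id"]):
        raise ValueError("marker sets differ between populations")
    if set(G_train.individuals) & set(G_test.individuals):
        # degenerate overlap (e.g. train = test): relabel the test copy
        rename = {i: f"{i}@{test_label}" for i in G_test.individuals}
        G_test = GenotypeMatrix(
            [rename[i] for i in G_test.individuals],
            G_test.markers.copy(), G_test.calls)
        y_test = y_test.rename(index=rename)
    G_union = G_train.concat_individuals(G_test)
    cache = _DesignCache(G_union)
    if spec.family in ("GBLUP", "RKHS"):
        p_train = (G_train.calls + 1).mean(axis=0) / 2.0
        if spec.family == "GBLUP":
            cache.kinships[("additive", 1.0)] = additive_kinship(
                G_union, freqs=p_train, freq_source=train_label)
            if spec.effects == "additive_dominant":
                cache.kinships[("dominance", 1.0)] = dominance_kinship(
                    G_union, freqs=p_train, freq_source=train_label)
    test_ids = [str(i) for i in y_test.index]
    pred = fit_and_predict(spec, y_train, cache, test_ids)
    acc = pearson_accuracy(pred, y_test)
    return AcrossPopResult(train=train_label, test=test_label,
                           trait=str(y_train.name), model=spec.label,
                           accuracy=acc)


# ---------------------------------------------------------------------------
# PCA overlay
# ---------------------------------------------------------------------------

def pca_overlay(G_combined: GenotypeMatrix, groups: list[str],
                n_components: int = 10):
    """Centered coded-genotype PCA with group labels for plotting.

    Returns (coordinates DataFrame with a 'group' column, variance
    fractions per component).
    """
    if G_combined.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if len(groups) != G_combined.n_individuals:
        raise ValueError("one group label per individual required")
    X = G_combined.calls.astype(np.float64)
    X = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(S**2))
    k = min(n_components, len(S))
    coords = U[:, :k] * S[:k]
    frac = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    df = pd.DataFrame(coords, index=G_combined.individuals,
                      columns=[f"PC{i + 1}" for i in range(k)])
    df["group"] = groups
    return df, frac
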