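"""Genomic prediction models: GBLUP (A / A+D), BayesB, Bayesian Lasso,
Gaussian-kernel RKHS regression, and a random-forest baseline.

The linear mixed model underlying GBLUP is

    y = 1 mu + g_A + g_D + e,
    g_A ~ N(0, A sigma2_A),  g_D ~ N(0, D sigma2_D),  e ~ N(0, I sigma2_e)

with A, D genomic relationship matrices.  The additive-only model drops
g_D.  Variance components are estimated by REML (default; deterministic)
or by a seeded Gibbs sampler; genetic values are BLUPs, and predictions
for unphenotyped individuals are the mixed-model conditional means

    g_hat_test = sigma2 * K[test, train] @ V^{-1} (y - mu).

Marker-effect models (BayesB, Bayesian Lasso) regress y on the coded
{-1,0,1} genotype matrix, optionally concatenated with the centered
{0,1,0} heterozygosity matrix so dominance deviations enter as separate
effects.  RKHS replaces A by a Gaussian kernel of genotype distances and
reuses the single-kinship REML path.  The random forest delegates to
scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize, minimize_scalar

from .relationship_matrices import KinshipMatrix

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "ModelFit",
    "fit_gblup",
    "predict_gblup",
    "fit_markers_bayesB",
    "fit_markers_blasso",
    "predict_markers",
    "gaussian_kernel",
    "fit_rkhs",
    "fit_tree_ensemble",
]

_FAMILIES = ("GBLUP", "BayesB", "BayesianLasso", "RKHS", "TreeEnsemble")

#: default MCMC settings, in the style of the Bayesian GS packages
DEFAULT_HYPERPARAMETERS: dict[str, Any] = {
    "n_iter": 12_000,
    "burn_in": 2_000,
    "thin": 5,
    "pi": 0.95,          # BayesB prior exclusion probability
    "df_beta": 5.0,      # slab scaled-inv-chi2 degrees of freedom
    "df_e": 5.0,
    "r2": 0.5,           # prior proportion of variance assigned to markers
    "theta": 1.0,        # RKHS bandwidth multiplier
    "n_trees": 500,
    "seed": 0,
    "engine": "REML",    # variance-component engine for kinship models
}


@dataclass(frozen=True)
class ModelSpec:
    """A prediction-model variant: family x effect structure.

    ``effects="additive_dominant"`` is rejected for RKHS and TreeEnsemble,
    which capture non-additive structure through the kernel / trees
    themselves.
    """

    family: str
    effects: str = "additive"
    hyperparameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.effects not in ("additive", "additive_dominant"):
            raise ValueError(f"unknown effects {self.effects!r}")
        if self.effects == "additive_dominant" and self.family in (
                "RKHS", "TreeEnsemble"):
            raise ValueError(
                f"{self.family} does not take an explicit dominance term")

    def hyper(self, key: str):
        return self.hyperparameters.get(key, DEFAULT_HYPERPARAMETERS[key])

    @property
    def label(self) -> str:
        suffix = {"additive": "A", "additive_dominant": "AD"}[self.effects]
        if self.family in ("RKHS", "TreeEnsemble"):
            return self.family
        short = {"GBLUP": "GBLUP", "BayesB": "BB", "BayesianLasso": "BL"}
        return f"{short[self.family]}-{suffix}"


@dataclass
class VarianceComponents:
    sigma2_A: float
    sigma2_e: float
    sigma2_D: float | None = None

    def __post_init__(self) -> None:
        if self.sigma2_A < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be non-negative")
        if self.sigma2_D is not None and self.sigma2_D < 0:
            raise ValueError("variance components must be non-negative")


@dataclass
class ModelFit:
    """A trained prediction model.

    For kinship models (GBLUP/RKHS) the fit keeps ``alpha = V^{-1}(y - mu)``
    over the training individuals, so conditional-mean prediction only
    needs kinship blocks.  For marker models it keeps posterior-mean
    effects and the centering vectors of the design matrices.
    """

    spec: ModelSpec
    mu: float
    train_ids: list[str]
    fitted_values: pd.Series
    components: VarianceComponents | None = None
    alpha: np.ndarray | None = None            # kinship models
    beta_add: np.ndarray | None = None         # marker models
    beta_het: np.ndarray | None = None
    center_add: np.ndarray | None = None
    center_het: np.ndarray | None = None
    kernel: KinshipMatrix | None = None        # RKHS full kernel
    model: Any = None                          # delegated learner (forest)
    diagnostics: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# REML, single kinship (eigendecomposition profile likelihood)
# ---------------------------------------------------------------------------

def _reml_single(y: np.ndarray, K: np.ndarray):
    """Profile REML for y = 1 mu + g + e, g ~ N(0, K sigma2_g).

    Eigendecompose K once; for each genetic:residual variance ratio
    ``lam`` the covariance is diagonal in the rotated basis, so the REML
    log-likelihood is evaluated in O(n) and maximised over log10(lam).
    Returns (mu, sigma2_g, sigma2_e, reml_loglik).
    """
    n = y.shape[0]
    s, U = eigh(K)
    s = np.clip(s, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def neg_ll(log10_lam: float) -> float:
        lam = 10.0 ** log10_lam
        d = lam * s + 1.0
        xdx = np.sum(xt * xt / d)
        beta = np.sum(xt * yt / d) / xdx
        r = yt - xt * beta
        rss = np.sum(r * r / d)
        sigma2_e = rss / (n - 1)
        ll = -0.5 * ((n - 1) * np.log(sigma2_e) + np.sum(np.log(d))
                     + np.log(xdx) + (n - 1))
        return -ll

    res = minimize_scalar(neg_ll, bounds=(-8.0, 8.0), method="bounded",
                          options={"xatol": 1e-8})
    lam = 10.0 ** res.x
    d = lam * s + 1.0
    xdx = np.sum(xt * xt / d)
    mu = np.sum(xt * yt / d) / xdx
    r = yt - xt * mu
    sigma2_e = float(np.sum(r * r / d) / (n - 1))
    sigma2_g = float(lam * sigma2_e)
    return float(mu), sigma2_g, sigma2_e, -res.fun


# ---------------------------------------------------------------------------
# REML, two kinships (direct likelihood maximisation)
# ---------------------------------------------------------------------------

def _reml_loglik(y: np.ndarray, variances: list[float],
                 kinships: list[np.ndarray]) -> float:
    """REML log-likelihood of y = 1 mu + sum_k g_k + e (up to a constant)."""
    n = y.shape[0]
    V = variances[-1] * np.eye(n)
    for v, K in zip(variances[:-1], kinships):
        V = V + v * K
    V[np.diag_indices_from(V)] += 1e-8  # numerical ridge for the solve
    c, low = cho_factor(V, lower=True)
    logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
    ones = np.ones(n)
    Vi_y = cho_solve((c, low), y)
    Vi_1 = cho_solve((c, low), ones)
    xvx = ones @ Vi_1
    mu = (ones @ Vi_y) / xvx
    r = y - mu
    quad = r @ cho_solve((c, low), r)
    return float(-0.5 * (logdet_V + np.log(xvx) + quad))


def _reml_multi(y: np.ndarray, kinships: list[np.ndarray]):
    """Nelder-Mead REML over log variances for one or two kinships plus
    residual.  Returns (mu, [sigma2_k...], sigma2_e, loglik)."""
    var_y = float(np.var(y))
    k = len(kinships)
    x0 = np.log(np.full(k + 1, var_y / (k + 1) + 1e-8))

    def neg(pars: np.ndarray) -> float:
        return -_reml_loglik(y, list(np.exp(pars)), kinships)

    res = minimize(neg, x0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000})
    if not res.success and res.fun > neg(x0):  # pragma: no cover
        raise RuntimeError(f"REML did not converge: {res.message}")
    variances = list(np.exp(res.x))
    n = y.shape[0]
    V = variances[-1] * np.eye(n)
    for v, K in zip(variances[:-1], kinships):
        V = V + v * K
    V[np.diag_indices_from(V)] += 1e-8
    c, low = cho_factor(V, lower=True)
    ones = np.ones(n)
    Vi_1 = cho_solve((c, low), ones)
    mu = float((ones @ cho_solve((c, low), y)) / (ones @ Vi_1))
    return mu, variances[:-1], variances[-1], -res.fun


# ---------------------------------------------------------------------------
# Gibbs engine for kinship models
# ---------------------------------------------------------------------------

def _gibbs_kinship(y: np.ndarray, kinships: list[np.ndarray], n_iter: int,
                   burn_in: int, thin: int, seed: int, df: float = 5.0,
                   r2: float = 0.5):
    """Seeded Gibbs sampler for the kinship mixed model.

    Each genetic term is rotated into the eigenbasis of its kinship
    (positive eigenvalues only), where its full conditional is diagonal.
    Returns posterior means and per-draw variance-component samples.
    """
    rng = np.random.default_rng(seed)
    n = y.shape[0]
    var_y = float(np.var(y))
    bases = []
    for K in kinships:
        s, U = eigh(K)
        keep = s > max(1e-10, 1e-10 * s.max())
        bases.append((s[keep], U[:, keep]))

    nk = len(kinships)
    # scaled-inv-chi2 prior scales split variance evenly across terms
    S_g = [var_y * r2 / max(nk, 1) * (df + 2) / df /
           max(np.mean(np.diag(K)), 1e-12) for K in kinships]
    S_e = var_y * (1 - r2) * (df + 2) / df

    mu = float(np.mean(y))
    a = [np.zeros(len(s)) for s, _ in bases]          # rotated genetic values
    g = [np.zeros(n) for _ in bases]
    sigma2_g = [var_y * r2 / max(nk, 1) + 1e-12] * nk
    sigma2_e = var_y * (1 - r2) + 1e-12

    keep_iters = range(burn_in, n_iter, thin)
    n_keep = len(keep_iters)
    samples = {"sigma2_g": np.zeros((n_keep, nk)), "sigma2_e": np.zeros(n_keep),
               "mu": np.zeros(n_keep)}
    g_sum = np.zeros((nk, n))
    kept = 0
    for it in range(n_iter):
        resid_all = y - mu - np.sum(g, axis=0) if nk else y - mu
        mu = float(np.mean(resid_all + mu) +
                   rng.standard_normal() * np.sqrt(sigma2_e / n))
        for k in range(nk):
            s, U = bases[k]
            others = sum(g[j] for j in range(nk) if j != k)
            ystar = y - mu - others
            yt = U.T @ ystar
            prec = 1.0 / (s * sigma2_g[k]) + 1.0 / sigma2_e
            mean = (yt / sigma2_e) / prec
            a[k] = mean + rng.standard_normal(len(s)) / np.sqrt(prec)
            g[k] = U @ a[k]
            ss = float(np.sum(a[k] ** 2 / s))
            dof = df + len(s)
            sigma2_g[k] = (df * S_g[k] + ss) / rng.chisquare(dof)
        resid = y - mu - (np.sum(g, axis=0) if nk else 0.0)
        sse = float(resid @ resid)
        sigma2_e = (df * S_e + sse) / rng.chisquare(df + n)

        if it >= burn_in and (it - burn_in) % thin == 0:
            samples["sigma2_g"][kept] = sigma2_g
            samples["sigma2_e"][kept] = sigma2_e
            samples["mu"][kept] = mu
            g_sum += np.asarray(g)
            kept += 1

    post = {
        "mu": float(samples["mu"].mean()),
        "sigma2_g": samples["sigma2_g"].mean(axis=0),
        "sigma2_e": float(samples["sigma2_e"].mean()),
        "g": g_sum / kept,
        "samples": samples,
    }
    return post


# ---------------------------------------------------------------------------
# GBLUP
# ---------------------------------------------------------------------------

def _align_kinship(K: KinshipMatrix, ids: list[str]) -> np.ndarray:
    missing = set(ids) - set(K.ids)
    if missing:
        raise KeyError(f"IDs absent from kinship: {sorted(missing)[:5]}")
    return K.submatrix(list(ids)).values


def _check_psd(K: KinshipMatrix, tol: float = 1e-6) -> None:
    lam_min = K.min_eigenvalue()
    scale = max(abs(np.diag(K.values)).max(), 1.0)
    if lam_min < -tol * scale:
        raise ValueError(
            f"kinship ({K.flavor}) not PSD: min eigenvalue {lam_min:.3e}")


def fit_gblup(y: pd.Series, A: KinshipMatrix, D: KinshipMatrix | None = None,
              engine: str = "REML", spec: ModelSpec | None = None) -> ModelFit:
    """Fit the GBLUP mixed model by REML (default) or Gibbs sampling.

    ``y`` is indexed by individual ID; kinships may cover a superset.
    With ``D`` supplied the additive-plus-dominance model is fitted.
    """
    if spec is None:
        spec = ModelSpec("GBLUP", "additive_dominant" if D is not None
                         else "additive")
    ids = [str(i) for i in y.index]
    yv = np.asarray(y, dtype=np.float64)
    if not np.isfinite(yv).all():
        raise ValueError("phenotypes must be finite")
    _check_psd(A)
    A_tr = _align_kinship(A, ids)
    kinships = [A_tr]
    if D is not None:
        _check_psd(D)
        kinships.append(_align_kinship(D, ids))

    diagnostics: dict[str, Any] = {"engine": engine}
    if engine == "REML":
        if D is None:
            mu, s2A, s2e, ll = _reml_single(yv, A_tr)
            var_g = [s2A]
        else:
            mu, var_g, s2e, ll = _reml_multi(yv, kinships)
        diagnostics["reml_loglik"] = ll
    elif engine == "Gibbs":
        post = _gibbs_kinship(
            yv, kinships,
            n_iter=spec.hyper("n_iter"), burn_in=spec.hyper("burn_in"),
            thin=spec.hyper("thin"), seed=spec.hyper("seed"),
            df=spec.hyper("df_e"), r2=spec.hyper("r2"))
        mu = post["mu"]
        var_g = list(post["sigma2_g"])
        s2e = post["sigma2_e"]
        diagnostics["samples"] = post["samples"]
        diagnostics["n_kept"] = len(post["samples"]["sigma2_e"])
    else:
        raise ValueError(f"unknown engine {engine!r}")

    vc = VarianceComponents(
        sigma2_A=max(var_g[0], 0.0), sigma2_e=max(s2e, 1e-12),
        sigma2_D=(max(var_g[1], 0.0) if D is not None else None))

    n = len(ids)
    V = vc.sigma2_e * np.eye(n) + vc.sigma2_A * A_tr
    if D is not None:
        V += vc.sigma2_D * kinships[1]
    V[np.diag_indices_from(V)] += 1e-8
    c, low = cho_factor(V, lower=True)
    alpha = cho_solve((c, low), yv - mu)

    G_total = vc.sigma2_A * A_tr
    if D is not None:
        G_total = G_total + vc.sigma2_D * kinships[1]
    fitted = pd.Series(mu + G_total @ alpha, index=ids, name=y.name)
    return ModelFit(spec=spec, mu=mu, train_ids=ids, fitted_values=fitted,
                    components=vc, alpha=alpha, diagnostics=diagnostics)


def predict_gblup(fit: ModelFit, A_full: KinshipMatrix,
                  D_full: KinshipMatrix | None = None,
                  test_ids: list[str] | None = None) -> pd.Series:
    """Conditional-mean (BLUP) prediction for unphenotyped individuals.

    ``A_full`` (and ``D_full`` for additive-dominant fits) must cover both
    the training and test individuals.
    """
    if test_ids is None:
        test_ids = [i for i in A_full.ids if i not in set(fit.train_ids)]
    test_ids = [str(i) for i in test_ids]
    vc = fit.components
    if vc is None or fit.alpha is None:
        raise ValueError("fit is not a kinship model")
    if (vc.sigma2_D is not None) != (D_full is not None):
        raise ValueError("dominance kinship must match the fitted model")
    cross = vc.sigma2_A * A_full.block(test_ids, fit.train_ids)
    if D_full is not None:
        cross = cross + vc.sigma2_D * D_full.block(test_ids, fit.train_ids)
    return pd.Series(fit.mu + cross @ fit.alpha, index=test_ids,
                     name=fit.fitted_values.name)


# ---------------------------------------------------------------------------
# Marker-effect models
# ---------------------------------------------------------------------------

def _prepare_designs(y, X_add, X_het):
    ids = [str(i) for i in y.index]
    yv = np.asarray(y, dtype=np.float64)
    X_add = np.ascontiguousarray(X_add, dtype=np.float64)
    if X_add.shape[0] != len(ids):
        raise ValueError("X_add rows must match y")
    c_add = X_add.mean(axis=0)
    Xc = X_add - c_add
    c_het = None
    if X_het is not None:
        X_het = np.ascontiguousarray(X_het, dtype=np.float64)
        if X_het.shape[0] != len(ids):
            raise ValueError("X_het rows must match y")
        c_het = X_het.mean(axis=0)
        Xc = np.hstack([Xc, X_het - c_het])
    return ids, yv, np.ascontiguousarray(Xc), c_add, c_het, X_add.shape[1]


def fit_markers_bayesB(y: pd.Series, X_add: np.ndarray,
                       X_het: np.ndarray | None = None,
                       spec: ModelSpec | None = None) -> ModelFit:
    """BayesB: spike-and-slab whole-genome regression via Gibbs sampling."""
    from ._samplers import bayes_b_chain

    if spec is None:
        spec = ModelSpec("BayesB", "additive_dominant" if X_het is not None
                         else "additive")
    n_iter, burn_in = spec.hyper("n_iter"), spec.hyper("burn_in")
    if n_iter <= burn_in:
        raise ValueError("chain length must exceed burn-in")
    ids, yv, Xc, c_add, c_het, m_add = _prepare_designs(y, X_add, X_het)
    pi = spec.hyper("pi")
    nu = spec.hyper("df_beta")
    var_y = float(np.var(yv)) + 1e-12
    sum_var_x = float(np.sum(Xc.var(axis=0))) + 1e-12
    # data-scaled slab prior: markers explain r2 of var(y) a priori
    s2_beta = var_y * spec.hyper("r2") / ((1.0 - pi) * sum_var_x) \
        * (nu - 2.0) / nu
    s2_e = var_y * (1.0 - spec.hyper("r2"))
    mu, beta, incl, s2e_post = bayes_b_chain(
        Xc, yv, pi, nu, s2_beta, spec.hyper("df_e"), s2_e,
        n_iter, burn_in, spec.hyper("thin"), spec.hyper("seed"))
    if not np.isfinite(beta).all():  # pragma: no cover
        raise RuntimeError("divergent chain: non-finite posterior state")
    fitted = pd.Series(mu + Xc @ beta, index=ids, name=y.name)
    return ModelFit(
        spec=spec, mu=float(mu), train_ids=ids, fitted_values=fitted,
        beta_add=beta[:m_add], beta_het=(beta[m_add:] if c_het is not None
                                         else None),
        center_add=c_add, center_het=c_het,
        diagnostics={"inclusion_freq": incl, "sigma2_e": float(s2e_post)})


def fit_markers_blasso(y: pd.Series, X_add: np.ndarray,
                       X_het: np.ndarray | None = None,
                       spec: ModelSpec | None = None) -> ModelFit:
    """Bayesian Lasso: double-exponential marker-effect prior via Gibbs."""
    from ._samplers import bayes_lasso_chain

    if spec is None:
        spec = ModelSpec("BayesianLasso",
                         "additive_dominant" if X_het is not None
                         else "additive")
    n_iter, burn_in = spec.hyper("n_iter"), spec.hyper("burn_in")
    if n_iter <= burn_in:
        raise ValueError("chain length must exceed burn-in")
    ids, yv, Xc, c_add, c_het, m_add = _prepare_designs(y, X_add, X_het)
    var_y = float(np.var(yv)) + 1e-12
    m = Xc.shape[1]
    sum_var_x = float(np.sum(Xc.var(axis=0))) + 1e-12
    # initial lambda^2 targeting r2 of var(y) explained by markers
    lambda2_init = max(2.0 * sum_var_x * (1 - spec.hyper("r2"))
                       / (spec.hyper("r2") * m + 1e-12), 1e-6)
    s2_e = var_y * (1.0 - spec.hyper("r2"))
    mu, beta, lam2, s2e_post = bayes_lasso_chain(
        Xc, yv, lambda2_init, 1.1, 1.1 / max(lambda2_init, 1e-12),
        spec.hyper("df_e"), s2_e,
        n_iter, burn_in, spec.hyper("thin"), spec.hyper("seed"))
    if not np.isfinite(beta).all():  # pragma: no cover
        raise RuntimeError("divergent chain: non-finite posterior state")
    fitted = pd.Series(mu + Xc @ beta, index=ids, name=y.name)
    return ModelFit(
        spec=spec, mu=float(mu), train_ids=ids, fitted_values=fitted,
        beta_add=beta[:m_add], beta_het=(beta[m_add:] if c_het is not None
                                         else None),
        center_add=c_add, center_het=c_het,
        diagnostics={"lambda2": float(lam2), "sigma2_e": float(s2e_post)})


def predict_markers(fit: ModelFit, X_add: np.ndarray,
                    X_het: np.ndarray | None = None,
                    ids: list[str] | None = None) -> pd.Series:
    """Score new genotypes with posterior-mean marker effects."""
    if fit.beta_add is None:
        raise ValueError("fit is not a marker-effect model")
    X_add = np.asarray(X_add, dtype=np.float64)
    pred = fit.mu + (X_add - fit.center_add) @ fit.beta_add
    if fit.beta_het is not None:
        if X_het is None:
            raise ValueError("fit has dominance effects; supply X_het")
        X_het = np.asarray(X_het, dtype=np.float64)
        pred = pred + (X_het - fit.center_het) @ fit.beta_het
    if ids is None:
        ids = [str(i) for i in range(len(pred))]
    return pd.Series(pred, index=ids, name=fit.fitted_values.name)


# ---------------------------------------------------------------------------
# RKHS
# ---------------------------------------------------------------------------

def gaussian_kernel(calls: np.ndarray, ids: list[str],
                    theta: float = 1.0) -> KinshipMatrix:
    """Gaussian kernel K_ij = exp(-theta * d2_ij / median(d2)) on coded
    genotypes; the median of off-diagonal squared distances sets the scale
    so theta = 1 is a reasonable default bandwidth."""
    X = np.asarray(calls, dtype=np.float64)
    sq = np.sum(X * X, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.clip(d2, 0.0, None, out=d2)
    off = d2[~np.eye(len(ids), dtype=bool)]
    med = float(np.median(off))
    if med <= 0:
        raise ValueError("degenerate genotypes: all pairwise distances zero")
    K = np.exp(-theta * d2 / med)
    return KinshipMatrix(list(ids), K, "rkhs")


def fit_rkhs(y: pd.Series, G, bandwidth: float | str = "AUTO",
             spec: ModelSpec | None = None,
             engine: str = "REML") -> ModelFit:
    """Gaussian-kernel RKHS regression as a single-kinship mixed model.

    ``G`` is a fully imputed :class:`GenotypeMatrix` (the kernel is built
    over all its individuals, so held-out individuals can be predicted
    from the stored kernel) or a precomputed :class:`KinshipMatrix`.
    """
    if spec is None:
        spec = ModelSpec("RKHS")
    theta = spec.hyper("theta") if bandwidth == "AUTO" else float(bandwidth)
    if isinstance(G, KinshipMatrix):
        K = G
    else:
        K = gaussian_kernel(G.calls, G.individuals, theta)
    fit = fit_gblup(y, K, None, engine=engine, spec=spec)
    fit.kernel = K
    return fit


# ---------------------------------------------------------------------------
# Random forest
# ---------------------------------------------------------------------------

def fit_tree_ensemble(y: pd.Series, X_add: np.ndarray,
                      spec: ModelSpec | None = None) -> ModelFit:
    """Regression forest on coded genotypes (delegates to scikit-learn)."""
    from sklearn.ensemble import RandomForestRegressor

    if spec is None:
        spec = ModelSpec("TreeEnsemble")
    X = np.asarray(X_add, dtype=np.float64)
    yv = np.asarray(y, dtype=np.float64)
    rf = RandomForestRegressor(n_estimators=spec.hyper("n_trees"),
                               random_state=spec.hyper("seed"), n_jobs=1)
    rf.fit(X, yv)
    ids = [str(i) for i in y.index]
    fitted = pd.Series(rf.predict(X), index=ids, name=y.name)
    return ModelFit(spec=spec, mu=float(yv.mean()), train_ids=ids,
                    fitted_values=fitted, model=rf,
                    diagnostics={"seed": spec.hyper("seed")})
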