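"""Gibbs sampler for multi-kernel Gaussian mixed models.

Model: y = 1μ + Σ_k u_k + e, with u_k ~ N(0, K_k σ²_k) and e ~ N(0, I σ²).
Each kernel is re-parameterized through its eigendecomposition K = B B'
(B = U Λ^½, small eigenvalues dropped), so u_k = B_k δ_k with iid coefficients
δ_k ~ N(0, I σ²_k).  Because B_k'B_k is diagonal, the δ_k full conditional is
a product of univariate normals and each Gibbs update costs two matrix-vector
products.  Variance components get scaled-inverse-chi-square updates under
weakly informative priors; missing phenotypes are imputed by data
augmentation, which is also how held-out observations are predicted in the
cross-validation schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .models import ModelSpec

__all__ = [
    "GibbsConfig",
    "PosteriorSummary",
    "factorize",
    "precompute_bases",
    "fit_gibbs",
    "blup_fixed_variances",
    "variance_percent",
    "fit_ridge_markers",
]


@dataclass
class GibbsConfig:
    """MCMC settings and hyper-priors.

    ``prior_R2`` is the share of phenotypic variance the prior assigns to the
    random terms collectively (split equally among them); the residual prior
    gets the complement.  Scales follow the usual weakly informative rule
    S = E[σ²]·(df + 2) so the prior mode sits at the intended share.
    """

    n_iter: int = 12000
    burn_in: int = 2000
    thin: int = 5
    seed: int = 0
    prior_df: float = 5.0
    prior_R2: float = 0.5
    eigen_tol: float = 1e-8

    def __post_init__(self):
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_df <= 0:
            raise ValueError("prior_df must be positive")
        if not 0 < self.prior_R2 < 1:
            raise ValueError("prior_R2 must lie in (0, 1)")


@dataclass
class PosteriorSummary:
    """Posterior means and variance partition from one chain."""

    mu_hat: float
    var_components: dict
    resid_var: float
    percent_table: dict
    predictions: np.ndarray
    effect_means: dict
    mcmc_meta: dict
    obs_ids: list = field(default_factory=list)


def factorize(K: np.ndarray, eigen_tol: float = 1e-8) -> np.ndarray:
    """Factor a PSD kernel as B B' via its eigendecomposition.

    Columns are eigenvectors scaled by the square root of their eigenvalues;
    eigenvalues below ``eigen_tol`` times the largest are dropped.  Raises if
    the most negative eigenvalue exceeds the same relative tolerance (times a
    small safety factor for accumulated floating error in kernel products).
    """
    M = K.matrix if hasattr(K, "matrix") else np.asarray(K, dtype=float)
    w, U = scipy.linalg.eigh(M)
    top = max(w[-1], np.finfo(float).tiny)
    if w[0] < -max(eigen_tol, 1e-10) * top:
        raise ValueError(
            f"kernel is not PSD within tolerance (min/max eigenvalue {w[0] / top:.3e})"
        )
    keep = w > eigen_tol * top
    return U[:, keep] * np.sqrt(w[keep])


def precompute_bases(model: ModelSpec, eigen_tol: float = 1e-8) -> dict:
    """Eigen-factorize every term kernel once (reusable across refits/masks)."""
    return {t.label: factorize(t.kernel, eigen_tol) for t in model.terms}


def variance_percent(var_components: dict, resid_var: float) -> dict:
    """Percent of total variance per random term (+ residual); sums to 100."""
    total = sum(var_components.values()) + resid_var
    out = {k: 100.0 * v / total for k, v in var_components.items()}
    out["Res"] = 100.0 * resid_var / total
    return out


def _check_y(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if np.isinf(y).any():
        raise ValueError("non-finite (infinite) phenotype value")
    obs = y[~np.isnan(y)]
    if obs.size < 2:
        raise ValueError("need at least 2 non-missing phenotypes")
    if obs.std() == 0:
        raise ValueError("phenotype is exactly constant; model is degenerate")
    return y


def fit_gibbs(
    y: np.ndarray,
    model: ModelSpec,
    cfg: GibbsConfig,
    fixed_variances: dict | None = None,
    bases: dict | None = None,
) -> PosteriorSummary:
    """Fit a multi-kernel model by Gibbs sampling.

    ``y`` uses NaN for missing/held-out phenotypes; those entries are sampled
    each iteration (data augmentation) and predicted like any other
    observation.  ``fixed_variances`` (label → σ², plus ``"Res"``) freezes the
    variance components (degenerate priors), turning the chain into a sampler
    of effects only — the posterior mean of η then equals the BLUP.
    ``bases`` allows reusing :func:`precompute_bases` output across refits.
    The chain is fully reproducible from ``cfg.seed``.
    """
    y = _check_y(y)
    n = y.size
    if n != len(model.obs_ids):
        raise ValueError(f"y has {n} entries but model has {len(model.obs_ids)} observations")
    if bases is None:
        bases = precompute_bases(model, cfg.eigen_tol)
    labels = list(model.labels)
    B = {lb: bases[lb] for lb in labels}
    lam = {lb: np.einsum("ij,ij->j", B[lb], B[lb]) for lb in labels}  # B'B diag

    rng = np.random.default_rng(cfg.seed)
    miss = np.isnan(y)
    y_full = y.copy()
    vy = float(np.nanvar(y))
    y_full[miss] = np.nanmean(y)

    K = len(labels)
    df0 = cfg.prior_df
    S_k = {lb: vy * cfg.prior_R2 / K * (df0 + 2) for lb in labels}
    S_e = vy * (1 - cfg.prior_R2) * (df0 + 2)

    fixed = fixed_variances or {}
    sig2 = float(fixed.get("Res", vy * (1 - cfg.prior_R2)))
    sig2_k = {lb: float(fixed.get(lb, vy * cfg.prior_R2 / K)) for lb in labels}

    mu = float(y_full.mean())
    delta = {lb: np.zeros(B[lb].shape[1]) for lb in labels}
    u = {lb: np.zeros(n) for lb in labels}
    e = y_full - mu  # current residual

    n_keep = (cfg.n_iter - cfg.burn_in + cfg.thin - 1) // cfg.thin
    acc_mu = 0.0
    acc_s2k = {lb: 0.0 for lb in labels}
    acc_s2 = 0.0
    acc_eta = np.zeros(n)
    acc_u = {lb: np.zeros(n) for lb in labels}
    samples = {"mu": [], "sigma2": [], **{lb: [] for lb in labels}}

    for it in range(cfg.n_iter):
        # (1) intercept, flat prior
        e += mu
        mu = e.mean() + rng.standard_normal() * np.sqrt(sig2 / n)
        e -= mu

        # (2) regression coefficients per term, in the eigen basis
        for lb in labels:
            e += u[lb]
            prec = lam[lb] / sig2 + 1.0 / sig2_k[lb]
            mean = (B[lb].T @ e) / sig2 / prec
            delta[lb] = mean + rng.standard_normal(mean.size) / np.sqrt(prec)
            u[lb] = B[lb] @ delta[lb]
            e -= u[lb]

        # (3) variance components, scaled-inverse-chi-square full conditionals
        for lb in labels:
            if lb not in fixed:
                d = delta[lb]
                sig2_k[lb] = (S_k[lb] + d @ d) / rng.chisquare(df0 + d.size)
        if "Res" not in fixed:
            sig2 = (S_e + e @ e) / rng.chisquare(df0 + n)
        if not np.isfinite(sig2) or sig2 > 1e12 * max(vy, 1e-300):
            raise FloatingPointError(f"divergent residual variance at iteration {it}")

        # (4) impute missing phenotypes from their predictive distribution
        if miss.any():
            eta_miss = mu + sum(u[lb][miss] for lb in labels)
            y_new = eta_miss + rng.standard_normal(int(miss.sum())) * np.sqrt(sig2)
            e[miss] += y_new - y_full[miss]
            y_full[miss] = y_new

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            eta = y_full - e
            acc_mu += mu
            acc_s2 += sig2
            acc_eta += eta
            samples["mu"].append(mu)
            samples["sigma2"].append(sig2)
            for lb in labels:
                acc_s2k[lb] += sig2_k[lb]
                acc_u[lb] += u[lb]
                samples[lb].append(sig2_k[lb])

    var_components = {lb: acc_s2k[lb] / n_keep for lb in labels}
    resid_var = acc_s2 / n_keep
    return PosteriorSummary(
        mu_hat=acc_mu / n_keep,
        var_components=var_components,
        resid_var=resid_var,
        percent_table=variance_percent(var_components, resid_var),
        predictions=acc_eta / n_keep,
        effect_means={lb: acc_u[lb] / n_keep for lb in labels},
        mcmc_meta={
            "seed": cfg.seed,
            "n_iter": cfg.n_iter,
            "burn_in": cfg.burn_in,
            "thin": cfg.thin,
            "n_retained": n_keep,
            "model": model.name,
            "samples": {k: np.asarray(v) for k, v in samples.items()},
        },
        obs_ids=list(model.obs_ids),
    )


def blup_fixed_variances(y: np.ndarray, model: ModelSpec, variances: dict) -> np.ndarray:
    """Closed-form mixed-model predictions at fixed variance components.

    Solves V = Σ σ²_k K_k + σ² I on the training (non-missing) block, with the
    intercept by GLS, and extends to masked observations through the kernel
    cross-covariance rows: η̂ = μ̂ + C[:, train] V⁻¹ (y_train − μ̂).
    """
    y = _check_y(y)
    train = ~np.isnan(y)
    n = y.size
    sig2 = float(variances["Res"])
    C = np.zeros((n, n))
    for t in model.terms:
        C += float(variances[t.label]) * t.kernel.matrix
    V = C[np.ix_(train, train)] + sig2 * np.eye(int(train.sum()))
    try:
        cho = scipy.linalg.cho_factor(V)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError(f"singular covariance matrix V: {exc}")
    ones = np.ones(int(train.sum()))
    Vi_y = scipy.linalg.cho_solve(cho, y[train])
    Vi_1 = scipy.linalg.cho_solve(cho, ones)
    mu_hat = float(ones @ Vi_y / (ones @ Vi_1))
    alpha = scipy.linalg.cho_solve(cho, y[train] - mu_hat)
    return mu_hat + C[:, train] @ alpha


def fit_ridge_markers(
    y: np.ndarray,
    X: np.ndarray,
    cfg: GibbsConfig,
    prior_scale_b: float | None = None,
) -> dict:
    """Explicit marker-effects ridge sampler: y = 1μ + X b + e, b ~ N(0, I σ²_b).

    Independent of the kernel machinery (joint Cholesky draw of b each
    iteration); serves as the duality check for the G-kernel model, since
    g = X b implies Cov(g) = G·(p σ²_b) with G = XX'/p.  ``prior_scale_b``
    overrides the σ²_b prior scale (use S_g / p to match a kernel fit).
    Returns posterior means of μ, b, σ²_b, σ²_e and per-line predictions.
    """
    y = _check_y(y)
    if np.isnan(y).any():
        raise ValueError("ridge sampler expects complete phenotypes")
    n, p = X.shape
    rng = np.random.default_rng(cfg.seed)
    vy = float(y.var())
    df0 = cfg.prior_df
    S_b = prior_scale_b if prior_scale_b is not None else vy * cfg.prior_R2 / p * (df0 + 2)
    S_e = vy * (1 - cfg.prior_R2) * (df0 + 2)

    XtX = X.T @ X
    mu = float(y.mean())
    b = np.zeros(p)
    sig2_b = vy * cfg.prior_R2 / p
    sig2 = vy * (1 - cfg.prior_R2)
    e = y - mu

    n_keep = (cfg.n_iter - cfg.burn_in + cfg.thin - 1) // cfg.thin
    acc = {"mu": 0.0, "b": np.zeros(p), "sigma2_b": 0.0, "sigma2_e": 0.0, "eta": np.zeros(n)}

    for it in range(cfg.n_iter):
        e += mu
        mu = e.mean() + rng.standard_normal() * np.sqrt(sig2 / n)
        e -= mu

        r = e + X @ b
        P = XtX / sig2 + np.eye(p) / sig2_b
        L = scipy.linalg.cholesky(P, lower=True)
        mean = scipy.linalg.cho_solve((L, True), X.T @ r / sig2)
        z = rng.standard_normal(p)
        b = mean + scipy.linalg.solve_triangular(L, z, lower=True, trans="T")
        e = r - X @ b

        sig2_b = (S_b + b @ b) / rng.chisquare(df0 + p)
        sig2 = (S_e + e @ e) / rng.chisquare(df0 + n)

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            acc["mu"] += mu
            acc["b"] += b
            acc["sigma2_b"] += sig2_b
            acc["sigma2_e"] += sig2
            acc["eta"] += mu + X @ b

    return {k: v / n_keep for k, v in acc.items()}
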