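"""Cross-validation schemes and the weighted Pearson correlation score.

Two schemes mirror the decision points of a breeding pipeline in which every
line is phenotyped in exactly one year:

* **CV1** — predict lines never observed in any environment: a seeded
  fivefold random partition of the lines, repeated (default 20 times); each
  fold is masked in turn, the model refit, and the five test-fold prediction
  vectors joined before scoring within each environment.
* **V00** — predict all lines of an entirely unobserved year: leave one
  year out, fit on the remaining years (held-out rows present with missing
  phenotypes), score within the held-out year.  No random partition exists,
  so it runs once.

Scores are Pearson correlations per environment, combined as a weighted mean
with weights n_e / Σ n_e (years with more observations count more).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .gibbs import GibbsConfig, fit_gibbs, precompute_bases
from .models import ModelSpec

__all__ = [
    "PhenotypeTable",
    "CVResult",
    "pearson",
    "weighted_mean_corr",
    "cv1_partitions",
    "run_cv1",
    "run_v00",
]

log = logging.getLogger("kernblup")


@dataclass
class PhenotypeTable:
    """Line-level phenotype records: one row per line (GID, ENV, traits...).

    Each line appears in exactly one environment (year) — enforced on
    construction, since the whole validation design rests on it.
    """

    data: pd.DataFrame

    def __post_init__(self):
        for col in ("GID", "ENV"):
            if col not in self.data.columns:
                raise ValueError(f"phenotype table must have a {col!r} column")
        if self.data["GID"].duplicated().any():
            dup = self.data.loc[self.data["GID"].duplicated(), "GID"].tolist()
            raise ValueError(f"duplicate GID(s) — lines are observed once: {dup[:5]}")
        self.data = self.data.reset_index(drop=True)

    @property
    def traits(self) -> list:
        return [c for c in self.data.columns if c not in ("GID", "ENV")]

    def canonical(self) -> pd.DataFrame:
        """Observations in canonical order: sort by (ENV, GID)."""
        return self.data.sort_values(["ENV", "GID"], kind="stable").reset_index(drop=True)

    def y_env(self, trait: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(gids, envs, y) aligned to the canonical observation order."""
        df = self.canonical()
        if trait not in df.columns:
            raise KeyError(f"trait {trait!r} not in phenotype table")
        return (
            df["GID"].to_numpy(),
            df["ENV"].to_numpy(),
            df[trait].to_numpy(dtype=float),
        )


@dataclass
class CVResult:
    """Per-environment and weighted-mean correlations for one scheme run."""

    scheme: str
    model: str
    per_env: dict            # env -> (mean r, sd r over replicates or None)
    weighted_mean: tuple     # (mean, sd or None)
    n_per_env: dict
    replicates: int
    per_replicate: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"env": e, "mean_r": m, "sd_r": s, "n": self.n_per_env.get(e)}
            for e, (m, s) in self.per_env.items()
        ]
        rows.append(
            {
                "env": "weighted_mean",
                "mean_r": self.weighted_mean[0],
                "sd_r": self.weighted_mean[1],
                "n": int(sum(self.n_per_env.values())),
            }
        )
        return pd.DataFrame(rows)


def pearson(obs: np.ndarray, pred: np.ndarray) -> float:
    """Product-moment correlation; errors on degenerate input (caller skips)."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("obs and pred must be paired vectors of equal length")
    if obs.size < 2:
        raise ValueError("need at least 2 points for a correlation")
    if obs.std() == 0 or pred.std() == 0:
        raise ValueError("zero variance in obs or pred")
    return float(scipy.stats.pearsonr(obs, pred).statistic)


def weighted_mean_corr(per_env_r: dict, n_per_env: dict) -> float:
    """Σ_e r_e · n_e / Σ n_e over the scored environments."""
    if not per_env_r:
        raise ValueError("no per-environment correlations to combine")
    if set(per_env_r) != set(n_per_env):
        raise ValueError("environment keys of r and n maps differ")
    total = sum(n_per_env.values())
    return float(sum(r * n_per_env[e] / total for e, r in per_env_r.items()))


def cv1_partitions(gids, k: int = 5, n_reps: int = 20, seed: int = 0) -> list:
    """Seeded random k-fold partitions of the lines, one list of folds per replicate.

    Fold sizes differ by at most one; remainder lines go to the earliest
    folds after the shuffle.  Replicate r uses seed ``seed + r`` so runs are
    reproducible and replicates differ.
    """
    gids = np.asarray(list(gids))
    if k > gids.size:
        raise ValueError(f"k={k} folds but only {gids.size} lines")
    reps = []
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        perm = rng.permutation(gids)
        reps.append([fold.tolist() for fold in np.array_split(perm, k)])
    return reps


def _score_envs(envs, y, pred, test_mask) -> tuple[dict, dict]:
    """Per-environment Pearson r on the test observations; skip degenerate envs."""
    per_env, n_env = {}, {}
    for env in pd.unique(envs):
        sel = (envs == env) & test_mask & ~np.isnan(y)
        if sel.sum() < 2:
            log.warning("env %s skipped: fewer than 2 scored observations", env)
            continue
        try:
            r = pearson(y[sel], pred[sel])
        except ValueError as exc:
            log.warning("env %s skipped: %s", env, exc)
            continue
        per_env[env] = r
        n_env[env] = int(sel.sum())
    return per_env, n_env


def run_cv1(
    data: PhenotypeTable,
    model: ModelSpec,
    cfg: GibbsConfig,
    trait: str,
    k: int = 5,
    n_reps: int = 20,
    seed: int = 0,
    bases: dict | None = None,
) -> CVResult:
    """Random fivefold cross-validation of new lines in observed years.

    Kernels (and their eigen-factorizations) are reused across all folds and
    replicates — only the phenotype mask changes.  Per replicate the five
    test-fold predictions are joined into one vector before scoring.
    """
    gids, envs, y = data.y_env(trait)
    if model.obs_ids != list(gids):
        raise ValueError("model observation ids do not match canonical phenotype order")
    if bases is None:
        bases = precompute_bases(model, cfg.eigen_tol)

    partitions = cv1_partitions(gids, k=k, n_reps=n_reps, seed=seed)
    rep_env_r: list[dict] = []
    rep_wmean: list[float] = []
    n_env_all: dict = {}
    for rep, folds in enumerate(partitions):
        pred = np.full(y.size, np.nan)
        for f, fold in enumerate(folds):
            test = np.isin(gids, fold)
            y_masked = y.copy()
            y_masked[test] = np.nan
            fit_cfg = GibbsConfig(
                n_iter=cfg.n_iter, burn_in=cfg.burn_in, thin=cfg.thin,
                seed=cfg.seed + 1000 * rep + f, prior_df=cfg.prior_df,
                prior_R2=cfg.prior_R2, eigen_tol=cfg.eigen_tol,
            )
            ps = fit_gibbs(y_masked, model, fit_cfg, bases=bases)
            pred[test] = ps.predictions[test]
        test_all = ~np.isnan(pred)
        per_env, n_env = _score_envs(envs, y, pred, test_all)
        if not per_env:
            log.warning("replicate %d produced no scorable environment", rep)
            continue
        rep_env_r.append(per_env)
        rep_wmean.append(weighted_mean_corr(per_env, n_env))
        n_env_all = {e: max(n_env_all.get(e, 0), n) for e, n in n_env.items()}

    envs_scored = sorted({e for d in rep_env_r for e in d})
    per_env_summary = {}
    for e in envs_scored:
        vals = np.array([d[e] for d in rep_env_r if e in d])
        per_env_summary[e] = (float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else None)
    wm = np.array(rep_wmean)
    return CVResult(
        scheme="CV1",
        model=model.name,
        per_env=per_env_summary,
        weighted_mean=(float(wm.mean()), float(wm.std(ddof=1)) if wm.size > 1 else None),
        n_per_env=n_env_all,
        replicates=len(rep_wmean),
        per_replicate=rep_wmean,
    )


def run_v00(
    data: PhenotypeTable,
    model: ModelSpec,
    cfg: GibbsConfig,
    trait: str,
    bases: dict | None = None,
) -> CVResult:
    """Leave-one-year-out validation: predict every line of an unseen year.

    Held-out rows stay in the model with missing phenotypes, so their
    environment and interaction effects shrink to the prior mean 0 and the
    predictions reduce to μ̂ plus the genetic main effects carried by
    relatives in the training years.
    """
    gids, envs, y = data.y_env(trait)
    env_levels = list(pd.unique(envs))
    if len(env_levels) < 2:
        raise ValueError("V00 needs at least 2 environments")
    if model.obs_ids != list(gids):
        raise ValueError("model observation ids do not match canonical phenotype order")
    if bases is None:
        bases = precompute_bases(model, cfg.eigen_tol)

    per_env, n_env = {}, {}
    for j, env in enumerate(env_levels):
        test = envs == env
        y_masked = y.copy()
        y_masked[test] = np.nan
        fit_cfg = GibbsConfig(
            n_iter=cfg.n_iter, burn_in=cfg.burn_in, thin=cfg.thin,
            seed=cfg.seed + j, prior_df=cfg.prior_df,
            prior_R2=cfg.prior_R2, eigen_tol=cfg.eigen_tol,
        )
        ps = fit_gibbs(y_masked, model, fit_cfg, bases=bases)
        sel = test & ~np.isnan(y)
        if sel.sum() < 2:
            log.warning("env %s skipped: fewer than 2 scored observations", env)
            continue
        try:
            per_env[env] = pearson(y[sel], ps.predictions[sel])
            n_env[env] = int(sel.sum())
        except ValueError as exc:
            log.warning("env %s skipped: %s", env, exc)
    if not per_env:
        raise ValueError("no environment could be scored under V00")
    wmean = weighted_mean_corr(per_env, n_env)
    return CVResult(
        scheme="V00",
        model=model.name,
        per_env={e: (r, None) for e, r in per_env.items()},
        weighted_mean=(wmean, None),
        n_per_env=n_env,
        replicates=1,
        per_replicate=[wmean],
    )
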