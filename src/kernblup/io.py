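"""Flat-file readers/writers and pipeline orchestration.

Formats are deliberately language-neutral text:

* phenotypes — CSV with columns ``GID, ENV, <trait>...``; blank = missing
* pedigree   — CSV ``id,sire,dam`` with header; empty field = unknown parent
* markers    — TSV, first column the line id, remaining columns 0/1/2/``NA``
* kernels    — square CSV with the entity ids as header row and first column
* results    — CSV per-environment table + JSON summary with a config-hash
               sidecar for provenance

``run_pipeline`` wires the stages together: load → QC → kernels → model →
(fit | cv1 | v00) → reports, logging dimensions and seeds along the way.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genomic import MarkerMatrix, build_G, impute_and_standardize, qc_markers
from .gibbs import GibbsConfig, fit_gibbs, variance_percent
from .kernels import IncidenceMap, Kernel
from .models import MODEL_TERMS, build_observation_kernels, make_model
from .pedigree import PedigreeTable, build_A, topo_sort_pedigree
from .validation import PhenotypeTable, run_cv1, run_v00

log = logging.getLogger("kernblup")

__all__ = [
    "RunConfig",
    "read_phenotypes",
    "write_phenotypes",
    "read_pedigree",
    "write_pedigree",
    "read_markers",
    "write_markers",
    "read_kernel",
    "write_kernel",
    "run_pipeline",
]


# ---------------------------------------------------------------- phenotypes

def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path)
    for col in ("GID", "ENV"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df["GID"] = df["GID"].astype(str)
    df["ENV"] = df["ENV"].astype(str)
    for c in df.columns:
        if c not in ("GID", "ENV"):
            try:
                df[c] = pd.to_numeric(df[c])
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}: non-numeric value in trait column {c!r}: {exc}")
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.data.to_csv(path, index=False)


# ------------------------------------------------------------------ pedigree

def read_pedigree(path) -> PedigreeTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["id", "sire", "dam"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: pedigree header must be id,sire,dam")
    records = [
        (r.id, r.sire or None, r.dam or None) for r in df.itertuples(index=False)
    ]
    return PedigreeTable(records)


def write_pedigree(ped: PedigreeTable, path) -> None:
    df = pd.DataFrame(ped.records, columns=["id", "sire", "dam"]).fillna("")
    df.to_csv(path, index=False)


# ------------------------------------------------------------------- markers

def read_markers(path) -> MarkerMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return MarkerMatrix(
        [str(i) for i in df.index], [str(c) for c in df.columns], df.to_numpy(dtype=float)
    )


def write_markers(m: MarkerMatrix, path) -> None:
    df = pd.DataFrame(m.codes, index=m.line_ids, columns=m.marker_ids)
    df.index.name = "GID"
    # integer codes with NA for missing
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


# ------------------------------------------------------------------- kernels

def write_kernel(K: Kernel, path) -> None:
    df = pd.DataFrame(K.matrix, index=K.entity_ids, columns=K.entity_ids)
    df.index.name = K.name
    df.to_csv(path, float_format="%.12g")


def read_kernel(path, name: str | None = None) -> Kernel:
    df = pd.read_csv(path, index_col=0)
    ids = [str(i) for i in df.index]
    if ids != [str(c) for c in df.columns]:
        raise ValueError(f"{path}: kernel row and column ids differ")
    return Kernel(name or (df.index.name or "K"), ids, df.to_numpy(dtype=float))


# ------------------------------------------------------------------ pipeline

@dataclass
class RunConfig:
    """One pipeline run: input paths, trait, model, scheme, MCMC settings."""

    phenotypes: str
    out_dir: str
    trait: str
    model: str = "M1"
    pedigree: str | None = None
    markers: str | None = None
    scheme: str = "fit"            # fit | cv1 | v00
    folds: int = 5
    reps: int = 20
    seed: int = 0
    gibbs: GibbsConfig = field(default_factory=GibbsConfig)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        gibbs = raw.pop("gibbs", {})
        cfg = cls(**raw)
        if gibbs:
            cfg.gibbs = GibbsConfig(**gibbs)
        return cfg

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _sidecar(path: Path, cfg: RunConfig) -> None:
    meta = {
        "config_hash": cfg.digest(),
        "package": "kernblup",
        "version": __version__,
        "seed": cfg.seed,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def assemble(cfg: RunConfig):
    """Load inputs and build the model for the canonical observation order."""
    pheno = read_phenotypes(cfg.phenotypes)
    if cfg.trait not in pheno.traits:
        raise ValueError(f"trait {cfg.trait!r} not in phenotype file (has {pheno.traits})")
    gids, envs, y = pheno.y_env(cfg.trait)
    gid_list = list(gids)
    line_map = IncidenceMap(gid_list, dict(zip(gid_list, gid_list)))
    env_map = IncidenceMap(gid_list, dict(zip(gid_list, envs)))

    labels = MODEL_TERMS.get(cfg.model)
    if labels is None:
        raise ValueError(f"unknown model {cfg.model!r}; valid: {', '.join(MODEL_TERMS)}")
    need_A = any(l in ("A", "AE", "GA", "GAE") for l in labels)
    need_G = any(l in ("G", "GE", "GA", "GAE") for l in labels)
    A = G = None
    if need_A:
        if cfg.pedigree is None:
            raise ValueError(f"model {cfg.model} needs a pedigree file")
        ped = topo_sort_pedigree(read_pedigree(cfg.pedigree), auto_insert_founders=True)
        A = build_A(ped).restrict(gid_list)
        log.info("A matrix: %d lines (pedigree of %d records)", A.n, len(ped))
    if need_G:
        if cfg.markers is None:
            raise ValueError(f"model {cfg.model} needs a marker file")
        raw = read_markers(cfg.markers).restrict(gid_list)
        mm, rep = qc_markers(raw)
        log.info(
            "marker QC: %d → %d (missing %d, MAF %d)",
            rep.n_input, rep.n_retained, rep.n_removed_missing, rep.n_removed_maf,
        )
        G = build_G(impute_and_standardize(mm))
    kernels = build_observation_kernels(line_map, env_map, A=A, G=G, labels=labels)
    model = make_model(cfg.model, kernels)
    return pheno, model, y


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured scheme; write result files; return artifact paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    try:
        log.info("pipeline start: scheme=%s model=%s seed=%d", cfg.scheme, cfg.model, cfg.seed)
        pheno, model, y = assemble(cfg)
        gcfg = dataclasses.replace(cfg.gibbs, seed=cfg.seed)
        artifacts: dict = {}
        if cfg.scheme == "fit":
            ps = fit_gibbs(y, model, gcfg)
            summary = {
                "model": model.name,
                "mu_hat": ps.mu_hat,
                "var_components": ps.var_components,
                "resid_var": ps.resid_var,
                "percent_table": ps.percent_table,
                "mcmc": {k: v for k, v in ps.mcmc_meta.items() if k != "samples"},
            }
            spath = out / "fit_summary.json"
            spath.write_text(json.dumps(summary, indent=2, sort_keys=True))
            ppath = out / "predictions.csv"
            pd.DataFrame({"GID": ps.obs_ids, "prediction": ps.predictions}).to_csv(
                ppath, index=False
            )
            _sidecar(spath, cfg)
            artifacts = {"summary": spath, "predictions": ppath}
        elif cfg.scheme in ("cv1", "v00"):
            if cfg.scheme == "cv1":
                res = run_cv1(
                    pheno, model, gcfg, cfg.trait, k=cfg.folds, n_reps=cfg.reps, seed=cfg.seed
                )
            else:
                res = run_v00(pheno, model, gcfg, cfg.trait)
            cpath = out / f"{cfg.scheme}_{model.name}.csv"
            res.to_frame().to_csv(cpath, index=False, float_format="%.6f")
            jpath = out / f"{cfg.scheme}_{model.name}.json"
            jpath.write_text(
                json.dumps(
                    {
                        "scheme": res.scheme,
                        "model": res.model,
                        "weighted_mean": res.weighted_mean,
                        "per_env": {e: list(v) for e, v in res.per_env.items()},
                        "n_per_env": res.n_per_env,
                        "replicates": res.replicates,
                        "sd_definition": "sd across replicates of per-env r; "
                        "weighted-mean sd is the sd of per-replicate weighted means",
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            _sidecar(jpath, cfg)
            artifacts = {"table": cpath, "summary": jpath}
        else:
            raise ValueError(f"unknown scheme {cfg.scheme!r} (fit|cv1|v00)")
        log.info("pipeline done: %s", {k: str(v) for k, v in artifacts.items()})
        return artifacts
    except Exception:
        log.exception("pipeline failed in scheme %s", cfg.scheme)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()
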