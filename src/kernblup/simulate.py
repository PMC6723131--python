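"""Synthetic breeding-program data generator.

Emulates the structure the multi-kernel analysis assumes: a multi-year
pipeline of full-sib families from crosses several generations deep, gametic
(Mendelian) inheritance of unlinked biallelic markers, every line phenotyped
in exactly one year, a minority of families spanning two or more years, and
phenotypes assembled additively from environment, pedigree, genomic and
Hadamard-interaction components with user-specified variance fractions.

Because each component is drawn as u = B z with B the eigen-factor of the
component's own (diagonal-normalized) kernel, the generator is literally the
data-generating process of the M1–M8 model family — parameter-recovery tests
compare fitted percent-of-variance tables against the requested fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genomic import MarkerMatrix, build_G, impute_and_standardize, qc_markers
from .gibbs import factorize
from .kernels import IncidenceMap
from .models import build_observation_kernels
from .pedigree import PedigreeTable, build_A
from .validation import PhenotypeTable

__all__ = [
    "SimConfig",
    "TrueComponents",
    "simulate_pedigree",
    "simulate_genotypes",
    "assign_years",
    "simulate_phenotypes",
    "simulate_dataset",
]

#: variance-fraction preset shaped like a grain-yield full-model partition
#: (E 35%, A 12%, G 7%, AE 20%, GE 7%, residual 19%)
TABLE1_LIKE = {"E": 0.35, "A": 0.12, "G": 0.07, "AE": 0.20, "GE": 0.07, "Res": 0.19}


@dataclass
class SimConfig:
    """Knobs of the synthetic breeding pipeline.

    ``mean_family_size`` parameterizes a geometric family-size law (min 1,
    capped at ``family_size_cap`` — real programs show sizes from 1 up to
    ~116).  ``family_overlap_frac`` is the share of families whose members
    are split across ≥2 years (~15% in the motivating pipeline).
    ``variance_fractions`` must sum to 1 and drives σ²_k for each component.
    """

    n_founders: int = 60
    n_families: int = 80
    mean_family_size: float = 5.0
    family_size_cap: int = 116
    generation_depth: int = 5
    n_years: int = 4
    family_overlap_frac: float = 0.15
    p_markers: int = 500
    maf_range: tuple = (0.05, 0.5)
    missing_rate: float = 0.0
    variance_fractions: dict = field(default_factory=lambda: dict(TABLE1_LIKE))
    mu: float = 0.0
    trait: str = "Y"
    seed: int = 0

    def __post_init__(self):
        fr = self.variance_fractions
        if any(v < 0 for v in fr.values()):
            raise ValueError("variance fractions must be non-negative")
        if abs(sum(fr.values()) - 1.0) > 1e-8:
            raise ValueError(f"variance fractions must sum to 1 (got {sum(fr.values())})")
        if self.n_years < 2:
            raise ValueError("need at least 2 years")
        if self.mean_family_size < 1:
            raise ValueError("family sizes must be >= 1")


@dataclass
class TrueComponents:
    """Ground-truth per-observation effect vectors and realized fractions."""

    components: dict          # label -> vector (incl. "Res"), canonical order
    realized_fractions: dict
    mu: float

    def phenotype(self) -> np.ndarray:
        return self.mu + sum(self.components.values())


def simulate_pedigree(cfg: SimConfig) -> PedigreeTable:
    """Founders, intermediate crossing generations, then full-sib families.

    Generation 0 holds ``n_founders`` unrelated founders; generations
    1..depth−2 are intermediate crosses (pool size kept at ``n_founders``);
    the final generation holds ``n_families`` full-sib families whose sizes
    follow the capped geometric law.  Output is topologically sorted.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_founders < 2:
        raise ValueError("need at least 2 founders")
    records = [(f"F{i:04d}", None, None) for i in range(cfg.n_founders)]
    prev = [r[0] for r in records]
    for g in range(1, max(2, cfg.generation_depth) - 1):
        cur = []
        for i in range(cfg.n_founders):
            s, d = rng.choice(len(prev), size=2, replace=False)
            iid = f"I{g}_{i:04d}"
            records.append((iid, prev[s], prev[d]))
            cur.append(iid)
        prev = cur
    sizes = np.minimum(rng.geometric(1.0 / cfg.mean_family_size, size=cfg.n_families),
                       cfg.family_size_cap)
    line_no = 0
    for fam in range(cfg.n_families):
        s, d = rng.choice(len(prev), size=2, replace=False)
        for _ in range(int(sizes[fam])):
            records.append((f"L{line_no:05d}", prev[s], prev[d]))
            line_no += 1
    return PedigreeTable(records, generation_depth=cfg.generation_depth)


def line_ids_of(ped: PedigreeTable) -> list:
    """Phenotyped lines: the deepest generation of the pedigree.

    Generation index is 0 for founders and 1 + max(parent generations)
    otherwise; unused founders or mid-pedigree individuals are not lines.
    """
    gen: dict = {}
    for i, s, d in ped.records:
        gen[i] = 1 + max(gen.get(s, -1), gen.get(d, -1))
    deepest = max(gen.values())
    return [i for i, _, _ in ped.records if gen[i] == deepest]


def families_of(ped: PedigreeTable) -> dict:
    """Full-sib families among the lines, keyed by the (sire, dam) pair."""
    lines = set(line_ids_of(ped))
    fams: dict = {}
    for i, s, d in ped.records:
        if i in lines:
            fams.setdefault((s, d), []).append(i)
    return fams


def simulate_genotypes(ped: PedigreeTable, cfg: SimConfig) -> MarkerMatrix:
    """Gene-drop unlinked biallelic markers down the pedigree.

    Founders are drawn from Hardy–Weinberg proportions at per-marker MAFs
    uniform on ``maf_range``; every offspring receives one allele per locus
    per parent uniformly at random (Mendelian sampling), so full sibs share
    identical pedigree relationships while their realized (marker) ones vary.
    """
    if not ped.is_sorted():
        raise ValueError("pedigree must be sorted")
    rng = np.random.default_rng(cfg.seed + 1)
    p = cfg.p_markers
    maf = rng.uniform(*cfg.maf_range, size=p)
    idx = {i: k for k, (i, _, _) in enumerate(ped.records)}
    codes = np.empty((len(ped), p))
    for k, (ind, s, d) in enumerate(ped.records):
        gam = []
        for par in (s, d):
            if par is None:
                gam.append(rng.binomial(1, maf))          # population allele
            else:
                gam.append(rng.binomial(1, codes[idx[par]] / 2.0))
        codes[k] = gam[0] + gam[1]
    if cfg.missing_rate > 0:
        mask = rng.random(codes.shape) < cfg.missing_rate
        codes[mask] = np.nan
    return MarkerMatrix(ped.ids, [f"M{j:05d}" for j in range(p)], codes)


def assign_years(ped: PedigreeTable, cfg: SimConfig) -> PhenotypeTable:
    """Assign each line to exactly one year; some families span two years.

    Families are assigned greedily to the currently smallest year (balanced
    sizes); a fraction ``family_overlap_frac`` of the multi-member families
    is split, sending about half of its members to a second year.  Returns a
    phenotype-table skeleton (trait column all missing).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    fams = list(families_of(ped).values())
    if not fams:
        raise ValueError("pedigree has no final-generation lines")
    years = [f"Y{t + 1}" for t in range(cfg.n_years)]
    order = rng.permutation(len(fams))
    multi = [k for k in order if len(fams[k]) >= 2]
    n_overlap = int(round(cfg.family_overlap_frac * len(fams)))
    if n_overlap > len(multi):
        import warnings

        warnings.warn(
            "requested family overlap infeasible with so many single-member "
            "families; splitting all multi-member families"
        )
        n_overlap = len(multi)
    split = set(multi[:n_overlap])

    counts = {yr: 0 for yr in years}
    rows = []
    for k in order:
        members = fams[k]
        home = min(counts, key=lambda yr: counts[yr])
        if k in split:
            other_choices = [yr for yr in years if yr != home]
            other = other_choices[rng.integers(len(other_choices))]
            half = len(members) // 2 or 1
            sel = set(rng.choice(members, size=half, replace=False))
            for gid in members:
                yr = other if gid in sel else home
                rows.append({"GID": gid, "ENV": yr})
                counts[yr] += 1
        else:
            for gid in members:
                rows.append({"GID": gid, "ENV": home})
                counts[home] += 1
    df = pd.DataFrame(rows).sort_values(["ENV", "GID"], kind="stable")
    df[cfg.trait] = np.nan
    return PhenotypeTable(df.reset_index(drop=True))


def simulate_phenotypes(
    ped: PedigreeTable,
    markers: MarkerMatrix | None,
    years: PhenotypeTable,
    cfg: SimConfig,
) -> tuple[PhenotypeTable, TrueComponents]:
    """Draw each requested component from its kernel and assemble phenotypes.

    Component k (except the residual) is u_k = B_k z, z ~ N(0, I σ²_k), with
    B_k the eigen-factor of that component's observation kernel (normalized
    to mean diagonal 1) and σ²_k the requested fraction of unit total
    variance.  The residual is iid.  Components sum to phenotype − μ exactly.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    df = years.canonical()
    gids = df["GID"].tolist()
    envs = df["ENV"].tolist()
    line_map = IncidenceMap(gids, dict(zip(gids, gids)))
    env_map = IncidenceMap(gids, dict(zip(gids, envs)))

    fractions = {k: v for k, v in cfg.variance_fractions.items() if v > 0}
    labels = [k for k in fractions if k != "Res"]
    need_A = any(l in ("A", "AE", "GA", "GAE") for l in labels)
    need_G = any(l in ("G", "GE", "GA", "GAE") for l in labels)
    A = build_A(ped).restrict(gids) if need_A else None
    G = None
    if need_G:
        if markers is None:
            raise ValueError("variance fractions reference genomic terms but no markers given")
        mm, _ = qc_markers(markers.restrict(gids))   # drop markers fixed among the lines
        G = build_G(impute_and_standardize(mm))
    kernels = build_observation_kernels(line_map, env_map, A=A, G=G, labels=labels)

    n = len(gids)
    comps: dict = {}
    for lb in labels:
        B = factorize(kernels[lb])
        z = rng.standard_normal(B.shape[1]) * np.sqrt(fractions[lb])
        comps[lb] = B @ z
    comps["Res"] = rng.standard_normal(n) * np.sqrt(fractions.get("Res", 0.0))

    y = cfg.mu + sum(comps.values())
    total = float(np.var(y - cfg.mu)) or 1.0
    realized = {lb: float(np.var(v)) / total for lb, v in comps.items()}

    out = df.copy()
    out[cfg.trait] = y
    return PhenotypeTable(out), TrueComponents(comps, realized, cfg.mu)


def simulate_dataset(cfg: SimConfig):
    """Full pipeline: pedigree → genotypes → years → phenotypes.

    Returns ``(ped, markers, phenotypes, truth)``; all randomness flows from
    ``cfg.seed`` through fixed per-stage offsets.
    """
    ped = simulate_pedigree(cfg)
    markers = simulate_genotypes(ped, cfg)
    years = assign_years(ped, cfg)
    pheno, truth = simulate_phenotypes(ped, markers, years, cfg)
    return ped, markers, pheno, truth
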