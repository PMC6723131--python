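"""Registry of the eight multi-kernel prediction models M1–M8.

Every model is y_ij = μ + Σ_k u_k + e_ij with each random term u_k defined by
an observation-level covariance kernel and its own variance component:

    M1: E + A            M5: E + G + A
    M2: E + A + AE       M6: E + G + A + GE + AE
    M3: E + G            M7: E + G + A + GA
    M4: E + G + GE       M8: E + G + A + GA + GAE

``E`` is the environment (year) main effect, ``A`` the pedigree additive
effect, ``G`` the genomic effect, and the interaction terms are Hadamard
products of the expanded main-effect kernels (``GA`` is genome × pedigree,
``GAE`` the three-way genome × pedigree × environment term).
"""

from __future__ import annotations

from dataclasses import dataclass

from .kernels import (
    IncidenceMap,
    Kernel,
    ObsKernel,
    env_kernel,
    expand,
    hadamard,
    normalize_kernel,
)

__all__ = [
    "ModelTerm",
    "ModelSpec",
    "MODEL_TERMS",
    "list_models",
    "make_model",
    "build_observation_kernels",
]

MODEL_TERMS = {
    "M1": ("E", "A"),
    "M2": ("E", "A", "AE"),
    "M3": ("E", "G"),
    "M4": ("E", "G", "GE"),
    "M5": ("E", "G", "A"),
    "M6": ("E", "G", "A", "GE", "AE"),
    "M7": ("E", "G", "A", "GA"),
    "M8": ("E", "G", "A", "GA", "GAE"),
}

VARIANCE_SYMBOLS = {
    "E": "sigma2_E",
    "A": "sigma2_a",
    "G": "sigma2_g",
    "AE": "sigma2_aE",
    "GE": "sigma2_gE",
    "GA": "sigma2_ga",
    "GAE": "sigma2_gaE",
}


@dataclass
class ModelTerm:
    """One random effect: a label, its observation kernel, and its σ² symbol."""

    label: str
    kernel: ObsKernel
    variance_symbol: str = ""

    def __post_init__(self):
        if not self.variance_symbol:
            self.variance_symbol = VARIANCE_SYMBOLS.get(self.label, f"sigma2_{self.label}")


@dataclass
class ModelSpec:
    """An ordered set of random-effect terms plus an iid residual.

    The intercept μ is an implicit fixed effect (flat prior) in every model.
    """

    name: str
    terms: list
    residual_symbol: str = "sigma2_e"

    @property
    def labels(self) -> tuple:
        return tuple(t.label for t in self.terms)

    @property
    def obs_ids(self) -> list:
        return self.terms[0].kernel.obs_ids

    def __post_init__(self):
        if not self.terms:
            raise ValueError("model needs at least one random term")
        first = self.terms[0].kernel.entity_ids
        for t in self.terms[1:]:
            if t.kernel.entity_ids != first:
                raise ValueError(
                    f"term {t.label!r} uses a different observation ordering"
                )


def list_models() -> list[str]:
    """The eight registered model names, in order."""
    return list(MODEL_TERMS)


def make_model(name: str, kernels: dict) -> ModelSpec:
    """Instantiate a registered model from a label → ObsKernel mapping."""
    if name not in MODEL_TERMS:
        raise ValueError(
            f"unknown model {name!r}; valid names: {', '.join(MODEL_TERMS)}"
        )
    terms = []
    for label in MODEL_TERMS[name]:
        if label not in kernels:
            raise ValueError(f"model {name} requires kernel {label!r}, not provided")
        terms.append(ModelTerm(label=label, kernel=kernels[label]))
    return ModelSpec(name=name, terms=terms)


def build_observation_kernels(
    line_map: IncidenceMap,
    env_map: IncidenceMap,
    A: Kernel | None = None,
    G: Kernel | None = None,
    labels=None,
    normalize: bool = True,
) -> dict:
    """Assemble the observation-level kernels for the requested term labels.

    ``line_map`` and ``env_map`` share one canonical observation ordering
    (sort by environment, then line id — which makes the interaction kernels
    literally block-diagonal by environment).  Entity kernels A and G are
    expanded with the line incidence; interactions are Hadamard products.
    With ``normalize`` every returned kernel is scaled to mean diagonal 1 so
    that variance components are on a common per-observation scale.
    """
    if line_map.obs_ids != env_map.obs_ids:
        raise ValueError("line and environment incidence maps disagree on observations")
    if labels is None:
        labels = [l for labs in MODEL_TERMS.values() for l in labs]
    need = set(labels)

    out: dict = {}
    E = env_kernel(env_map)
    if "E" in need:
        out["E"] = E
    A_obs = expand(A, line_map) if A is not None else None
    G_obs = expand(G, line_map) if G is not None else None

    def _req(obj, label, dep):
        if obj is None:
            raise ValueError(f"kernel {label!r} requires the {dep} matrix")
        return obj

    if "A" in need:
        out["A"] = _req(A_obs, "A", "pedigree A")
    if "G" in need:
        out["G"] = _req(G_obs, "G", "genomic G")
    if "AE" in need:
        out["AE"] = hadamard(_req(A_obs, "AE", "pedigree A"), E, name="AE")
    if "GE" in need:
        out["GE"] = hadamard(_req(G_obs, "GE", "genomic G"), E, name="GE")
    ga = None
    if need & {"GA", "GAE"}:
        ga = hadamard(
            _req(G_obs, "GA", "genomic G"), _req(A_obs, "GA", "pedigree A"), name="GA"
        )
    if "GA" in need:
        out["GA"] = ga
    if "GAE" in need:
        out["GAE"] = hadamard(ga, E, name="GAE")
    if normalize:
        out = {k: normalize_kernel(v) for k, v in out.items()}
    return out


def ga_entity_kernel(G: Kernel, A: Kernel) -> Kernel:
    """Line-level genome × pedigree kernel G∘A (A restricted to G's lines).

    When every line is observed once, expanding this entity kernel equals the
    Hadamard product of the separately expanded G and A observation kernels.
    """
    A_r = A.restrict(G.entity_ids)
    return Kernel("GA", G.entity_ids, G.matrix * A_r.matrix)
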