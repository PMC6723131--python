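"""Similarity kernels and the Hadamard-product interaction algebra.

Multi-environment reaction-norm models express every random term through a
covariance (kernel) matrix.  Main effects use entity-level kernels — the
pedigree numerator relationship matrix ``A`` over lines, the genomic
relationship matrix ``G`` over lines, and the environment-membership kernel
``Z_E Z_E'`` over observations.  Interaction terms are built by expanding the
entity kernels to observation level with 0/1 incidence matrices (``Z K Z'``)
and taking element-by-element (Hadamard) products, which preserve positive
semi-definiteness by the Schur product theorem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Kernel",
    "ObsKernel",
    "IncidenceMap",
    "expand",
    "hadamard",
    "env_kernel",
    "verify_block_diagonal",
    "normalize_kernel",
]

#: default relative eigenvalue tolerance for PSD checks
PSD_TOL = 1e-8


@dataclass
class Kernel:
    """A named symmetric positive-semidefinite similarity matrix.

    Parameters
    ----------
    name
        Short label (``A``, ``G``, ``E``, ``AE``, ``GE``, ``GA``, ``GAE`` ...).
    entity_ids
        Ordered identifiers of the entities the rows/columns refer to
        (lines, environments, or observations).
    matrix
        Dense symmetric matrix, unitless similarity.
    """

    name: str
    entity_ids: list
    matrix: np.ndarray

    def __post_init__(self):
        self.entity_ids = list(self.entity_ids)
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.entity_ids)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"kernel {self.name!r}: matrix shape {self.matrix.shape} does "
                f"not match {n} entity ids"
            )
        if len(set(self.entity_ids)) != n:
            raise ValueError(f"kernel {self.name!r}: duplicate entity ids")

    @property
    def n(self) -> int:
        return len(self.entity_ids)

    def index_of(self, ids) -> np.ndarray:
        pos = {e: i for i, e in enumerate(self.entity_ids)}
        try:
            return np.array([pos[i] for i in ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"entity {exc.args[0]!r} not in kernel {self.name!r}")

    def restrict(self, ids) -> "Kernel":
        """Sub-kernel over a subset (or reordering) of entities."""
        idx = self.index_of(ids)
        return Kernel(self.name, list(ids), self.matrix[np.ix_(idx, idx)])

    def is_symmetric(self, tol: float = 1e-10) -> bool:
        return bool(np.allclose(self.matrix, self.matrix.T, atol=tol))

    def min_eigenvalue_ratio(self) -> float:
        """min eigenvalue divided by max eigenvalue (PSD iff >= -tol)."""
        w = np.linalg.eigvalsh(self.matrix)
        top = max(w[-1], np.finfo(float).tiny)
        return float(w[0] / top)

    def check_psd(self, tol: float = PSD_TOL) -> None:
        if not self.is_symmetric():
            raise ValueError(f"kernel {self.name!r} is not symmetric")
        if self.min_eigenvalue_ratio() < -tol:
            raise ValueError(f"kernel {self.name!r} is not PSD within tolerance {tol}")


@dataclass
class ObsKernel(Kernel):
    """A kernel whose entities are observations.

    ``provenance`` records the expression that produced the matrix, e.g.
    ``"(Zg G Zg')∘(ZE ZE')"``, so interaction terms can be audited.
    """

    provenance: str = ""

    @property
    def obs_ids(self) -> list:
        return self.entity_ids


@dataclass
class IncidenceMap:
    """Observation → entity assignment (a 0/1 incidence matrix in disguise).

    Each observation maps to exactly one entity (its line for ``Z_g``, its
    environment for ``Z_E``), so the implied matrix has a single 1 per row.
    """

    obs_ids: list
    entity_of: dict

    def __post_init__(self):
        self.obs_ids = list(self.obs_ids)
        missing = [o for o in self.obs_ids if o not in self.entity_of]
        if missing:
            raise ValueError(f"observations without an entity: {missing[:5]}")

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)

    def entities(self) -> list:
        """Distinct entities in first-appearance order."""
        seen: dict = {}
        for o in self.obs_ids:
            seen.setdefault(self.entity_of[o], None)
        return list(seen)

    def indices(self, entity_ids) -> np.ndarray:
        """Entity index per observation, relative to ``entity_ids``."""
        pos = {e: i for i, e in enumerate(entity_ids)}
        idx = np.empty(self.n_obs, dtype=np.intp)
        for k, o in enumerate(self.obs_ids):
            ent = self.entity_of[o]
            if ent not in pos:
                raise KeyError(f"entity {ent!r} (observation {o!r}) not found")
            idx[k] = pos[ent]
        return idx

    def matrix(self, entity_ids) -> np.ndarray:
        """Dense 0/1 incidence matrix Z (n_obs × n_entities)."""
        Z = np.zeros((self.n_obs, len(entity_ids)))
        Z[np.arange(self.n_obs), self.indices(entity_ids)] = 1.0
        return Z


def expand(K: Kernel, Z: IncidenceMap, name: str | None = None) -> ObsKernel:
    """Expand an entity-level kernel to observation level: ``Z K Z'``.

    The result satisfies ``out[o1, o2] = K[entity(o1), entity(o2)]`` — an
    integer row/column selection, exact to the copy.
    """
    idx = Z.indices(K.entity_ids)
    M = K.matrix[np.ix_(idx, idx)]
    return ObsKernel(
        name=name or K.name,
        entity_ids=Z.obs_ids,
        matrix=M,
        provenance=f"(Zg {K.name} Zg')" if name is None else name,
    )


def hadamard(*kernels: ObsKernel, name: str | None = None) -> ObsKernel:
    """Element-by-element product of observation kernels (Schur product).

    PSD is preserved; operands must share the same observation ordering.
    """
    if len(kernels) < 2:
        raise ValueError("hadamard needs at least two kernels")
    first = kernels[0]
    M = first.matrix.copy()
    for K in kernels[1:]:
        if K.entity_ids != first.entity_ids:
            raise ValueError(
                f"observation ordering mismatch between {first.name!r} and {K.name!r}"
            )
        M *= K.matrix
    prov = "∘".join(getattr(K, "provenance", "") or K.name for K in kernels)
    return ObsKernel(
        name=name or "*".join(K.name for K in kernels),
        entity_ids=first.entity_ids,
        matrix=M,
        provenance=prov,
    )


def env_kernel(Z_E: IncidenceMap) -> ObsKernel:
    """Environment-membership kernel ``Z_E Z_E'``: 1 if same environment.

    This is the covariance structure of the iid environmental main effect
    E_i ~ N(0, σ²_E) written at observation level.
    """
    envs = Z_E.entities()
    idx = Z_E.indices(envs)
    M = (idx[:, None] == idx[None, :]).astype(float)
    return ObsKernel(
        name="E", entity_ids=Z_E.obs_ids, matrix=M, provenance="(ZE ZE')"
    )


def verify_block_diagonal(K: ObsKernel, Z_E: IncidenceMap, tol: float = 1e-12) -> bool:
    """Check that ``K`` is block-diagonal once observations are sorted by environment.

    True for any Hadamard product that includes the environment-membership
    factor: entries linking observations in different environments vanish.
    """
    envs = Z_E.indices(Z_E.entities())
    order = np.argsort(envs, kind="stable")
    M = K.matrix[np.ix_(order, order)]
    e = envs[order]
    off = e[:, None] != e[None, :]
    return bool(np.all(np.abs(M[off]) <= tol))


def normalize_kernel(K: Kernel) -> Kernel:
    """Scale a kernel so its mean diagonal equals 1.

    Makes variance components attached to different kernels directly
    comparable (the expected per-observation variance contributed by a term
    is σ²_k · mean diag K_k).
    """
    d = float(np.mean(np.diag(K.matrix)))
    if d <= 0:
        raise ValueError(f"kernel {K.name!r} has non-positive mean diagonal")
    out = Kernel(K.name, K.entity_ids, K.matrix / d)
    if isinstance(K, ObsKernel):
        out = ObsKernel(K.name, K.entity_ids, K.matrix / d, provenance=K.provenance)
    return out
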