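"""Marker QC, standardization, and the genomic relationship matrix G.

Biallelic SNPs are coded 0/1/2 (minor-allele dosage) with possible missing
calls.  Quality control discards markers with more than ``max_missing``
missing values or a minor allele frequency below ``min_maf``.  Surviving
markers are mean-imputed and column-standardized to form X, and the genomic
relationship matrix is G = X X' / p — the realized-relatedness counterpart of
the pedigree expectation A.  The genomic breeding value g_j = Σ_m x_jm b_m
with b_m ~ N(0, σ²_b) has Cov(g) = G σ²_g with σ²_g = p σ²_b, which the
kernel-vs-ridge duality tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import Kernel

__all__ = [
    "MarkerMatrix",
    "StandardizedGenotypes",
    "QCReport",
    "qc_markers",
    "impute_and_standardize",
    "build_G",
]


@dataclass
class MarkerMatrix:
    """Lines × markers dosage codes in {0, 1, 2}, NaN for missing."""

    line_ids: list
    marker_ids: list
    codes: np.ndarray

    def __post_init__(self):
        self.line_ids = list(self.line_ids)
        self.marker_ids = list(self.marker_ids)
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.line_ids)} lines × {len(self.marker_ids)} markers"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        obs = self.codes[np.isfinite(self.codes)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            bad = np.unique(obs[~np.isin(obs, (0.0, 1.0, 2.0))])
            raise ValueError(f"marker codes outside {{0,1,2,NA}}: {bad[:5]}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def restrict(self, line_ids) -> "MarkerMatrix":
        pos = {l: i for i, l in enumerate(self.line_ids)}
        idx = np.array([pos[l] for l in line_ids], dtype=np.intp)
        return MarkerMatrix(list(line_ids), self.marker_ids, self.codes[idx])


@dataclass
class StandardizedGenotypes:
    """Column-standardized genotype matrix X (mean 0, sd 1 per marker)."""

    line_ids: list
    marker_ids: list
    X: np.ndarray

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class QCReport:
    n_input: int
    n_removed_missing: int
    n_removed_maf: int
    n_retained: int


def marker_maf(codes: np.ndarray) -> np.ndarray:
    """Per-marker minor allele frequency from observed (non-missing) calls."""
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(codes, axis=0) / 2.0
    return np.minimum(freq, 1.0 - freq)


def qc_markers(
    raw: MarkerMatrix, max_missing: float = 0.30, min_maf: float = 0.05
) -> tuple[MarkerMatrix, QCReport]:
    """Discard markers with more than ``max_missing`` missing or MAF below ``min_maf``.

    Boundary semantics are strict on the removal side: exactly 30% missing is
    kept, MAF exactly 0.05 is kept.  The line set is unchanged.  Returns the
    filtered matrix and a report of removal counts by reason (a marker failing
    both is counted under the missingness reason).
    """
    miss_frac = np.mean(np.isnan(raw.codes), axis=0)
    maf = marker_maf(raw.codes)
    bad_missing = miss_frac > max_missing
    # all-missing markers have undefined MAF; they are already removed above
    bad_maf = ~bad_missing & (np.nan_to_num(maf, nan=0.0) < min_maf)
    keep = ~(bad_missing | bad_maf)
    if not keep.any():
        raise ValueError(
            "all markers removed by QC; review max_missing/min_maf thresholds"
        )
    out = MarkerMatrix(
        raw.line_ids,
        [m for m, k in zip(raw.marker_ids, keep) if k],
        raw.codes[:, keep],
    )
    report = QCReport(
        n_input=raw.n_markers,
        n_removed_missing=int(bad_missing.sum()),
        n_removed_maf=int(bad_maf.sum()),
        n_retained=int(keep.sum()),
    )
    return out, report


def impute_and_standardize(m: MarkerMatrix) -> StandardizedGenotypes:
    """Mean-impute missing codes, then center and scale each marker to sd 1."""
    codes = m.codes.copy()
    mu = np.nanmean(codes, axis=0)
    nan_r, nan_c = np.where(np.isnan(codes))
    codes[nan_r, nan_c] = mu[nan_c]
    sd = codes.std(axis=0)
    if (sd < 1e-12).any():
        bad = [m.marker_ids[j] for j in np.where(sd < 1e-12)[0][:5]]
        raise ValueError(
            f"zero-variance marker(s) after imputation (should have been "
            f"removed by the MAF filter): {bad}"
        )
    X = (codes - codes.mean(axis=0)) / sd
    return StandardizedGenotypes(m.line_ids, m.marker_ids, X)


def build_G(X: StandardizedGenotypes) -> Kernel:
    """Genomic relationship matrix G = X X' / p over lines."""
    if X.p == 0:
        raise ValueError("no markers: cannot build G")
    G = X.X @ X.X.T / X.p
    return Kernel(name="G", entity_ids=X.line_ids, matrix=G)
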