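"""Coexpression network construction: correlation, adjacency, topological overlap.

Two adjacency modes are supported. The *hard* mode thresholds the absolute
Pearson correlation at tau (binary, unweighted network); the *soft* mode
raises it to a power beta (weighted network with connection strengths in
[0, 1]). The topological overlap of an adjacency matrix combines direct
connection strength with shared-neighbor strength:

    omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with l_ij = sum_u a_iu * a_uj and connectivity k_i = sum_u a_iu. For a
binary adjacency, l_ij is the number of common neighbors of i and j.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from coexnet.preprocess import ExpressionMatrix

_SYM_TOL = 1e-12


def _check_square_symmetric(mat: np.ndarray, n: int, name: str) -> None:
    if mat.shape != (n, n):
        raise ValueError(f"{name} must be {n}x{n}, got {mat.shape}")
    if not np.allclose(mat, mat.T, atol=_SYM_TOL, rtol=0.0):
        raise ValueError(f"{name} must be symmetric")


@dataclass
class CorrelationMatrix:
    """Symmetric gene-gene Pearson correlation matrix with unit diagonal."""

    gene_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        _check_square_symmetric(self.r, len(self.gene_ids), "correlation matrix")
        if np.any(np.abs(self.r) > 1 + 1e-9):
            raise ValueError("correlation entries must lie in [-1, 1]")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-12):
            raise ValueError("correlation diagonal must be exactly 1")


@dataclass
class AdjacencyMatrix:
    """Symmetric connection-strength matrix with zero diagonal.

    ``mode`` is ``"hard"`` (binary entries, threshold ``threshold_tau``) or
    ``"soft"`` (continuous entries in [0, 1], power ``power_beta``).
    """

    gene_ids: list[str]
    a: np.ndarray
    mode: str
    threshold_tau: float | None = field(default=None)
    power_beta: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        _check_square_symmetric(self.a, len(self.gene_ids), "adjacency matrix")
        if self.mode not in ("hard", "soft"):
            raise ValueError(f"unknown adjacency mode {self.mode!r}")
        if np.any(self.a < 0) or np.any(self.a > 1):
            raise ValueError("adjacency entries must lie in [0, 1]")
        if np.any(np.diag(self.a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if self.mode == "hard" and not np.all(np.isin(self.a, (0.0, 1.0))):
            raise ValueError("hard adjacency entries must be binary")

    @property
    def connectivity(self) -> np.ndarray:
        """Per-gene connectivity k_i = sum_j a_ij (degree in hard mode)."""
        return self.a.sum(axis=1)


@dataclass
class TOMResult:
    """Topological overlap similarity (omega) and dissimilarity (1 - omega)."""

    gene_ids: list[str]
    omega: np.ndarray
    dissim: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.dissim = np.asarray(self.dissim, dtype=float)
        _check_square_symmetric(self.omega, len(self.gene_ids), "omega")
        if not np.array_equal(self.dissim, 1.0 - self.omega):
            raise ValueError("dissim must equal 1 - omega exactly")


def correlation_matrix(m: ExpressionMatrix) -> CorrelationMatrix:
    """Pairwise Pearson correlations between gene expression profiles.

    Raises
    ------
    ValueError
        If there are fewer than 3 samples, or a gene has zero variance
        (the offending gene is named).
    """
    if m.n_samples < 3:
        raise ValueError("correlation requires at least 3 samples")
    sd = m.values.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = ", ".join(m.gene_ids[i] for i in zero[:5])
        raise ValueError(f"zero-variance gene(s): {names}")
    r = np.corrcoef(m.values)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(gene_ids=list(m.gene_ids), r=r)


def hard_adjacency(c: CorrelationMatrix, tau: float = 0.7) -> AdjacencyMatrix:
    """Binary adjacency: a_ij = 1 iff |r_ij| >= tau and i != j.

    The threshold is inclusive: |r| exactly equal to tau counts as
    connected.
    """
    if not 0 < tau <= 1:
        raise ValueError(f"tau must lie in (0, 1], got {tau}")
    a = (np.abs(c.r) >= tau).astype(float)
    np.fill_diagonal(a, 0.0)
    return AdjacencyMatrix(gene_ids=list(c.gene_ids), a=a, mode="hard", threshold_tau=tau)


def soft_adjacency(c: CorrelationMatrix, beta: float = 7.0) -> AdjacencyMatrix:
    """Weighted adjacency: a_ij = |r_ij|**beta for i != j, zero diagonal."""
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    a = np.abs(c.r) ** beta
    np.fill_diagonal(a, 0.0)
    return AdjacencyMatrix(gene_ids=list(c.gene_ids), a=a, mode="soft", power_beta=beta)


def topological_overlap(adj: AdjacencyMatrix) -> TOMResult:
    """Topological overlap matrix of a (hard or soft) adjacency.

    omega_ii = 1 by convention; isolated node pairs get omega_ij = 0.
    The denominator min(k_i, k_j) + 1 - a_ij is always >= 1 because
    k_i >= a_ij and a_ij <= 1.
    """
    a = adj.a
    k = a.sum(axis=1)
    l = a @ a
    min_k = np.minimum.outer(k, k)
    omega = (l + a) / (min_k + 1.0 - a)
    np.fill_diagonal(omega, 1.0)
    omega = np.clip((omega + omega.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(omega, 1.0)
    return TOMResult(gene_ids=list(adj.gene_ids), omega=omega, dissim=1.0 - omega)
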