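"""Module detection: average-linkage clustering of TOM dissimilarity and summaries.

Genes are clustered with UPGMA on d = 1 - omega, the tree is cut at a
fixed height, and branches below the minimum size are set aside as "grey"
(unassigned). Module colors follow the conventional size-ranked palette:
the largest module is always "turquoise".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from coexnet.network import AdjacencyMatrix, TOMResult

GREY = "grey"

#: Size-ranked module color palette (largest module first).
COLOR_ORDER = (
    "turquoise",
    "blue",
    "brown",
    "yellow",
    "green",
    "red",
    "black",
    "pink",
    "magenta",
    "purple",
    "greenyellow",
    "tan",
    "salmon",
    "cyan",
    "midnightblue",
    "lightcyan",
    "grey60",
    "lightgreen",
    "lightyellow",
    "royalblue",
)


def _color_name(rank: int) -> str:
    if rank < len(COLOR_ORDER):
        return COLOR_ORDER[rank]
    return f"module{rank + 1}"


@dataclass
class ModuleAssignment:
    """Gene -> module-color map plus the dendrogram it was cut from."""

    gene_ids: list[str]
    color: dict[str, str]
    dendrogram: np.ndarray
    height_cutoff: float
    min_module_size: int

    def __post_init__(self) -> None:
        missing = [g for g in self.gene_ids if g not in self.color]
        if missing:
            raise ValueError(f"genes without a color: {missing[:5]}")

    @property
    def module_colors(self) -> list[str]:
        """Non-grey colors, in canonical (size-ranked) order."""
        seen = [c for c in self.color.values() if c != GREY]
        order = {c: i for i, c in enumerate(COLOR_ORDER)}
        return sorted(set(seen), key=lambda c: order.get(c, len(order)))

    def members(self, color: str) -> list[str]:
        return [g for g in self.gene_ids if self.color[g] == color]

    def sizes(self) -> dict[str, int]:
        """Gene counts per color, grey included."""
        out: dict[str, int] = {}
        for g in self.gene_ids:
            out[self.color[g]] = out.get(self.color[g], 0) + 1
        return out


@dataclass
class ModuleSummary:
    color: str
    size: int
    mean_connectivity: float
    intramodular_connectivity: dict[str, float]


@dataclass
class ModuleSummaryReport:
    """Per-module summaries (grey excluded) plus network-level bookkeeping."""

    modules: list[ModuleSummary]
    sizes: dict[str, int]
    effective_mean_degree: float
    intramodular_connectivity: dict[str, float] = field(default_factory=dict)


def hierarchical_cluster(d: TOMResult) -> np.ndarray:
    """Average-linkage (UPGMA) merge tree over genes using TOM dissimilarity.

    Returns a SciPy linkage matrix. The input dissimilarity must be
    square, symmetric, and zero on the diagonal.
    """
    dissim = np.asarray(d.dissim, dtype=float)
    n = len(d.gene_ids)
    if dissim.shape != (n, n):
        raise ValueError("dissimilarity must be square and match gene_ids")
    if not np.allclose(dissim, dissim.T, atol=1e-12, rtol=0.0):
        raise ValueError("dissimilarity must be symmetric")
    if np.any(np.diag(dissim) != 0):
        raise ValueError("dissimilarity diagonal must be zero")
    condensed = squareform((dissim + dissim.T) / 2.0, checks=False)
    return linkage(condensed, method="average")


def cut_modules(
    dendrogram: np.ndarray,
    gene_ids: list[str],
    height_cutoff: float = 0.99,
    min_module_size: int = 20,
) -> ModuleAssignment:
    """Partition genes by cutting the merge tree at a fixed height.

    Branches whose cophenetic distance stays below ``height_cutoff`` form
    candidate modules; those smaller than ``min_module_size`` are assigned
    grey. Surviving modules are colored by decreasing size (ties broken by
    the smallest member gene id) in the canonical palette order.
    """
    if not 0 < height_cutoff <= 1:
        raise ValueError(f"height_cutoff must lie in (0, 1], got {height_cutoff}")
    if min_module_size < 1:
        raise ValueError("min_module_size must be >= 1")
    n = len(gene_ids)
    if n == 1:
        labels = np.array([1])
    else:
        labels = fcluster(dendrogram, t=height_cutoff, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(i)
    surviving = [idx for idx in clusters.values() if len(idx) >= min_module_size]
    surviving.sort(key=lambda idx: (-len(idx), min(gene_ids[i] for i in idx)))
    color = {g: GREY for g in gene_ids}
    for rank, idx in enumerate(surviving):
        name = _color_name(rank)
        for i in idx:
            color[gene_ids[i]] = name
    return ModuleAssignment(
        gene_ids=list(gene_ids),
        color=color,
        dendrogram=dendrogram,
        height_cutoff=height_cutoff,
        min_module_size=min_module_size,
    )


def module_summaries(
    assign: ModuleAssignment, adj: AdjacencyMatrix
) -> ModuleSummaryReport:
    """Per-module size, mean connectivity, and intramodular connectivity.

    Grey genes are excluded from module summaries but appear in the size
    ledger. The network-level effective mean degree is the mean
    connectivity over non-isolated nodes.
    """
    if list(assign.gene_ids) != list(adj.gene_ids):
        raise ValueError("assignment and adjacency gene ids do not match")
    k = adj.connectivity
    index = {g: i for i, g in enumerate(adj.gene_ids)}
    intra_all: dict[str, float] = {}
    summaries = []
    for color in assign.module_colors:
        members = assign.members(color)
        rows = np.array([index[g] for g in members])
        sub = adj.a[np.ix_(rows, rows)]
        intra = sub.sum(axis=1)
        for g, v in zip(members, intra):
            intra_all[g] = float(v)
        summaries.append(
            ModuleSummary(
                color=color,
                size=len(members),
                mean_connectivity=float(k[rows].mean()),
                intramodular_connectivity={
                    g: float(v) for g, v in zip(members, intra)
                },
            )
        )
    non_isolated = k[k > 0]
    emd = float(non_isolated.mean()) if non_isolated.size else 0.0
    return ModuleSummaryReport(
        modules=summaries,
        sizes=assign.sizes(),
        effective_mean_degree=emd,
        intramodular_connectivity=intra_all,
    )
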