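"""Node centralities, clustering coefficients, and degree-distribution model fits.

Betweenness and closeness centralities are computed on the binary (hard
threshold) network by default; a weighted mode interprets adjacency
strengths via an edge-length transform (1/a or 1-a). Degree distributions
are fit by ordinary least squares of log10 p(k) on log10 k, optionally
with an extra linear term in k for the exponentially truncated power law
p(k) ~ k**-r * exp(-alpha*k).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from coexnet.network import AdjacencyMatrix

EDGE_LENGTHS = ("reciprocal", "one_minus")


@dataclass
class NodeTopologyProfile:
    """Per-gene topology metrics; degree equals the adjacency row sum."""

    gene_id: str
    degree: float
    betweenness: float
    closeness: float
    clustering_coefficient: float


@dataclass
class DegreeDistributionFit:
    """OLS fit of a degree-distribution model on log-log axes.

    For ``model="power_law"`` the reported ``exponent`` is the log-log
    regression slope (negative for decaying distributions). For
    ``model="truncated_power_law"`` the fit is parameterized as
    p(k) ~ k**-exponent * exp(-alpha*k), so ``exponent`` is positive for
    a decaying power-law part and ``alpha`` is the exponential rate.
    """

    model: str
    exponent: float
    r_squared: float
    alpha: float | None = field(default=None)
    bins: list[tuple[float, float]] = field(default_factory=list)


def _graph(adj: AdjacencyMatrix, weighted: bool, edge_length: str) -> nx.Graph:
    n = len(adj.gene_ids)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    rows, cols = np.nonzero(np.triu(adj.a, k=1))
    if weighted:
        if edge_length not in EDGE_LENGTHS:
            raise ValueError(f"edge_length must be one of {EDGE_LENGTHS}")
        for i, j in zip(rows, cols):
            a = adj.a[i, j]
            length = 1.0 / a if edge_length == "reciprocal" else 1.0 - a
            g.add_edge(int(i), int(j), length=length)
    else:
        g.add_edges_from(zip(rows.tolist(), cols.tolist()))
    return g


def betweenness_centrality(
    adj: AdjacencyMatrix,
    normalized: bool = True,
    weighted: bool = False,
    edge_length: str = "reciprocal",
) -> dict[str, float]:
    """Fraction of shortest paths between other node pairs passing through each node.

    Edges of a hard adjacency are unweighted; with ``weighted=True`` each
    edge gets geodesic length 1/a_ij (or 1-a_ij). Normalization divides by
    the (n-1)(n-2) ordered pairs so values lie in [0, 1]; disconnected
    pairs contribute nothing. Networks with fewer than 3 nodes have all
    betweenness zero.
    """
    n = len(adj.gene_ids)
    if n < 3:
        return {g: 0.0 for g in adj.gene_ids}
    g = _graph(adj, weighted, edge_length)
    bc = nx.betweenness_centrality(
        g, normalized=normalized, weight="length" if weighted else None
    )
    return {adj.gene_ids[i]: float(bc[i]) for i in range(n)}


def closeness_centrality(
    adj: AdjacencyMatrix,
    weighted: bool = False,
    edge_length: str = "reciprocal",
) -> dict[str, float]:
    """Component-scaled closeness: (reachable/(n-1)) * (reachable/total distance).

    Isolated nodes get 0. On a connected unweighted network this is the
    usual (n-1)/sum-of-geodesics closeness.
    """
    n = len(adj.gene_ids)
    g = _graph(adj, weighted, edge_length)
    cc = nx.closeness_centrality(
        g, distance="length" if weighted else None, wf_improved=True
    )
    return {adj.gene_ids[i]: float(cc[i]) for i in range(n)}


def clustering_coefficients(adj: AdjacencyMatrix) -> dict[str, float]:
    """Weighted clustering coefficient; reduces to 2*triangles/(k(k-1)) when binary.

    c_i = sum_{j!=i} sum_{l!=i,j} a_ij a_jl a_li / ((sum_j a_ij)^2 - sum_j a_ij^2),
    defined as 0 where the denominator vanishes.
    """
    a = adj.a
    numer = np.diag(a @ a @ a).copy()
    k = a.sum(axis=1)
    denom = k**2 - (a**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)
    return {g: float(c[i]) for i, g in enumerate(adj.gene_ids)}


def topology_profiles(
    adj: AdjacencyMatrix,
    weighted: bool = False,
    edge_length: str = "reciprocal",
) -> list[NodeTopologyProfile]:
    """Degree/connectivity, betweenness, closeness, and clustering per gene."""
    k = adj.connectivity
    bc = betweenness_centrality(adj, weighted=weighted, edge_length=edge_length)
    cl = closeness_centrality(adj, weighted=weighted, edge_length=edge_length)
    cc = clustering_coefficients(adj)
    return [
        NodeTopologyProfile(
            gene_id=g,
            degree=float(k[i]),
            betweenness=bc[g],
            closeness=cl[g],
            clustering_coefficient=cc[g],
        )
        for i, g in enumerate(adj.gene_ids)
    ]


def fit_degree_model(
    k: np.ndarray, pk: np.ndarray, model: str = "power_law"
) -> DegreeDistributionFit:
    """Fit a degree-distribution model to pre-binned (k, p(k)) points.

    Bins with k <= 0 or p(k) <= 0 are dropped (they have no log-log
    representation); at least 3 usable bins are required.
    """
    if model not in ("power_law", "truncated_power_law"):
        raise ValueError(f"unknown model {model!r}")
    k = np.asarray(k, dtype=float)
    pk = np.asarray(pk, dtype=float)
    keep = (k > 0) & (pk > 0)
    k, pk = k[keep], pk[keep]
    if k.size < 3:
        raise ValueError(f"need at least 3 usable bins, got {k.size}")
    logk = np.log10(k)
    logp = np.log10(pk)
    if model == "power_law":
        design = np.column_stack([np.ones_like(logk), logk])
    else:
        design = np.column_stack([np.ones_like(logk), logk, k])
    coef, *_ = np.linalg.lstsq(design, logp, rcond=None)
    fitted = design @ coef
    ss_res = float(np.sum((logp - fitted) ** 2))
    ss_tot = float(np.sum((logp - logp.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    r2 = min(max(r2, 0.0), 1.0)
    bins = list(zip(k.tolist(), pk.tolist()))
    if model == "power_law":
        return DegreeDistributionFit(
            model=model, exponent=float(coef[1]), r_squared=r2, bins=bins
        )
    return DegreeDistributionFit(
        model=model,
        exponent=float(-coef[1]),
        alpha=float(-coef[2] * math.log(10.0)),
        r_squared=r2,
        bins=bins,
    )


def degree_distribution_fit(
    degrees: np.ndarray,
    model: str = "power_law",
    n_bins: int = 15,
    binning: str = "auto",
) -> DegreeDistributionFit:
    """Bin observed degrees into an empirical p(k) and fit a model to it.

    Integer (binary-network) degrees are binned per distinct value;
    continuous connectivities are binned into ``n_bins`` equal-width bins
    on log10 k with probability density per bin. ``binning`` may be
    "integer", "log", or "auto" (integer iff all degrees are integral).
    """
    degrees = np.asarray(degrees, dtype=float)
    if binning == "auto":
        binning = "integer" if np.all(degrees == np.round(degrees)) else "log"
    if binning not in ("integer", "log"):
        raise ValueError(f"unknown binning {binning!r}")
    total = degrees.size
    if total == 0:
        raise ValueError("no degrees supplied")
    positive = degrees[degrees > 0]
    if binning == "integer":
        ks, counts = np.unique(positive, return_counts=True)
        pk = counts / total
        return fit_degree_model(ks, pk, model=model)
    if positive.size < 3:
        raise ValueError("need at least 3 positive connectivities for log binning")
    lo, hi = np.log10(positive.min()), np.log10(positive.max())
    if hi <= lo:
        raise ValueError("connectivities span a single value; cannot bin")
    edges = np.logspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(positive, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    density = counts / (total * widths)
    return fit_degree_model(centers, density, model=model)


@dataclass
class Candidate:
    """A hub/bottleneck gene with the selection criteria that picked it."""

    gene_id: str
    selected_by: tuple[str, ...]
    degree: float
    betweenness: float


def select_candidates(
    profiles: list[NodeTopologyProfile], n_top_degree: int, n_top_bc: int
) -> list[Candidate]:
    """Union of the top genes by degree and by betweenness centrality.

    Ties are broken by the other metric, then by gene id. A gene ranking
    in both lists appears once, tagged with both criteria.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    if n_top_degree < 0 or n_top_bc < 0:
        raise ValueError("selection counts must be non-negative")
    if max(n_top_degree, n_top_bc) > len(profiles):
        raise ValueError(
            f"requested {max(n_top_degree, n_top_bc)} genes from {len(profiles)} profiles"
        )
    by_degree = sorted(profiles, key=lambda p: (-p.degree, -p.betweenness, p.gene_id))
    by_bc = sorted(profiles, key=lambda p: (-p.betweenness, -p.degree, p.gene_id))
    tags: dict[str, list[str]] = {}
    info: dict[str, NodeTopologyProfile] = {}
    for p in by_degree[:n_top_degree]:
        tags.setdefault(p.gene_id, []).append("degree")
        info[p.gene_id] = p
    for p in by_bc[:n_top_bc]:
        tags.setdefault(p.gene_id, []).append("betweenness")
        info[p.gene_id] = p
    ordered = [p.gene_id for p in by_degree[:n_top_degree]] + [
        p.gene_id for p in by_bc[:n_top_bc] if "degree" not in tags[p.gene_id]
    ]
    return [
        Candidate(
            gene_id=g,
            selected_by=tuple(tags[g]),
            degree=info[g].degree,
            betweenness=info[g].betweenness,
        )
        for g in ordered
    ]
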