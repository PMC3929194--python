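"""Gene-set over-representation testing with Fisher's exact test.

Per gene set, a 2x2 contingency table (module vs set membership over the
gene universe) is tested one-sided for over-representation; p-values are
adjusted across sets with Benjamini-Hochberg by default. The optional
EASE variant subtracts one from the overlap before testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    """Named gene sets filtered to a gene universe; empty sets are dropped."""

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: list[str]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            raise ValueError("universe contains duplicate gene ids")
        filtered: dict[str, tuple[str, frozenset[str]]] = {}
        for set_id, (name, members) in self.sets.items():
            kept = frozenset(members) & uni
            if kept:
                filtered[set_id] = (name, kept)
        self.sets = filtered

    @classmethod
    def from_records(
        cls, records: list[tuple[str, str, list[str]]], universe: list[str]
    ) -> "GeneSetCollection":
        """Build from (set_id, description, members) records (e.g. parsed GMT)."""
        sets: dict[str, tuple[str, frozenset[str]]] = {}
        for set_id, desc, members in records:
            if set_id in sets:
                raise ValueError(f"duplicate gene-set id: {set_id}")
            sets[set_id] = (desc, frozenset(members))
        return cls(sets=sets, universe=list(universe))


@dataclass
class EnrichmentResult:
    set_id: str
    name: str
    overlap_count: int
    module_size: int
    set_size: int
    universe_size: int
    p_value: float
    adjusted_p: float = field(default=1.0)
    overlap_genes: tuple[str, ...] = field(default=())


def fisher_enrichment(
    module_genes: list[str],
    sets: GeneSetCollection,
    alternative: str = "greater",
    ease: bool = False,
    correction: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """One-sided Fisher's exact over-representation test per gene set.

    Parameters
    ----------
    module_genes :
        Genes of the module under test; must be a subset of the universe.
    sets :
        The gene-set collection (defines the universe).
    alternative :
        Tail passed to :func:`scipy.stats.fisher_exact`; "greater" tests
        over-representation.
    ease :
        If true, subtract 1 from the observed overlap (EASE-score style
        conservative variant).
    correction :
        Multiple-testing method understood by
        :func:`statsmodels.stats.multitest.multipletests`.

    Returns results sorted by ascending p-value.
    """
    universe = set(sets.universe)
    module = set(module_genes)
    outside = sorted(module - universe)
    if outside:
        raise ValueError(f"module genes outside the universe: {outside[:10]}")
    u = len(universe)
    m = len(module)
    results = []
    for set_id, (name, members) in sets.sets.items():
        overlap = module & members
        a = len(overlap)
        if ease:
            a = max(a - 1, 0)
        table = [[a, m - a], [len(members) - a, u - m - len(members) + a]]
        _, p = fisher_exact(table, alternative=alternative)
        results.append(
            EnrichmentResult(
                set_id=set_id,
                name=name,
                overlap_count=len(overlap),
                module_size=m,
                set_size=len(members),
                universe_size=u,
                p_value=float(min(p, 1.0)),
                overlap_genes=tuple(sorted(overlap)),
            )
        )
    if results:
        _, adjusted, *_ = multipletests([r.p_value for r in results], method=correction)
        for r, adj in zip(results, adjusted):
            r.adjusted_p = float(max(adj, r.p_value))
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results
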