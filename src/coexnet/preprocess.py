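"""Expression-matrix container, quantile normalization, and probe collapsing.

All downstream stages consume an :class:`ExpressionMatrix` of log2-scale
values with genes in rows and samples in columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 expression values.

    Parameters
    ----------
    gene_ids :
        Ordered row labels (probe or gene identifiers), unique.
    sample_ids :
        Ordered column labels, unique.
    values :
        Real matrix of shape ``(len(gene_ids), len(sample_ids))``; every
        entry must be finite (missing values are not supported).
    probe_map :
        Optional map from row label (probe) to gene label, required by
        :func:`collapse_probes`.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    probe_map: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def copy(self) -> "ExpressionMatrix":
        return replace(
            self,
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            values=self.values.copy(),
            probe_map=dict(self.probe_map) if self.probe_map is not None else None,
        )


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the same reference distribution.

    The reference is the row-wise mean of the column-sorted matrix; each
    column's values are replaced by the reference values at their ranks.
    Ties within a column receive the mean of the reference values at the
    tied rank positions.

    Raises
    ------
    ValueError
        If fewer than two samples are present.
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    vals = m.values
    n = m.n_genes
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(m.n_samples):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = reference
        # ties share the mean of the reference values at their positions
        sorted_col = col[order]
        start = 0
        for end in range(1, n + 1):
            if end == n or sorted_col[end] != sorted_col[start]:
                if end - start > 1:
                    assigned[order[start:end]] = reference[start:end].mean()
                start = end
        out[:, j] = assigned
    result = m.copy()
    result.values = out
    return result


def collapse_probes(m: ExpressionMatrix, min_probes: int = 2) -> ExpressionMatrix:
    """Collapse probe rows to one mean row per gene.

    Rows are grouped via ``m.probe_map``; each retained gene's row is the
    arithmetic mean of its probes' rows. Genes matched by fewer than
    ``min_probes`` probes are dropped, as are probes absent from the map.

    Raises
    ------
    ValueError
        If ``m.probe_map`` is missing.
    """
    if m.probe_map is None:
        raise ValueError("collapse_probes requires probe_map on the expression matrix")
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    groups: dict[str, list[int]] = {}
    for i, probe in enumerate(m.gene_ids):
        gene = m.probe_map.get(probe)
        if gene is not None:
            groups.setdefault(gene, []).append(i)
    kept = sorted(g for g, rows in groups.items() if len(rows) >= min_probes)
    values = np.array(
        [m.values[groups[g], :].mean(axis=0) for g in kept]
    ).reshape(len(kept), m.n_samples)
    return ExpressionMatrix(
        gene_ids=kept, sample_ids=list(m.sample_ids), values=values, probe_map=None
    )
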