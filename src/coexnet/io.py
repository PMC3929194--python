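"""Readers and writers for the plain-text formats the pipeline touches.

Matrices travel as TSV (first column = gene id, header row = sample or
gene ids), gene sets as GMT, traits/fixtures as CSV, networks as edge
lists or GraphML. Floats are written with 17 significant digits so a
write/read round trip reproduces values to better than 1e-12.
"""

from __future__ import annotations

import csv
from pathlib import Path

import networkx as nx
import numpy as np

from coexnet.modules import ModuleAssignment
from coexnet.network import AdjacencyMatrix
from coexnet.preprocess import ExpressionMatrix
from coexnet.validation import ValidationFixture

_FLOAT_FMT = "%.17g"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """TSV with header ``gene_id<TAB>sample...`` and one row per gene."""
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(m.sample_ids) + "\n")
        for i, g in enumerate(m.gene_ids):
            fh.write(g + "\t" + "\t".join(_fmt(v) for v in m.values[i]) + "\n")


def read_expression(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}:1: empty header line")
        sample_ids = header.split("\t")[1:]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(sample_ids) + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} fields, "
                    f"got {len(parts)}"
                )
            gene_ids.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return ExpressionMatrix(
        gene_ids=gene_ids, sample_ids=sample_ids, values=np.array(rows)
    )


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (probe, gene)."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
            mapping[parts[0]] = parts[1]
    return mapping


def write_matrix(gene_ids: list[str], mat: np.ndarray, path: str | Path) -> None:
    """Square gene x gene matrix as TSV with gene ids on both axes."""
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(gene_ids) + "\n")
        for i, g in enumerate(gene_ids):
            fh.write(g + "\t" + "\t".join(_fmt(v) for v in mat[i]) + "\n")


def read_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        gene_ids = header[1:]
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(gene_ids) + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {len(gene_ids) + 1} fields, "
                    f"got {len(parts)}"
                )
            rows.append([float(v) for v in parts[1:]])
    return gene_ids, np.array(rows)


def read_gmt(path: str | Path) -> list[tuple[str, str, list[str]]]:
    """GMT gene sets: tab-separated set id, description, member genes.

    Raises on malformed lines (with line number) and duplicate set ids.
    """
    path = Path(path)
    records: list[tuple[str, str, list[str]]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs id, description and >=1 member"
                )
            set_id = parts[0]
            if set_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set id {set_id!r}")
            seen.add(set_id)
            records.append((set_id, parts[1], [g for g in parts[2:] if g]))
    return records


def write_fixture(fixture: list[ValidationFixture], path: str | Path) -> None:
    """CSV with animal, group, age_months, imf_percent, housekeeping + gene columns."""
    genes = sorted({g for f in fixture for g in f.expression})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["animal", "group", "age_months", "imf_percent", "housekeeping", *genes])
        for f in fixture:
            writer.writerow(
                [
                    f.animal_id,
                    f.group,
                    _fmt(f.age_months),
                    _fmt(f.imf_percent),
                    _fmt(f.housekeeping),
                    *[_fmt(f.expression[g]) if g in f.expression else "" for g in genes],
                ]
            )


def read_fixture(path: str | Path) -> list[ValidationFixture]:
    path = Path(path)
    fixture: list[ValidationFixture] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"animal", "group", "age_months", "imf_percent"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = sorted(required - set(reader.fieldnames or []))
            raise ValueError(f"{path}: missing required columns {missing}")
        gene_cols = [
            c
            for c in reader.fieldnames
            if c not in required and c != "housekeeping"
        ]
        for lineno, row in enumerate(reader, start=2):
            try:
                fixture.append(
                    ValidationFixture(
                        animal_id=row["animal"],
                        group=row["group"],
                        age_months=float(row["age_months"]),
                        imf_percent=float(row["imf_percent"]),
                        housekeeping=float(row.get("housekeeping") or 1.0),
                        expression={
                            g: float(row[g]) for g in gene_cols if row.get(g)
                        },
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return fixture


def write_edgelist(
    adj: AdjacencyMatrix, path: str | Path, cutoff: float = 0.0
) -> int:
    """Gene-pair edge list TSV (gene_a, gene_b, weight), pairs with a_ij >= cutoff.

    Returns the number of edges written. A cutoff of 0 would include
    every pair, so zero-weight pairs are skipped in that case.
    """
    count = 0
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        n = len(adj.gene_ids)
        for i in range(n):
            for j in range(i + 1, n):
                w = adj.a[i, j]
                if w >= cutoff and w > 0:
                    fh.write(f"{adj.gene_ids[i]}\t{adj.gene_ids[j]}\t{_fmt(w)}\n")
                    count += 1
    return count


def read_edgelist(path: str | Path) -> list[tuple[str, str, float]]:
    path = Path(path)
    edges = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_a"):
            raise ValueError(f"{path}:1: expected edge-list header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields")
            edges.append((parts[0], parts[1], float(parts[2])))
    return edges


def write_graphml(
    adj: AdjacencyMatrix,
    path: str | Path,
    assignment: ModuleAssignment | None = None,
    node_attrs: dict[str, dict[str, float]] | None = None,
    cutoff: float = 0.0,
) -> None:
    """GraphML export with optional module colors and topology attributes."""
    g = nx.Graph()
    for gene in adj.gene_ids:
        attrs: dict[str, object] = {}
        if assignment is not None:
            attrs["module"] = assignment.color[gene]
        if node_attrs:
            for key, table in node_attrs.items():
                if gene in table:
                    attrs[key] = float(table[gene])
        g.add_node(gene, **attrs)
    n = len(adj.gene_ids)
    for i in range(n):
        for j in range(i + 1, n):
            w = adj.a[i, j]
            if w >= cutoff and w > 0:
                g.add_edge(adj.gene_ids[i], adj.gene_ids[j], weight=float(w))
    nx.write_graphml(g, str(path))


def write_module_assignment(assignment: ModuleAssignment, path: str | Path) -> None:
    """TSV of gene_id, module_color."""
    with open(path, "w") as fh:
        fh.write("gene_id\tmodule_color\n")
        for gene in assignment.gene_ids:
            fh.write(f"{gene}\t{assignment.color[gene]}\n")


def read_module_assignment(path: str | Path) -> dict[str, str]:
    path = Path(path)
    colors: dict[str, str] = {}
    with open(path) as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields")
            colors[parts[0]] = parts[1]
    return colors
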