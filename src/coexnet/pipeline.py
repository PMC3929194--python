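"""End-to-end pipeline orchestration.

Runs preprocess -> correlation -> hard/soft adjacency -> TOM -> modules ->
topology -> candidates (plus enrichment and trait validation when inputs
are supplied), writing each stage's output and a JSON manifest into the
run directory. Reruns with identical config and inputs are byte
identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from coexnet import io
from coexnet.config import PipelineConfig
from coexnet.enrichment import GeneSetCollection, fisher_enrichment
from coexnet.modules import cut_modules, hierarchical_cluster, module_summaries
from coexnet.network import (
    correlation_matrix,
    hard_adjacency,
    soft_adjacency,
    topological_overlap,
)
from coexnet.preprocess import collapse_probes, quantile_normalize
from coexnet.topology import select_candidates, topology_profiles
from coexnet.validation import (
    expression_trait_correlation,
    fold_change,
    group_stats,
    trait_regression,
)

logger = logging.getLogger("coexnet")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(data, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest (also written to disk).

    On stage failure, partial outputs are retained and the manifest
    records an error marker before the exception propagates.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {"expression": config.expression}
    for key in ("probe_map", "traits", "gene_sets"):
        if getattr(config, key):
            inputs[key] = getattr(config, key)
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "input_hashes": {k: _sha256(v) for k, v in inputs.items()},
        "stages": [],
        "status": "running",
    }
    stage = "start"
    try:
        stage = "preprocess"
        expr = io.read_expression(config.expression)
        if config.probe_map:
            expr.probe_map = io.read_probe_map(config.probe_map)
        if config.quantile_normalize:
            expr = quantile_normalize(expr)
        if expr.probe_map is not None:
            expr = collapse_probes(expr, min_probes=config.min_probes)
        io.write_expression(expr, out / "expression_normalized.tsv")
        manifest["stages"].append(
            {"stage": stage, "genes": expr.n_genes, "samples": expr.n_samples,
             "output": "expression_normalized.tsv"}
        )
        logger.info("preprocess: %d genes x %d samples", expr.n_genes, expr.n_samples)

        stage = "correlation"
        corr = correlation_matrix(expr)
        io.write_matrix(corr.gene_ids, corr.r, out / "correlation.tsv")
        manifest["stages"].append({"stage": stage, "genes": len(corr.gene_ids),
                                   "output": "correlation.tsv"})

        stage = "hard_adjacency"
        hard = hard_adjacency(corr, tau=config.tau)
        n_edges = io.write_edgelist(hard, out / "edges_hard.tsv", cutoff=config.edge_cutoff)
        manifest["stages"].append({"stage": stage, "edges": n_edges,
                                   "output": "edges_hard.tsv"})
        logger.info("hard adjacency (tau=%.3g): %d edges", config.tau, n_edges)

        stage = "soft_adjacency"
        soft = soft_adjacency(corr, beta=config.beta)
        n_edges = io.write_edgelist(soft, out / "edges_soft.tsv", cutoff=config.edge_cutoff)
        manifest["stages"].append({"stage": stage, "edges": n_edges,
                                   "output": "edges_soft.tsv"})

        stage = "tom"
        tom = topological_overlap(soft)
        io.write_matrix(tom.gene_ids, tom.omega, out / "tom.tsv")
        manifest["stages"].append({"stage": stage, "genes": len(tom.gene_ids),
                                   "output": "tom.tsv"})

        stage = "modules"
        dendrogram = hierarchical_cluster(tom)
        assignment = cut_modules(
            dendrogram,
            tom.gene_ids,
            height_cutoff=config.height_cutoff,
            min_module_size=config.min_module_size,
        )
        io.write_module_assignment(assignment, out / "modules.tsv")
        report = module_summaries(assignment, soft)
        _write_json(
            {
                "sizes": report.sizes,
                "effective_mean_degree": report.effective_mean_degree,
                "modules": [
                    {
                        "color": s.color,
                        "size": s.size,
                        "mean_connectivity": s.mean_connectivity,
                    }
                    for s in report.modules
                ],
            },
            out / "module_summary.json",
        )
        manifest["stages"].append(
            {"stage": stage, "modules": len(report.modules),
             "grey": report.sizes.get("grey", 0),
             "output": "modules.tsv"}
        )
        logger.info("modules: %d (grey=%d)", len(report.modules),
                    report.sizes.get("grey", 0))

        stage = "topology"
        bc_adj = hard if config.bc_network_mode == "binary" else soft
        profiles = topology_profiles(
            bc_adj,
            weighted=config.bc_network_mode == "weighted",
            edge_length=config.edge_length,
        )
        soft_k = soft.connectivity
        with open(out / "topology.tsv", "w") as fh:
            fh.write(
                "gene_id\tdegree\tconnectivity\tbetweenness\tcloseness\t"
                "clustering_coefficient\tmodule_color\n"
            )
            for i, p in enumerate(profiles):
                fh.write(
                    f"{p.gene_id}\t{p.degree:.17g}\t{soft_k[i]:.17g}\t"
                    f"{p.betweenness:.17g}\t{p.closeness:.17g}\t"
                    f"{p.clustering_coefficient:.17g}\t{assignment.color[p.gene_id]}\n"
                )
        manifest["stages"].append({"stage": stage, "genes": len(profiles),
                                   "output": "topology.tsv"})

        stage = "candidates"
        candidates = select_candidates(profiles, config.n_top_degree, config.n_top_bc)
        with open(out / "candidates.tsv", "w") as fh:
            fh.write("gene_id\tselected_by\tdegree\tbetweenness\n")
            for c in candidates:
                fh.write(
                    f"{c.gene_id}\t{','.join(c.selected_by)}\t"
                    f"{c.degree:.17g}\t{c.betweenness:.17g}\n"
                )
        manifest["stages"].append({"stage": stage, "candidates": len(candidates),
                                   "output": "candidates.tsv"})

        if config.gene_sets:
            stage = "enrichment"
            records = io.read_gmt(config.gene_sets)
            collection = GeneSetCollection.from_records(records, universe=expr.gene_ids)
            rows = []
            for color in assignment.module_colors:
                members = assignment.members(color)
                for r in fisher_enrichment(
                    members,
                    collection,
                    ease=config.enrichment_method == "ease",
                    correction=config.multiple_testing,
                ):
                    rows.append((color, r))
            with open(out / "enrichment.tsv", "w") as fh:
                fh.write(
                    "module\tset_id\tname\toverlap\tmodule_size\tset_size\t"
                    "universe_size\tp_value\tadjusted_p\n"
                )
                for color, r in rows:
                    fh.write(
                        f"{color}\t{r.set_id}\t{r.name}\t{r.overlap_count}\t"
                        f"{r.module_size}\t{r.set_size}\t{r.universe_size}\t"
                        f"{r.p_value:.6g}\t{r.adjusted_p:.6g}\n"
                    )
            manifest["stages"].append({"stage": stage, "tests": len(rows),
                                       "output": "enrichment.tsv"})

        if config.traits:
            stage = "validation"
            fixture = io.read_fixture(config.traits)
            stats = group_stats(fixture)
            genes = sorted({g for f in fixture for g in f.expression})
            candidate_ids = [c.gene_id for c in candidates if c.gene_id in set(genes)]
            target_genes = candidate_ids or genes
            validation: dict = {
                "group_stats": {
                    g: dataclasses.asdict(s) for g, s in stats.items()
                },
                "genes": {},
            }
            for gene in target_genes:
                entry: dict = {}
                try:
                    entry["fold_change"] = fold_change(fixture, gene)
                except ValueError as exc:
                    entry["fold_change_error"] = str(exc)
                try:
                    rep = trait_regression(
                        fixture, gene, covariates=config.candidate_covariates
                    )
                    entry["regression"] = {
                        "coefficients": rep.coefficients,
                        "expression_p": rep.expression_p,
                        "residual_df": rep.residual_df,
                    }
                except ValueError as exc:
                    entry["regression_error"] = str(exc)
                try:
                    r, p = expression_trait_correlation(fixture, gene)
                    entry["correlation"] = {"r": r, "p_value": p}
                except ValueError as exc:
                    entry["correlation_error"] = str(exc)
                validation["genes"][gene] = entry
            _write_json(validation, out / "validation.json")
            manifest["stages"].append({"stage": stage, "genes": len(target_genes),
                                       "output": "validation.json"})

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "error"
        manifest["error"] = {"stage": stage, "message": str(exc)}
        _write_json(manifest, out / "manifest.json")
        raise
    _write_json(manifest, out / "manifest.json")
    return manifest
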