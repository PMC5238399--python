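"""End-to-end orchestration: counts -> DEG calls -> categories -> crucial set
-> enrichment -> annotation networks -> summary report."""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from . import classification, deg_stats, enrichment, networks
from .classification import RATIO_LABEL_BY_GROUP, CategoryAssignment
from .core_io import DEFAULT_CONFIG, AnnotationMap, CountTable

__all__ = ["classify_experiment", "run_pipeline", "summary_report"]


def classify_experiment(
    table: CountTable,
    annotations: AnnotationMap,
    config: Mapping | None = None,
) -> tuple[dict[str, pd.DataFrame], list[CategoryAssignment]]:
    """DEG calling in all four groups followed by the two-round classification.

    Returns the per-group DEG call frames and the category assignments with
    crucial flags set.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    calls = deg_stats.call_all_groups(
        table,
        fdr_max=cfg["fdr_deg"],
        min_abs_log2=cfg["min_abs_log2"],
        rpkm_pseudocount=cfg["rpkm_pseudocount"],
    )
    assignments = classify_from_calls(calls, annotations, cfg)
    return calls, assignments


def classify_from_calls(
    calls: dict[str, pd.DataFrame],
    annotations: AnnotationMap,
    config: Mapping | None = None,
) -> list[CategoryAssignment]:
    """Venn classification and crucial filtering from per-group DEG calls."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    deg_sets = {
        group: set(frame.index[frame["is_deg"]]) for group, frame in calls.items()
    }
    deg_sets = classification.filter_pathway_annotated(deg_sets, annotations)
    regions = classification.venn_partition(deg_sets)

    ratios: dict[str, dict[str, float]] = {}
    for group, frame in calls.items():
        label = RATIO_LABEL_BY_GROUP[group]
        for gene in deg_sets.get(group, ()):
            ratios.setdefault(gene, {})[label] = float(frame.at[gene, "log2_ratio"])

    assignments = classification.assign_categories(regions, ratios)
    return classification.filter_crucial(assignments, cfg)


def run_pipeline(
    table: CountTable,
    annotations: AnnotationMap,
    config: Mapping | None = None,
) -> dict:
    """Full analysis on one experiment; returns a structured result bundle.

    Keys: ``calls`` (per-group DEG frames), ``assignments``, ``crucial_genes``,
    ``enrichment`` (per category: KEGG and GO-BP result lists), ``tripartite``
    and ``projections`` (six weighted one-mode networks for the crucial set),
    and ``report`` (JSON-ready summary, see :func:`summary_report`).
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    calls, assignments = classify_experiment(table, annotations, cfg)
    crucial = {a.gene_id for a in assignments if a.crucial}

    enrich_results = {}
    for category in ("RDR", "SDR", "CDR"):
        genes = {a.gene_id for a in assignments if a.crucial and a.category == category}
        enrich_results[category] = {
            kind: enrichment.enrich(genes, annotations, term_kind=kind, alpha=cfg["enrich_alpha"])
            for kind in ("KEGG", "GO-BP")
        }

    graph = networks.build_tripartite(crucial, annotations)
    projections = networks.all_projections(graph)

    result = {
        "calls": calls,
        "assignments": assignments,
        "crucial_genes": crucial,
        "enrichment": enrich_results,
        "tripartite": graph,
        "projections": projections,
    }
    result["report"] = summary_report(result, annotations)
    return result


def summary_report(result: dict, annotations: AnnotationMap) -> dict:
    """JSON-ready summary of a pipeline run (schema version 1)."""
    assignments: list[CategoryAssignment] = result["assignments"]
    totals = classification.category_totals(assignments)
    crucial_by_mask: dict[str, int] = {}
    for a in assignments:
        if a.crucial:
            key = ",".join(sorted(a.region))
            crucial_by_mask[key] = crucial_by_mask.get(key, 0) + 1

    involvement = enrichment.pathway_involvement(result["crucial_genes"], annotations)
    net_stats = {}
    for name, net in result["projections"].items():
        s = networks.network_stats(net)
        net_stats[name] = {
            "nodes": s.node_count,
            "edges": s.edge_count,
            "mean_degree_2E_over_N": round(s.mean_degree, 4),
            "mean_degree_E_over_N": round(s.mean_degree_edges_per_node, 4),
            "isolated_nodes": len(s.isolated_nodes),
            "max_weight_edge": list(s.max_weight_edge) if s.max_weight_edge else None,
            "powerlaw_slope": networks.powerlaw_slope(s.degree_histogram),
        }

    enriched_terms = {
        category: {
            kind: [r.term_id for r in res if r.enriched]
            for kind, res in kinds.items()
        }
        for category, kinds in result["enrichment"].items()
    }
    return {
        "schema_version": 1,
        "n_degs_per_group": {
            g: int(frame["is_deg"].sum()) for g, frame in result["calls"].items()
        },
        "category_totals": {k: totals[k] for k in ("RDR", "SDR", "CDR", "EXCLUDED")},
        "crucial_total": len(result["crucial_genes"]),
        "crucial_per_mask": crucial_by_mask,
        "unique_pathways": int(len(involvement)),
        "enriched_terms": enriched_terms,
        "network_stats": net_stats,
    }
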