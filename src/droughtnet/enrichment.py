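"""Hypergeometric over-representation tests for GO processes and KEGG pathways.

For a query set of n genes drawn from a whole-transcriptome background of
N_bg genes, a term annotating K background genes and k query genes is scored
by the upper hypergeometric tail P(X >= k). Multiplicity is controlled with
the Bonferroni correction over the family of terms that annotate at least
one query gene (the tested nodes), and a term is called enriched when the
corrected p-value is at or below ``alpha`` (default 0.05). Only
over-representation is tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .core_io import AnnotationMap

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper_pvalue",
    "enrich",
    "pathway_involvement",
]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_kind: str  # "KEGG" or "GO-BP"
    k: int  # annotated genes in the query set
    n: int  # query-set size
    K: int  # annotated genes in the background
    N_bg: int  # background size
    p_raw: float
    p_corrected: float
    enriched: bool


def hypergeom_upper_pvalue(k: int, n: int, K: int, N_bg: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N_bg, K, n)."""
    if not (0 <= k <= min(n, K) and k <= n <= N_bg and 0 <= K <= N_bg):
        raise ValueError(
            f"invalid hypergeometric counts k={k}, n={n}, K={K}, N_bg={N_bg}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N_bg, K, n))


def enrich(
    query_genes: set[str],
    annotations: AnnotationMap,
    term_kind: str = "KEGG",
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Bonferroni-corrected over-representation results, sorted by p_corrected.

    One result per term carried by at least one query gene; the correction
    factor m is the number of such tested terms.
    """
    if term_kind == "KEGG":
        gene_to_terms = annotations.gene_to_pathways
    elif term_kind == "GO-BP":
        gene_to_terms = annotations.gene_to_processes
    else:
        raise ValueError(f"term_kind must be 'KEGG' or 'GO-BP', got {term_kind!r}")

    n = len(query_genes)
    N_bg = annotations.background_gene_count
    if n > N_bg:
        raise ValueError(f"query size {n} exceeds background size {N_bg}")
    if n == 0:
        return []

    term_k: dict[str, int] = {}
    for gene in query_genes:
        for term in gene_to_terms.get(gene, ()):
            term_k[term] = term_k.get(term, 0) + 1
    if not term_k:
        return []

    term_K: dict[str, int] = {}
    for terms in gene_to_terms.values():
        for term in terms:
            term_K[term] = term_K.get(term, 0) + 1

    m = len(term_k)
    results = []
    for term, k in term_k.items():
        K = term_K[term]
        p_raw = hypergeom_upper_pvalue(k, n, K, N_bg)
        p_corr = min(1.0, m * p_raw)
        results.append(
            EnrichmentResult(
                term_id=term,
                term_kind=term_kind,
                k=k,
                n=n,
                K=K,
                N_bg=N_bg,
                p_raw=p_raw,
                p_corrected=p_corr,
                enriched=p_corr <= alpha,
            )
        )
    results.sort(key=lambda r: (r.p_corrected, r.p_raw, r.term_id))
    return results


def pathway_involvement(gene_set: set[str], annotations: AnnotationMap) -> pd.DataFrame:
    """Exact pathway membership tallies (no test) for a gene set.

    Returns a frame with one row per pathway carried by at least one gene of
    the set: columns ``pathway``, ``genes`` (sorted tuple) and ``count``,
    sorted by descending count then pathway id.
    """
    members: dict[str, set[str]] = {}
    for gene in gene_set:
        for pw in annotations.gene_to_pathways.get(gene, ()):
            members.setdefault(pw, set()).add(gene)
    rows = [
        {"pathway": pw, "genes": tuple(sorted(genes)), "count": len(genes)}
        for pw, genes in members.items()
    ]
    rows.sort(key=lambda r: (-r["count"], r["pathway"]))
    return pd.DataFrame(rows, columns=["pathway", "genes", "count"])


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Flatten enrichment results into a DataFrame."""
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_kind": r.term_kind,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N_bg": r.N_bg,
                "p_raw": r.p_raw,
                "p_corrected": r.p_corrected,
                "enriched": r.enriched,
            }
            for r in results
        ],
        columns=["term_id", "term_kind", "k", "n", "K", "N_bg", "p_raw", "p_corrected", "enriched"],
    )
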