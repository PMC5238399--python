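"""Venn partition of DEG sets, category assignment and crucial-gene filtering.

Genes are first filtered to those carrying at least one pathway annotation,
then partitioned by the subset of comparison groups in which they were
called differentially expressed (their *Venn mask*, 15 non-empty masks over
the four groups). Any mask containing ST-RT — the control-versus-control
comparison, which does not probe the drought response — is excluded. The
seven analysed masks map onto three categories:

    RDR (resistant-cultivar drought-responsive): {RT-R}, {RT-R, S-R}
    SDR (sensitive-cultivar drought-responsive): {ST-S}, {S-R, ST-S}
    CDR (cultivar-non-specific):                 {S-R}, {RT-R, ST-S},
                                                 {RT-R, S-R, ST-S}

A second selection round flags *crucial* genes whose fold changes pass
subgroup-specific cutoffs (all inclusive ``>=``):

    {RT-R}:            |log2(R/RT)| >= 5
    {RT-R, S-R}:       |log2(R/RT) - log2(R/S)| >= 2  or either |.| >= 5
    {ST-S}:            |log2(S/ST)| >= 5
    {S-R, ST-S}:       |log2(R/S) - log2(S/ST)| >= 5  or either |.| >= 5
    {S-R}:             |log2(R/S)| >= 5
    {RT-R, ST-S}:      |log2(R/RT) - log2(S/ST)| >= 1 or either |.| >= 3
    {RT-R, S-R, ST-S}: any of |log2(R/RT)|, |log2(R/S)|, |log2(S/ST)| >= 2
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core_io import DEFAULT_CONFIG, AnnotationMap

__all__ = [
    "GROUPS",
    "VennRegion",
    "CategoryAssignment",
    "filter_pathway_annotated",
    "venn_partition",
    "assign_categories",
    "filter_crucial",
    "regulation_summary",
    "CATEGORY_BY_MASK",
    "RATIOS_BY_MASK",
]

GROUPS = ("RT-R", "S-R", "ST-RT", "ST-S")

Mask = frozenset


@dataclass(frozen=True)
class VennRegion:
    """One of the 15 disjoint regions of the four-set Venn diagram."""

    membership_mask: frozenset[str]
    genes: frozenset[str]


@dataclass
class CategoryAssignment:
    """Category label and crucial flag for a single gene."""

    gene_id: str
    region: frozenset[str]
    category: str  # "RDR", "SDR", "CDR" or "EXCLUDED"
    crucial: bool = False
    log2_ratios: dict[str, float] = field(default_factory=dict)


#: Category by analysed Venn mask; every mask containing ST-RT is EXCLUDED.
CATEGORY_BY_MASK: dict[frozenset[str], str] = {
    frozenset({"RT-R"}): "RDR",
    frozenset({"RT-R", "S-R"}): "RDR",
    frozenset({"ST-S"}): "SDR",
    frozenset({"S-R", "ST-S"}): "SDR",
    frozenset({"S-R"}): "CDR",
    frozenset({"RT-R", "ST-S"}): "CDR",
    frozenset({"RT-R", "S-R", "ST-S"}): "CDR",
}

#: Fold-change labels each subgroup rule needs (group -> ratio orientation).
RATIO_LABEL_BY_GROUP = {"RT-R": "R/RT", "S-R": "R/S", "ST-S": "S/ST", "ST-RT": "RT/ST"}

RATIOS_BY_MASK: dict[frozenset[str], tuple[str, ...]] = {
    mask: tuple(RATIO_LABEL_BY_GROUP[g] for g in ("RT-R", "S-R", "ST-S") if g in mask)
    for mask in CATEGORY_BY_MASK
}


def filter_pathway_annotated(
    deg_sets: dict[str, set[str]], annotations: AnnotationMap
) -> dict[str, set[str]]:
    """Drop genes without any pathway annotation from each group's DEG set."""
    return {
        group: {g for g in genes if annotations.pathway_annotated(g)}
        for group, genes in deg_sets.items()
    }


def venn_partition(deg_sets: dict[str, set[str]]) -> list[VennRegion]:
    """Partition the union of the four DEG sets into its 15 Venn regions.

    Regions are returned for every non-empty mask (some possibly with zero
    genes); they are pairwise disjoint and their union is the full DEG union.
    """
    unknown = set(deg_sets) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown comparison groups {sorted(unknown)}")
    by_mask: dict[frozenset[str], set[str]] = {}
    universe = set().union(*deg_sets.values()) if deg_sets else set()
    for gene in universe:
        mask = frozenset(g for g in GROUPS if gene in deg_sets.get(g, ()))
        by_mask.setdefault(mask, set()).add(gene)
    regions = []
    # enumerate all 15 non-empty masks deterministically
    for i in range(1, 16):
        mask = frozenset(g for bit, g in enumerate(GROUPS) if i >> bit & 1)
        regions.append(VennRegion(mask, frozenset(by_mask.get(mask, set()))))
    return regions


def assign_categories(
    regions: list[VennRegion],
    log2_ratios: dict[str, dict[str, float]] | None = None,
) -> list[CategoryAssignment]:
    """Label every gene of every region RDR / SDR / CDR / EXCLUDED.

    ``log2_ratios`` optionally supplies per-gene fold changes keyed by gene
    then by ratio label (``"R/RT"``, ``"R/S"``, ``"S/ST"``, ``"RT/ST"``); they
    are carried on the assignments for the second-round crucial filter.
    """
    assignments: list[CategoryAssignment] = []
    for region in regions:
        mask = region.membership_mask
        if "ST-RT" in mask:
            category = "EXCLUDED"
        else:
            category = CATEGORY_BY_MASK.get(mask)
            if category is None:
                raise ValueError(f"unexpected Venn mask {sorted(mask)}")
        for gene in sorted(region.genes):
            ratios = dict(log2_ratios.get(gene, {})) if log2_ratios else {}
            assignments.append(
                CategoryAssignment(gene_id=gene, region=mask, category=category, log2_ratios=ratios)
            )
    return assignments


def category_totals(assignments: list[CategoryAssignment]) -> dict[str, int]:
    totals: dict[str, int] = {"RDR": 0, "SDR": 0, "CDR": 0, "EXCLUDED": 0}
    for a in assignments:
        totals[a.category] += 1
    return totals


def _rule_passes(mask: frozenset[str], ratios: dict[str, float], cfg: dict) -> bool:
    def r(label: str) -> float:
        if label not in ratios:
            raise ValueError(f"missing log2({label}) for mask {sorted(mask)}")
        return ratios[label]

    single = cfg["crucial_single_cutoff"]
    if mask == frozenset({"RT-R"}):
        return abs(r("R/RT")) >= single
    if mask == frozenset({"RT-R", "S-R"}):
        return (
            abs(r("R/RT") - r("R/S")) >= cfg["crucial_rdr_pair_diff"]
            or abs(r("R/RT")) >= single
            or abs(r("R/S")) >= single
        )
    if mask == frozenset({"ST-S"}):
        return abs(r("S/ST")) >= single
    if mask == frozenset({"S-R", "ST-S"}):
        return (
            abs(r("R/S") - r("S/ST")) >= cfg["crucial_sdr_pair_diff"]
            or abs(r("R/S")) >= single
            or abs(r("S/ST")) >= single
        )
    if mask == frozenset({"S-R"}):
        return abs(r("R/S")) >= single
    if mask == frozenset({"RT-R", "ST-S"}):
        return (
            abs(r("R/RT") - r("S/ST")) >= cfg["crucial_cdr_pair_diff"]
            or abs(r("R/RT")) >= cfg["crucial_cdr_pair_single"]
            or abs(r("S/ST")) >= cfg["crucial_cdr_pair_single"]
        )
    if mask == frozenset({"RT-R", "S-R", "ST-S"}):
        t = cfg["crucial_triple_single"]
        return abs(r("R/RT")) >= t or abs(r("R/S")) >= t or abs(r("S/ST")) >= t
    raise ValueError(f"no crucial rule for mask {sorted(mask)}")


def filter_crucial(
    assignments: list[CategoryAssignment], config: dict | None = None
) -> list[CategoryAssignment]:
    """Apply the second-round subgroup-specific fold-change rules in place.

    Excluded genes are never crucial. A gene whose mask's rule references a
    fold change it does not carry raises an error naming gene and mask.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    for a in assignments:
        if a.category == "EXCLUDED":
            a.crucial = False
            continue
        try:
            a.crucial = _rule_passes(a.region, a.log2_ratios, cfg)
        except ValueError as exc:
            raise ValueError(f"gene {a.gene_id}: {exc}") from None
    return assignments


def regulation_summary(
    assignments: list[CategoryAssignment],
    category: str,
    crucial_only: bool = True,
) -> pd.DataFrame:
    """Up/down tallies (and percentages) per fold-change label for a category.

    Direction is read off the sign of each carried log2 ratio: positive means
    up-regulated in the ratio's numerator sample. Rows index the ratio
    labels; columns are ``up``, ``down``, ``n``, ``pct_up``, ``pct_down``.
    """
    rows: dict[str, dict[str, int]] = {}
    for a in assignments:
        if a.category != category or (crucial_only and not a.crucial):
            continue
        for label in RATIOS_BY_MASK.get(a.region, ()):
            value = a.log2_ratios.get(label)
            if value is None or value == 0:
                continue
            tally = rows.setdefault(label, {"up": 0, "down": 0})
            tally["up" if value > 0 else "down"] += 1
    out = []
    for label, tally in sorted(rows.items()):
        n = tally["up"] + tally["down"]
        out.append(
            {
                "ratio": label,
                "up": tally["up"],
                "down": tally["down"],
                "n": n,
                "pct_up": round(100.0 * tally["up"] / n, 2),
                "pct_down": round(100.0 * tally["down"] / n, 2),
            }
        )
    return pd.DataFrame(out).set_index("ratio") if out else pd.DataFrame(
        columns=["up", "down", "n", "pct_up", "pct_down"]
    )
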