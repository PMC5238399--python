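"""Synthetic four-library tag-count experiments with planted structure.

The generator emulates the study design the pipeline targets: four
*B. napus* libraries — a drought-resistant cultivar under osmotic stress (R)
and well-watered (RT), and a drought-sensitive cultivar stressed (S) and
well-watered (ST) — with Poisson-distributed unique tag counts per gene,
gene identifiers in the ``BnaXXXgYYYYYD`` convention over the 19 chromosomes
plus unknown-position labels, and pathway/process annotation maps with
planted term enrichment. Library totals default to 1e6 reads per library, a
down-scaled stand-in for deep sequencing runs; they are configurable.

Planted differential expression is parameterised by per-comparison log2
effects (e1, e2, e3) for log2(R/RT), log2(R/S) and log2(S/ST). Because each
sample has a single expression level, the fourth comparison is determined:
log2(RT/ST) = -e1 + e2 + e3. This identity makes some Venn masks
unreachable at large effect sizes — a gene responding strongly only in one
comparison necessarily drags a second comparison past the threshold — so
each target mask has a planting recipe that respects the identity, and
ground-truth labels (mask, category, crucial flag) are derived from the
*realised* effects, never from the requested target, keeping truth
consistent with the generated counts by construction. Strong, crucial-level
effects are therefore planted on the multi-group masks; single-group masks
only support moderate effects (|log2| < 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classification import (
    CATEGORY_BY_MASK,
    CategoryAssignment,
    _rule_passes,
)
from .core_io import DEFAULT_CONFIG, SAMPLES, AnnotationMap, CountTable

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_experiment",
    "table3_fixture",
    "TABLE3_SUBGROUPS",
]

#: Analysed Venn masks in a fixed order (mask key -> frozenset of groups).
MASK_KEYS: dict[str, frozenset[str]] = {
    "RT-R": frozenset({"RT-R"}),
    "RT-R,S-R": frozenset({"RT-R", "S-R"}),
    "ST-S": frozenset({"ST-S"}),
    "S-R,ST-S": frozenset({"S-R", "ST-S"}),
    "S-R": frozenset({"S-R"}),
    "RT-R,ST-S": frozenset({"RT-R", "ST-S"}),
    "RT-R,S-R,ST-S": frozenset({"RT-R", "S-R", "ST-S"}),
}

_CHROMS = (
    [f"A{i:02d}" for i in range(1, 11)]
    + [f"C{i:02d}" for i in range(1, 10)]
    + ["Ann", "Cnn", "Unn"]
)


@dataclass
class SimulationConfig:
    """Parameters of a synthetic four-library experiment.

    ``planted_fractions`` gives the fraction of genes planted per target
    mask; the remainder are null genes. ``planted_log2_effects`` gives the
    per-mask magnitude range of the primary effect (single-group masks are
    capped below 2 by the log-ratio identity discussed in the module
    docstring; their defaults stay within that cap).
    """

    n_genes: int = 2000
    library_totals: dict[str, int] = field(
        default_factory=lambda: {s: 1_000_000 for s in SAMPLES}
    )
    baseline_log_mean: float = 3.0  # natural-log scale of expected anchor counts
    baseline_log_sigma: float = 1.0
    planted_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "RT-R": 0.020,
            "RT-R,S-R": 0.020,
            "ST-S": 0.010,
            "S-R,ST-S": 0.020,
            "S-R": 0.040,
            "RT-R,ST-S": 0.010,
            "RT-R,S-R,ST-S": 0.010,
        }
    )
    planted_log2_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "RT-R": (1.2, 1.9),
            "RT-R,S-R": (2.0, 7.0),
            "ST-S": (1.2, 1.9),
            "S-R,ST-S": (1.5, 7.0),
            "S-R": (1.2, 1.9),
            "RT-R,ST-S": (1.5, 6.0),
            "RT-R,S-R,ST-S": (1.2, 5.0),
        }
    )
    planted_min_baseline: float = 50.0  # expected anchor count floor for planted genes
    pathway_count: int = 128
    process_count: int = 1200
    pathways_per_gene: float = 2.0
    processes_per_gene: float = 6.0
    unannotated_fraction: float = 0.4  # null genes lacking pathway annotation
    n_enriched_pathways: int = 3
    n_enriched_processes: int = 3
    enrichment_concentration: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        unknown = set(self.planted_fractions) - set(MASK_KEYS)
        if unknown:
            raise ValueError(f"unknown planted masks {sorted(unknown)}")
        total = sum(self.planted_fractions.values())
        if total > 1.0:
            raise ValueError(f"planted fractions sum to {total} > 1")
        if any(f < 0 for f in self.planted_fractions.values()):
            raise ValueError("planted fractions must be non-negative")
        for key, (lo, hi) in self.planted_log2_effects.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo <= hi):
                raise ValueError(f"bad effect range for {key}: ({lo}, {hi})")
        if not 0 <= self.unannotated_fraction <= 1:
            raise ValueError("unannotated_fraction must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground-truth labels of a simulated experiment.

    ``effects`` maps gene -> realised log2 ratios keyed "R/RT", "R/S",
    "S/ST", "RT/ST"; ``mask`` / ``category`` / ``crucial`` are derived from
    those effects with the default thresholds, so an effect pattern that
    spills into the control-versus-control comparison is truthfully labelled
    EXCLUDED. Null genes carry an empty mask and category ``None``.
    """

    effects: dict[str, dict[str, float]]
    mask: dict[str, frozenset[str]]
    category: dict[str, str | None]
    crucial: dict[str, bool]
    target_mask: dict[str, str | None]  # requested planting recipe, for reference
    enriched_pathways: set[str]
    enriched_processes: set[str]

    @property
    def crucial_genes(self) -> set[str]:
        return {g for g, c in self.crucial.items() if c}


def _draw_effects(mask_key: str, m: float, rng: np.random.Generator) -> tuple[float, float, float]:
    """Planting recipe: realise (e1, e2, e3) for a target mask.

    Recipes keep the implied log2(RT/ST) = -e1+e2+e3 below 1 in magnitude
    whenever the target mask permits it.
    """
    s = rng.choice((-1.0, 1.0))
    if mask_key == "RT-R":
        e1 = s * m
        return e1, e1 / 2.0, e1 / 2.0
    if mask_key == "ST-S":
        e3 = s * m
        return 0.0, -e3 / 2.0, e3
    if mask_key == "S-R":
        e2 = s * m
        return 0.0, e2, -e2 / 2.0
    if mask_key == "RT-R,S-R":
        # resistant-cultivar drought response: both drought comparisons move
        e1 = s * m
        delta = rng.uniform(-0.8, 0.8)
        return e1, e1 + delta, -delta
    if mask_key == "S-R,ST-S":
        # sensitive-cultivar drought response: S moves against both R and ST
        e2 = s * m
        delta, delta2 = rng.uniform(-0.4, 0.4, size=2)
        return delta2, e2, -e2 + delta
    if mask_key == "RT-R,ST-S":
        # both cultivars respond; difference |e1-e3| may span the diff rule
        e1 = s * m
        delta = rng.uniform(-1.8, 1.8)
        return e1, -delta / 2.0, e1 + delta
    if mask_key == "RT-R,S-R,ST-S":
        m3 = rng.uniform(1.2, max(1.2, min(2.0, m)))
        s3 = rng.choice((-1.0, 1.0))
        e1, e3 = s * m, s3 * m3
        e4 = rng.uniform(-0.9, 0.9)
        e2 = e1 - e3 + e4
        if abs(e2) < 1.0:  # keep S-R in the mask
            e2 = 1.0 if e2 >= 0 else -1.0
        return e1, e2, e3
    raise ValueError(f"unknown mask key {mask_key!r}")


def _truth_from_effects(
    e1: float, e2: float, e3: float, threshold: float = 1.0
) -> tuple[frozenset[str], str | None, bool]:
    e4 = -e1 + e2 + e3
    mask = frozenset(
        g
        for g, e in (("RT-R", e1), ("S-R", e2), ("ST-S", e3), ("ST-RT", e4))
        if abs(e) >= threshold
    )
    if not mask:
        return mask, None, False
    if "ST-RT" in mask:
        return mask, "EXCLUDED", False
    category = CATEGORY_BY_MASK[mask]
    ratios = {"R/RT": e1, "R/S": e2, "S/ST": e3}
    crucial = _rule_passes(mask, ratios, DEFAULT_CONFIG)
    return mask, category, crucial


def _generate_gene_ids(n: int, rng: np.random.Generator) -> list[str]:
    """Unique identifiers in the BnaXXXgYYYYYD convention."""
    weights = np.array([1.0] * 19 + [0.25, 0.25, 0.1])
    weights /= weights.sum()
    chrom_idx = rng.choice(len(_CHROMS), size=n, p=weights)
    counters = {c: 0 for c in _CHROMS}
    ids = []
    for idx in chrom_idx:
        chrom = _CHROMS[idx]
        counters[chrom] += int(rng.integers(10, 200))
        code = counters[chrom] % 100000
        ids.append(f"Bna{chrom}g{code:05d}D")
    if len(set(ids)) != n:  # astronomically unlikely at supported sizes
        raise RuntimeError("gene identifier collision; reduce n_genes")
    return ids


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[CountTable, AnnotationMap, SyntheticTruth]:
    """Draw a synthetic experiment: counts, annotations and ground truth.

    Identical configs (including seed) produce byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = _generate_gene_ids(n, rng)

    # assign planting targets
    targets: list[str | None] = [None] * n
    pos = 0
    for key in MASK_KEYS:
        frac = config.planted_fractions.get(key, 0.0)
        count = int(round(frac * n))
        for _ in range(count):
            if pos < n:
                targets[pos] = key
                pos += 1
    perm = rng.permutation(n)
    targets = [targets[i] for i in perm]

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sigma, size=n)
    lengths = rng.integers(500, 3001, size=n)

    effects: dict[str, dict[str, float]] = {}
    truth_mask: dict[str, frozenset[str]] = {}
    truth_cat: dict[str, str | None] = {}
    truth_crucial: dict[str, bool] = {}
    target_by_gene: dict[str, str | None] = {}
    e_arr = np.zeros((n, 3))
    for i, (gene, target) in enumerate(zip(gene_ids, targets)):
        if target is None:
            e1 = e2 = e3 = 0.0
        else:
            lo, hi = config.planted_log2_effects[target]
            m = rng.uniform(lo, hi)
            e1, e2, e3 = _draw_effects(target, m, rng)
            baseline[i] = max(baseline[i], config.planted_min_baseline)
        e_arr[i] = (e1, e2, e3)
        mask, cat, crucial = _truth_from_effects(e1, e2, e3)
        effects[gene] = {"R/RT": e1, "R/S": e2, "S/ST": e3, "RT/ST": -e1 + e2 + e3}
        truth_mask[gene] = mask
        truth_cat[gene] = cat
        truth_crucial[gene] = crucial
        target_by_gene[gene] = target

    # per-sample log2 offsets anchored at RT
    e1v, e2v, e3v = e_arr[:, 0], e_arr[:, 1], e_arr[:, 2]
    offsets = {
        "R": e1v,
        "RT": np.zeros(n),
        "S": e1v - e2v,
        "ST": e1v - e2v - e3v,
    }
    counts = {}
    for s in SAMPLES:
        rate = baseline * np.exp2(offsets[s]) * (config.library_totals[s] / 1e6)
        counts[s] = rng.poisson(rate)
    count_frame = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"))
    totals = {
        s: max(int(config.library_totals[s]), int(count_frame[s].sum())) for s in SAMPLES
    }
    table = CountTable(
        counts=count_frame,
        gene_length_bases=pd.Series(lengths, index=count_frame.index, name="length"),
        library_total=totals,
    )

    # annotation maps with planted term concentration in planted genes
    pathway_universe = [f"ko{i + 1:05d}" for i in range(config.pathway_count)]
    process_universe = [f"GO:{i + 1:07d}" for i in range(config.process_count)]
    enriched_pw = set(pathway_universe[: config.n_enriched_pathways])
    enriched_proc = set(process_universe[: config.n_enriched_processes])

    gene_to_pathways: dict[str, set[str]] = {}
    gene_to_processes: dict[str, set[str]] = {}
    for gene, target in zip(gene_ids, targets):
        planted = target is not None
        if not planted and rng.random() < config.unannotated_fraction:
            pws: set[str] = set()
        else:
            k = 1 + rng.poisson(max(config.pathways_per_gene - 1.0, 0.0))
            pws = set(
                map(str, rng.choice(pathway_universe, size=min(k, len(pathway_universe)), replace=False))
            )
        procs: set[str] = set()
        kp = rng.poisson(config.processes_per_gene)
        if kp:
            procs = set(
                map(str, rng.choice(process_universe, size=min(kp, len(process_universe)), replace=False))
            )
        if planted and truth_crucial[gene]:
            for term in sorted(enriched_pw):
                if rng.random() < config.enrichment_concentration:
                    pws.add(term)
            for term in sorted(enriched_proc):
                if rng.random() < config.enrichment_concentration:
                    procs.add(term)
        if pws:
            gene_to_pathways[gene] = pws
        if procs:
            gene_to_processes[gene] = procs

    annotations = AnnotationMap(
        gene_to_pathways=gene_to_pathways,
        gene_to_processes=gene_to_processes,
        background_gene_count=n,
    )
    truth = SyntheticTruth(
        effects=effects,
        mask=truth_mask,
        category=truth_cat,
        crucial=truth_crucial,
        target_mask=target_by_gene,
        enriched_pathways=enriched_pw,
        enriched_processes=enriched_proc,
    )
    return table, annotations, truth


# ---------------------------------------------------------------------------
# Reference fixture: the 169 crucial drought-responsive genes by subgroup.
# ---------------------------------------------------------------------------

TABLE3_SUBGROUPS: dict[str, tuple[str, str, tuple[str, ...]]] = {
    # mask key -> (category, condition gloss, gene labels)
    "RT-R": (
        "RDR",
        "|log2(R/RT)| >= 5",
        (
            "BnaC03g56210D", "BnaCnng59500D", "BnaA05g01040D", "BnaCnng20790D",
            "BnaC09g44020D", "BnaC03g12620D", "BnaC01g37110D", "BnaA02g18900D",
            "BnaC07g19090D", "BnaA05g28740D", "BnaC05g09790D", "BnaA10g07930D",
            "BnaC01g34960D", "BnaA06g03410D", "BnaA03g24880D", "BnaA03g03260D",
            "BnaA02g11330D", "BnaA03g34560D", "BnaC03g58100D", "BnaC09g15390D",
            "BnaC04g18800D",
        ),
    ),
    "RT-R,S-R": (
        "RDR",
        "|log2(R/RT)-log2(R/S)| >= 2 or |log2(R/RT)| >= 5 or |log2(R/S)| >= 5",
        (
            "BnaA03g58830D", "BnaC04g08480D", "BnaAnng21300D", "BnaA08g28220D",
            "BnaC01g17200D", "BnaA03g06740D", "BnaA08g14940D", "BnaC01g15100D",
            "BnaA07g06750D", "BnaA10g13870D", "BnaC04g25850D", "BnaAnng32880D",
            "BnaA06g30800D", "BnaC02g09490D", "BnaC04g24050D", "BnaA03g51150D",
        ),
    ),
    "ST-S": (
        "SDR",
        "|log2(S/ST)| >= 5",
        ("BnaA09g29930D", "BnaA01g15420D", "BnaA10g19500D"),
    ),
    "S-R,ST-S": (
        "SDR",
        "|log2(R/S)-log2(S/ST)| >= 5 or |log2(R/S)| >= 5 or |log2(S/ST)| >= 5",
        (
            "BnaC04g53040D", "BnaA07g25920D", "BnaC03g21190D", "BnaA06g16790D",
            "BnaAnng38110D", "BnaC07g23420D", "BnaA05g07610D", "BnaC09g30400D",
            "BnaA05g04050D", "BnaC01g15930D", "BnaA10g25810D", "BnaA08g10720D",
            "BnaC08g34950D", "BnaAnng13920D", "BnaA05g01210D", "BnaC06g27540D",
            "BnaA09g45070D", "BnaA02g35770D", "BnaCnng49200D", "BnaAnng16550D",
            "BnaC01g01680D", "BnaC01g00790D", "BnaC04g12030D", "BnaC07g22910D",
            "BnaC09g13640D", "BnaC04g40560D", "BnaAnng35070D", "BnaC06g40190D",
            "BnaA06g03560D", "BnaA08g15660D", "BnaCnng58050D", "BnaA08g15380D",
        ),
    ),
    "S-R": (
        "CDR",
        "|log2(R/S)| >= 5",
        (
            "BnaC04g08380D", "BnaC08g34220D", "BnaC09g25150D", "BnaC04g06610D",
            "BnaA05g36130D", "BnaA07g09990D", "BnaC06g40170D", "BnaC03g54190D",
            "BnaA04g19170D", "BnaC06g42330D", "BnaC01g32000D", "BnaA03g18320D",
            "BnaA03g17650D", "BnaA06g25710D", "BnaCnng24430D", "BnaC03g65980D",
            "BnaA10g01810D", "BnaA10g23290D", "BnaC02g29620D", "BnaC04g04810D",
            "BnaA05g25890D", "BnaA02g15580D", "BnaC06g19400D", "BnaA09g13870D",
            "BnaA09g13340D", "BnaA01g27050D", "BnaC03g71340D", "BnaA06g20540D",
            "BnaC04g47740D", "BnaA09g00640D", "BnaA07g30770D", "BnaC02g05370D",
            "BnaC07g47180D", "BnaC06g27550D", "BnaAnng19400D", "BnaA03g23600D",
            "BnaA02g05950D", "BnaC08g38290D", "BnaCnng16640D", "BnaC01g41100D",
            "BnaC02g43320D", "BnaA01g11120D", "BnaC09g40740D", "BnaC04g07040D",
            "BnaC04g47180D", "BnaC05g39240D", "BnaC08g07260D", "BnaC04g51180D",
            "BnaC03g10010D", "BnaA06g17920D", "BnaC03g43240D", "BnaC03g28890D",
            "BnaCnng65600D", "BnaC09g42520D", "BnaC04g19980D", "BnaAnng28200D",
            "BnaC01g25210D", "BnaC09g54060D", "BnaA02g30890D", "BnaC04g30340D",
            "BnaA04g09660D", "BnaC06g20800D", "BnaC03g15560D", "BnaA05g04030D",
            "BnaA07g09660D", "BnaA04g11170D", "BnaA02g32580D", "BnaC04g48100D",
            "BnaC03g30200D", "BnaAnng33710D", "BnaC05g20880D", "BnaC09g30440D",
        ),
    ),
    "RT-R,ST-S": (
        "CDR",
        "|log2(R/RT)-log2(S/ST)| >= 1 or |log2(R/RT)| >= 3 or |log2(S/ST)| >= 3",
        (
            "BnaA05g24610D", "BnaA03g36420D", "BnaA04g15830D", "BnaAnng27690D",
            "BnaA05g09600D", "BnaA03g55400D", "BnaC05g04100D", "BnaA02g16190D",
            "BnaA08g31100D", "BnaC09g21910D", "BnaA03g46430D", "BnaC09g28340D",
            "BnaC03g42310D", "BnaA09g55800D",
        ),
    ),
    "RT-R,S-R,ST-S": (
        "CDR",
        "|log2(R/RT)| >= 2 or |log2(R/S)| >= 2 or |log2(S/ST)| >= 2",
        (
            "BnaA04g17930D", "BnaA04g27940D", "BnaA05g27700D", "BnaA08g04230D",
            "BnaA09g41620D", "BnaA10g11530D", "BnaC01g39170D", "BnaC02g00830D",
            "BnaC03g02620D", "BnaC04g22390D", "BnaC09g48690D",
        ),
    ),
}


def table3_fixture() -> list[CategoryAssignment]:
    """The 169 crucial drought-responsive genes with their subgroup masks.

    Packaged as category assignments (crucial flag already set) for use as a
    reference fixture; fold-change values are not part of the published
    per-subgroup lists and are left empty.
    """
    out: list[CategoryAssignment] = []
    for mask_key, (category, _, labels) in TABLE3_SUBGROUPS.items():
        mask = MASK_KEYS[mask_key]
        for gene in labels:
            out.append(
                CategoryAssignment(
                    gene_id=gene, region=mask, category=category, crucial=True
                )
            )
    return out
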