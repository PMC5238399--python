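import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from droughtnet.classification import (
    CATEGORY_BY_MASK,
    GROUPS,
    CategoryAssignment,
    VennRegion,
    assign_categories,
    category_totals,
    filter_crucial,
    filter_pathway_annotated,
    regulation_summary,
    venn_partition,
)
from droughtnet.core_io import AnnotationMap


def region(mask, genes):
    return VennRegion(frozenset(mask), frozenset(genes))


class TestAnnotationFilter:
    def test_keeps_only_annotated(self, toy_annotations):
        out = filter_pathway_annotated({"RT-R": {"g1", "gX"}}, toy_annotations)
        assert out == {"RT-R": {"g1"}}

    def test_identity_when_all_annotated(self, toy_annotations):
        sets = {"RT-R": {"g1", "g2"}, "ST-S": {"g3"}}
        assert filter_pathway_annotated(sets, toy_annotations) == sets

    def test_all_unannotated_yields_empty_sets(self):
        ann = AnnotationMap(gene_to_pathways={}, background_gene_count=10)
        out = filter_pathway_annotated({g: {"a", "b"} for g in GROUPS}, ann)
        assert all(v == set() for v in out.values())
        # downstream stages accept the degenerate input
        assignments = assign_categories(venn_partition(out))
        assert assignments == []


class TestVennPartition:
    def test_disjoint_sets_fill_singleton_masks(self):
        sets = {g: {f"{g}:{i}" for i in range(3)} for g in GROUPS}
        regions = venn_partition(sets)
        nonempty = {r.membership_mask: r.genes for r in regions if r.genes}
        assert set(nonempty) == {frozenset({g}) for g in GROUPS}

    def test_identical_sets_fill_full_mask(self):
        sets = {g: {"a", "b"} for g in GROUPS}
        regions = venn_partition(sets)
        nonempty = [r for r in regions if r.genes]
        assert len(nonempty) == 1
        assert nonempty[0].membership_mask == frozenset(GROUPS)

    def test_returns_all_fifteen_masks_disjoint(self):
        sets = {"RT-R": {"a", "b"}, "S-R": {"b", "c"}, "ST-RT": set(), "ST-S": {"c"}}
        regions = venn_partition(sets)
        assert len(regions) == 15
        union = set()
        for r in regions:
            assert not (union & r.genes)
            union |= r.genes
        assert union == {"a", "b", "c"}

    @given(st.data())
    def test_matches_bitmask_oracle(self, data):
        universe = [f"g{i}" for i in range(50)]
        sets = {
            g: set(data.draw(st.lists(st.sampled_from(universe), max_size=50)))
            for g in GROUPS
        }
        regions = {r.membership_mask: r.genes for r in venn_partition(sets)}
        # oracle: per-gene membership bitmask accumulation
        oracle: dict[frozenset, set] = {}
        for gene in {x for s in sets.values() for x in s}:
            mask = frozenset(g for g in GROUPS if gene in sets[g])
            oracle.setdefault(mask, set()).add(gene)
        for mask, genes in oracle.items():
            assert regions[mask] == genes


class TestAssignCategories:
    def test_published_subgroup_sizes_reproduce_category_totals(self):
        sizes = {
            ("RT-R",): 487,
            ("RT-R", "S-R"): 282,
            ("ST-S",): 111,
            ("S-R", "ST-S"): 114,
            ("S-R",): 1086,
            ("RT-R", "ST-S"): 85,
            ("RT-R", "S-R", "ST-S"): 20,
        }
        regions, n = [], 0
        for mask, size in sizes.items():
            regions.append(region(mask, {f"{'_'.join(mask)}:{i}" for i in range(size)}))
            n += size
        totals = category_totals(assign_categories(regions))
        assert totals["RDR"] == 769
        assert totals["SDR"] == 225
        assert totals["CDR"] == 1191
        assert totals["EXCLUDED"] == 0
        assert n == 2185

    @pytest.mark.parametrize(
        "mask", [("ST-RT",), ("RT-R", "ST-RT"), ("RT-R", "S-R", "ST-RT", "ST-S")]
    )
    def test_control_comparison_masks_excluded(self, mask):
        out = assign_categories([region(mask, {"g"})])
        assert out[0].category == "EXCLUDED"

    def test_each_analysed_mask_maps_to_its_category(self):
        for mask, category in CATEGORY_BY_MASK.items():
            out = assign_categories([region(mask, {"g"})])
            assert out[0].category == category


def brute_force_crucial(mask, r):
    """Independent re-statement of the second-round rules."""
    a = {k: abs(v) for k, v in r.items()}
    if mask == {"RT-R"}:
        return a["R/RT"] >= 5
    if mask == {"RT-R", "S-R"}:
        return abs(r["R/RT"] - r["R/S"]) >= 2 or a["R/RT"] >= 5 or a["R/S"] >= 5
    if mask == {"ST-S"}:
        return a["S/ST"] >= 5
    if mask == {"S-R", "ST-S"}:
        return abs(r["R/S"] - r["S/ST"]) >= 5 or a["R/S"] >= 5 or a["S/ST"] >= 5
    if mask == {"S-R"}:
        return a["R/S"] >= 5
    if mask == {"RT-R", "ST-S"}:
        return abs(r["R/RT"] - r["S/ST"]) >= 1 or a["R/RT"] >= 3 or a["S/ST"] >= 3
    return a["R/RT"] >= 2 or a["R/S"] >= 2 or a["S/ST"] >= 2


LABELS_BY_MASK = {
    frozenset({"RT-R"}): ("R/RT",),
    frozenset({"RT-R", "S-R"}): ("R/RT", "R/S"),
    frozenset({"ST-S"}): ("S/ST",),
    frozenset({"S-R", "ST-S"}): ("R/S", "S/ST"),
    frozenset({"S-R"}): ("R/S",),
    frozenset({"RT-R", "ST-S"}): ("R/RT", "S/ST"),
    frozenset({"RT-R", "S-R", "ST-S"}): ("R/RT", "R/S", "S/ST"),
}


class TestFilterCrucial:
    def _assign(self, mask, ratios):
        a = CategoryAssignment(
            "g", frozenset(mask), CATEGORY_BY_MASK[frozenset(mask)], log2_ratios=ratios
        )
        return filter_crucial([a])[0]

    def test_strong_negative_fold_change_is_crucial(self):
        assert self._assign({"RT-R"}, {"R/RT": -10.2858}).crucial

    def test_moderate_fold_change_is_not_crucial(self):
        assert not self._assign({"RT-R"}, {"R/RT": 1.2528}).crucial

    def test_cutoff_is_inclusive(self):
        assert self._assign({"RT-R"}, {"R/RT": 5.0}).crucial

    def test_excluded_genes_never_crucial(self):
        a = CategoryAssignment("g", frozenset({"ST-RT"}), "EXCLUDED")
        assert not filter_crucial([a])[0].crucial

    def test_missing_ratio_raises_naming_gene_and_mask(self):
        a = CategoryAssignment("gene7", frozenset({"RT-R"}), "RDR", log2_ratios={})
        with pytest.raises(ValueError, match="gene7"):
            filter_crucial([a])

    def test_random_assignments_match_rule_oracle(self):
        rng = np.random.default_rng(5)
        masks = list(LABELS_BY_MASK)
        assignments = []
        for i in range(1000):
            mask = masks[rng.integers(len(masks))]
            ratios = {lab: float(rng.uniform(-8, 8)) for lab in LABELS_BY_MASK[mask]}
            assignments.append(
                CategoryAssignment(f"g{i}", mask, CATEGORY_BY_MASK[mask], log2_ratios=ratios)
            )
        filter_crucial(assignments)
        for a in assignments:
            assert a.crucial == brute_force_crucial(set(a.region), a.log2_ratios)

    def test_raising_cutoffs_never_adds_crucial_genes(self):
        rng = np.random.default_rng(9)
        masks = list(LABELS_BY_MASK)
        assignments = []
        for i in range(400):
            mask = masks[rng.integers(len(masks))]
            ratios = {lab: float(rng.uniform(-8, 8)) for lab in LABELS_BY_MASK[mask]}
            assignments.append(
                CategoryAssignment(f"g{i}", mask, CATEGORY_BY_MASK[mask], log2_ratios=ratios)
            )
        base = {a.gene_id for a in filter_crucial(assignments) if a.crucial}
        raised = {
            "crucial_single_cutoff": 6.0,
            "crucial_rdr_pair_diff": 3.0,
            "crucial_sdr_pair_diff": 6.0,
            "crucial_cdr_pair_diff": 2.0,
            "crucial_cdr_pair_single": 4.0,
            "crucial_triple_single": 3.0,
        }
        strict = {a.gene_id for a in filter_crucial(assignments, raised) if a.crucial}
        assert strict <= base


class TestRegulationSummary:
    def _assignments(self, values):
        out = []
        for i, v in enumerate(values):
            a = CategoryAssignment(
                f"g{i}", frozenset({"RT-R"}), "RDR", crucial=True, log2_ratios={"R/RT": v}
            )
            out.append(a)
        return out

    def test_all_up_means_zero_down(self):
        summary = regulation_summary(self._assignments([1.5, 2.0, 3.0]), "RDR")
        assert summary.at["R/RT", "down"] == 0
        assert summary.at["R/RT", "up"] == 3

    def test_published_percentage_reproduces(self):
        # 37 genes, 29 down-regulated in R vs RT -> 78.38%
        values = [-2.0] * 29 + [2.0] * 8
        summary = regulation_summary(self._assignments(values), "RDR")
        assert summary.at["R/RT", "n"] == 37
        assert summary.at["R/RT", "pct_down"] == pytest.approx(78.38)

    def test_tallies_sum_to_genes_with_direction(self):
        values = [-1.0, 2.0, -3.0, 4.0, -5.0]
        summary = regulation_summary(self._assignments(values), "RDR")
        assert summary.at["R/RT", "up"] + summary.at["R/RT", "down"] == len(values)
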