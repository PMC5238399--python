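from itertools import combinations

import numpy as np
import pytest

from droughtnet.core_io import AnnotationMap
from droughtnet.networks import (
    all_projections,
    build_tripartite,
    export_network,
    network_stats,
    powerlaw_slope,
    project,
    read_network,
)


def make_annotations(pathways: dict, processes: dict | None = None, n_bg: int = 1000):
    return AnnotationMap(
        gene_to_pathways=pathways,
        gene_to_processes=processes or {},
        background_gene_count=n_bg,
    )


class TestBuildTripartite:
    def test_single_gene_forms_triangle(self):
        ann = make_annotations({"g": {"ko00010"}}, {"g": {"GO:0000001"}})
        g = build_tripartite({"g"}, ann)
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 3

    def test_disjoint_annotations_form_disjoint_triangles(self):
        ann = make_annotations(
            {"a": {"ko00010"}, "b": {"ko00020"}},
            {"a": {"GO:0000001"}, "b": {"GO:0000002"}},
        )
        g = build_tripartite({"a", "b"}, ann)
        assert g.number_of_nodes() == 6
        assert g.number_of_edges() == 6

    def test_unannotated_gene_kept_as_isolated_node(self):
        g = build_tripartite({"lonely"}, make_annotations({}))
        assert g.degree("lonely") == 0

    def test_process_pathway_edge_requires_shared_gene(self):
        ann = make_annotations(
            {"a": {"ko00010"}, "b": {"ko00020"}},
            {"a": {"GO:0000001"}, "b": {"GO:0000001"}},
        )
        g = build_tripartite({"a", "b"}, ann)
        assert g.has_edge("GO:0000001", "ko00010")
        assert g.has_edge("GO:0000001", "ko00020")
        assert not g.has_edge("ko00010", "ko00020")  # no intra-layer edges


class TestProject:
    def test_shared_pathway_weight_one(self):
        ann = make_annotations({"a": {"ko01100"}, "b": {"ko01100"}})
        net = project(build_tripartite({"a", "b"}, ann), "gene", "pathway")
        assert net["a"]["b"]["weight"] == 1

    def test_toy_pathway_gene_network(self):
        ann = make_annotations(
            {"a": {"ko00001", "ko00002"}, "b": {"ko00001", "ko00002"}, "c": {"ko00003"}}
        )
        net = project(build_tripartite({"a", "b", "c"}, ann), "gene", "pathway")
        assert net["a"]["b"]["weight"] == 2
        assert net.degree("c") == 0
        assert net.number_of_edges() == 1

    def test_same_layer_rejected(self):
        g = build_tripartite({"a"}, make_annotations({"a": {"ko00001"}}))
        with pytest.raises(ValueError, match="must differ"):
            project(g, "gene", "gene")

    def test_weights_match_brute_force_intersections(self):
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(30)]
        terms = [f"ko{i:05d}" for i in range(1, 11)]
        pathways = {
            g: set(rng.choice(terms, size=rng.integers(0, 5), replace=False).tolist())
            for g in genes
        }
        pathways = {g: s for g, s in pathways.items() if s}
        ann = make_annotations(pathways)
        net = project(build_tripartite(set(genes), ann), "gene", "pathway")
        for a, b in combinations(genes, 2):
            expected = len(pathways.get(a, set()) & pathways.get(b, set()))
            got = net[a][b]["weight"] if net.has_edge(a, b) else 0
            assert got == expected

    def test_projection_total_weight_duality(self):
        # sum of pairwise shared counts == sum over terms of C(members, 2)
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(25)]
        terms = [f"ko{i:05d}" for i in range(1, 9)]
        pathways = {
            g: set(rng.choice(terms, size=rng.integers(1, 5), replace=False).tolist())
            for g in genes
        }
        ann = make_annotations(pathways)
        tri = build_tripartite(set(genes), ann)
        net = project(tri, "gene", "pathway")
        total_weight = sum(w for _, _, w in net.edges(data="weight"))
        members = {t: sum(t in pathways[g] for g in genes) for t in terms}
        assert total_weight == sum(m * (m - 1) // 2 for m in members.values())

    def test_projection_preserves_node_layer(self):
        ann = make_annotations({"a": {"ko00001"}}, {"a": {"GO:0000001", "GO:0000002"}})
        nets = all_projections(build_tripartite({"a"}, ann))
        assert set(nets) == {
            "pathway-gene", "process-gene", "gene-pathway",
            "process-pathway", "gene-process", "pathway-process",
        }
        assert set(nets["pathway-gene"].nodes) == {"a"}
        assert set(nets["gene-process"].nodes) == {"GO:0000001", "GO:0000002"}
        # the two processes share gene a -> weight-1 edge
        assert nets["gene-process"]["GO:0000001"]["GO:0000002"]["weight"] == 1


class TestNetworkStats:
    def test_empty_network(self):
        ann = make_annotations({})
        net = project(build_tripartite({"a", "b"}, ann), "gene", "pathway")
        s = network_stats(net)
        assert s.edge_count == 0
        assert s.mean_degree == 0.0
        assert s.isolated_nodes == ["a", "b"]
        assert s.max_weight_edge is None

    def test_triangle_mean_degrees(self):
        ann = make_annotations({g: {"ko00001"} for g in "abc"})
        net = project(build_tripartite(set("abc"), ann), "gene", "pathway")
        s = network_stats(net)
        assert s.node_count == 3
        assert s.edge_count == 3
        assert s.mean_degree == pytest.approx(2.0)  # 2E/N
        assert s.mean_degree_edges_per_node == pytest.approx(1.0)  # E/N
        assert s.degree_histogram == {2: 3}

    def test_max_weight_edge_reported(self):
        ann = make_annotations({"a": {"ko00001", "ko00002"}, "b": {"ko00001", "ko00002"}, "c": {"ko00001"}})
        net = project(build_tripartite(set("abc"), ann), "gene", "pathway")
        assert network_stats(net).max_weight_edge == ("a", "b", 2)


class TestPowerlawSlope:
    def test_exact_power_law_recovered(self):
        hist = {d: int(round(1000 * d**-2.0)) for d in range(1, 51)}
        # exact frequencies to avoid rounding distortion
        hist = {d: 1000 * 50**2 // d**2 for d in range(1, 51)}
        slope = powerlaw_slope(hist)
        assert slope == pytest.approx(-2.0, abs=0.01)

    def test_uniform_histogram_flat(self):
        assert powerlaw_slope({d: 7 for d in range(1, 20)}) == pytest.approx(0.0, abs=1e-9)

    def test_too_few_bins_signals_undefined(self):
        assert powerlaw_slope({1: 5, 2: 3}) is None
        assert powerlaw_slope({0: 10, 1: 5, 2: 3}) is None  # zero-degree bin excluded


class TestExportImport:
    def _toy_net(self):
        ann = make_annotations(
            {"a": {"ko00001", "ko00002"}, "b": {"ko00001", "ko00002"}, "c": {"ko00003"}}
        )
        return project(build_tripartite({"a", "b", "c"}, ann), "gene", "pathway")

    @pytest.mark.parametrize("fmt", ["tsv", "graphml"])
    def test_round_trip(self, fmt, tmp_path):
        net = self._toy_net()
        path = tmp_path / f"net.{fmt}"
        export_network(net, path, fmt=fmt)
        back = read_network(path, fmt=fmt)
        assert set(back.nodes) == set(net.nodes)
        assert {
            (tuple(sorted(e)), d["weight"]) for *e, d in back.edges(data=True)
        } == {(tuple(sorted(e)), d["weight"]) for *e, d in net.edges(data=True)}

    def test_triangle_edge_list_lines(self, tmp_path):
        ann = make_annotations({g: {"ko00001"} for g in "abc"})
        net = project(build_tripartite(set("abc"), ann), "gene", "pathway")
        path = tmp_path / "net.tsv"
        export_network(net, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "node_a\tnode_b\tweight"
        assert len(lines) == 4  # header + 3 edges

    def test_empty_network_header_only(self, tmp_path):
        ann = make_annotations({})
        net = project(build_tripartite(set(), ann), "gene", "pathway")
        path = tmp_path / "empty.tsv"
        export_network(net, path)
        assert path.read_text() == "node_a\tnode_b\tweight\n"
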