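"""Tripartite annotation graph and its six weighted projections.

Builds the gene / biological-process / pathway tripartite graph for the
crucial gene set, derives all six one-mode projections (edge weight =
number of shared linking-layer entities) and prints their summary
statistics, including both mean-degree conventions and the log-log
degree-distribution slope where defined.
"""

from droughtnet import pipeline
from droughtnet.networks import all_projections, build_tripartite, network_stats, powerlaw_slope
from droughtnet.synthetic_data import SimulationConfig, simulate_experiment

table, annotations, _ = simulate_experiment(SimulationConfig(n_genes=2000, seed=7))
_, assignments = pipeline.classify_experiment(table, annotations)
crucial = {a.gene_id for a in assignments if a.crucial}

graph = build_tripartite(crucial, annotations)
layers = {"gene": 0, "process": 0, "pathway": 0}
for _, d in graph.nodes(data=True):
    layers[d["layer"]] += 1
print(f"tripartite graph: {layers} nodes, {graph.number_of_edges()} edges")

print(f"\n{'projection':18s} {'nodes':>5s} {'edges':>6s} {'2E/N':>8s} {'E/N':>8s} {'isolated':>8s}  slope")
for name, net in all_projections(graph).items():
    s = network_stats(net)
    slope = powerlaw_slope(s.degree_histogram)
    slope_txt = f"{slope:+.2f}" if slope is not None else "undef"
    print(
        f"{name:18s} {s.node_count:5d} {s.edge_count:6d} "
        f"{s.mean_degree:8.2f} {s.mean_degree_edges_per_node:8.2f} "
        f"{len(s.isolated_nodes):8d}  {slope_txt}"
    )

pg = all_projections(graph)["gene-pathway"]
s = network_stats(pg)
if s.max_weight_edge:
    a, b, w = s.max_weight_edge
    print(f"\nstrongest pathway pair: {a} -- {b} share {w} crucial genes")
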