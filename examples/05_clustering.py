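"""Hierarchical clustering of expression profiles and gene locations.

Clusters the crucial genes' log2(RPKM) profiles across the four libraries
(Euclidean distance, average linkage) and the chromosome x position-bin
incidence matrix of their locations (Pearson distance), printing the merge
heights that would shape the dendrograms.
"""

from droughtnet import pipeline
from droughtnet.clustering import (
    chromosome_position_matrix,
    distance_matrix,
    hclust_average,
    log_rpkm_matrix,
)
from droughtnet.core_io import parse_gene_id
from droughtnet.synthetic_data import SimulationConfig, simulate_experiment

table, annotations, _ = simulate_experiment(SimulationConfig(n_genes=2000, seed=7))
_, assignments = pipeline.classify_experiment(table, annotations)
crucial = sorted(a.gene_id for a in assignments if a.crucial)
print(f"clustering {len(crucial)} crucial genes")

expr = log_rpkm_matrix(table).loc[crucial]
dend = hclust_average(distance_matrix(expr, metric="euclidean"))
print(f"expression dendrogram: {len(dend.merges)} merges, "
      f"heights {dend.heights[0]:.2f} .. {dend.heights[-1]:.2f}")

# sample-side view: which libraries have the most similar profiles?
sample_dend = hclust_average(distance_matrix(expr.T, metric="pearson"))
first = sample_dend.merges[0]
labels = list(expr.columns)
print(f"most similar libraries: {labels[first[0]]} and {labels[first[1]]} "
      f"(Pearson distance {first[2]:.3f})")

loci = [parse_gene_id(g) for g in crucial]
incidence = chromosome_position_matrix(loci, bin_width=1000)
chrom_dend = hclust_average(distance_matrix(incidence + 1e-9, metric="euclidean"))
print(f"chromosome incidence matrix: {incidence.shape[0]} chromosomes x "
      f"{incidence.shape[1]} bins; first merge at height {chrom_dend.heights[0]:.2f}")
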