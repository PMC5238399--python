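"""Classify DEGs into RDR / SDR / CDR categories and select crucial genes.

Runs the full two-round selection on a simulated experiment: pathway-
annotation filtering, the four-set Venn partition (masks containing the
control-versus-control comparison ST-RT are excluded), Table-style category
assignment, and the subgroup-specific fold-change rules for crucial genes.
"""

from droughtnet import pipeline
from droughtnet.classification import category_totals, regulation_summary
from droughtnet.synthetic_data import SimulationConfig, simulate_experiment

table, annotations, truth = simulate_experiment(SimulationConfig(n_genes=2000, seed=7))
calls, assignments = pipeline.classify_experiment(table, annotations)

totals = category_totals(assignments)
print("category totals (first round):", totals)

crucial = [a for a in assignments if a.crucial]
print(f"crucial genes (second round): {len(crucial)}")
by_mask: dict[str, int] = {}
for a in crucial:
    by_mask[",".join(sorted(a.region))] = by_mask.get(",".join(sorted(a.region)), 0) + 1
for mask, n in sorted(by_mask.items()):
    print(f"  {mask:20s} {n}")

print("\nregulation of crucial RDR genes (sign of each carried log2 ratio):")
print(regulation_summary(assignments, "RDR"))

recovered = {a.gene_id for a in crucial} & truth.crucial_genes
print(f"\n{len(recovered)} of {len(truth.crucial_genes)} truly crucial genes recovered")
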