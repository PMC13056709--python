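"""Generate a paired day-0/day-14 synthetic snRNA-seq experiment.

Four broad brain cell types with disjoint marker blocks; day-14 profiles are
drift-perturbed copies of day-0 profiles and the neuronal fraction is halved,
mimicking the cell loss seen in cultured tissue slices.
"""

from txfidelity import SimConfig, cell_table_from_truth, generate_experiment

config = SimConfig(n_genes=1000, n_cells_day0=1000, n_cells_day14=800,
                   n_markers_per_type=40, drift_sd=0.3, seed=1)
day0, day14, truth = generate_experiment(config)

print(f"day 0:  {day0.n_genes} genes x {day0.n_cells} cells")
print(f"day 14: {day14.n_genes} genes x {day14.n_cells} cells")
print(f"mitochondrial genes: {sorted(truth.mito_genes)[:3]} ... ({len(truth.mito_genes)} total)")

cells = cell_table_from_truth(day0, day14, truth)
print("\ncomposition (fraction of cells per type and timepoint):")
table = cells.groupby(["timepoint", "true_label"]).size().unstack()
print((table.div(table.sum(axis=1), axis=0)).round(3))
# The day-14 neuron fraction is half the day-0 one by construction; the other
# types expand proportionally.
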