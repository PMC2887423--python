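"""Generate a simulated regulatory network with knockout expression data.

Builds a 20-gene network (TF-hub topology, mostly tree-like) and its
steady-state expression matrix: one wild-type column plus one column per
single-gene knockout, noisy and normalized to a dataset maximum of one.
"""

from pugrn import SimulationConfig, generate_dataset

config = SimulationConfig(n_genes=20, edge_density=1.5, noise_sd=0.05, seed=7)
network, expr = generate_dataset(config)

regulators = sorted({a for a, _ in network.edges})
print(f"network: {network.n_genes} genes, {len(network.edges)} edges, "
      f"{len(regulators)} regulators {regulators}")
print(f"expression: {expr.values.shape[0]} genes x {expr.values.shape[1]} conditions "
      f"(wt + one knockout per gene), max entry {expr.values.max():.1f}")

# a knockout silences its own gene and depresses its direct targets
tf = regulators[0]
col = expr.condition_ids.index(f"kd_{tf}")
row = expr.gene_ids.index(tf)
print(f"knockout of {tf}: own level {expr.values[row, col]:.2g} "
      f"(wild type {expr.values[row, 0]:.2f})")
for a, b in sorted(network.edges):
    if a == tf:
        r = expr.gene_ids.index(b)
        print(f"  target {b}: {expr.values[r, 0]:.2f} -> {expr.values[r, col]:.2f}")
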