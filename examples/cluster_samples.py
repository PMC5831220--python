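"""Hierarchical sample clustering next to the silhouette score.

Builds the average-linkage (UPGMA) dendrogram of the samples on the
1 - Spearman r distance matrix and prints it as a Newick string — the
tree a researcher would inspect visually, while AS summarizes the same
separation numerically.
"""

from groupsil import (
    SimulationConfig,
    average_linkage,
    filter_genes,
    newick_string,
    silhouette_scores,
    simulate_counts,
    spearman_distance,
)

ds = simulate_counts(SimulationConfig(n_genes=1500, p_deg=0.4,
                                      n_rep_A=4, n_rep_B=4, seed=11))
filtered, _ = filter_genes(ds.matrix)
D = spearman_distance(filtered)
tree = average_linkage(D)
print("merge heights:", [round(h, 4) for h in tree.heights])
print("newick:", newick_string(tree))
print(f"AS = {silhouette_scores(D, ds.labels).AS:.4f} "
      "(the numerical counterpart of the visual group separation)")
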