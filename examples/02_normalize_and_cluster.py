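"""Quantile normalization and sample clustering.

Normalizes the mouse-like experiment, keeps the 2000 most variable genes,
clusters samples with 1 - Pearson distance and average linkage, and cuts
the tree at the three developmental stages.
"""

from pagenet import (
    SyntheticConfig,
    average_linkage,
    correlation_distance,
    cut_clusters,
    generate_catalog,
    generate_experiment_pair,
    quantile_normalize,
    select_top_variable,
    to_newick,
)

config = SyntheticConfig(seed=1)
_, mouse, _, _ = generate_experiment_pair(config, generate_catalog(config))

normalized = quantile_normalize(mouse)
top = select_top_variable(normalized, 2000)
dendrogram = average_linkage(correlation_distance(top))
assignment = cut_clusters(dendrogram, 3)

print(f"clustered {top.n_genes} variable genes x {top.n_samples} samples")
print("newick:", to_newick(dendrogram)[:80], "...")
for group in ("E16d", "PN1d", "PN7d"):
    members = sorted(s for s in assignment if s.startswith(group))
    clusters = sorted({assignment[s] for s in members})
    print(f"  {group}: samples fall in cluster(s) {clusters}")
# Each developmental stage should occupy its own cluster: the planted
# per-stage expression programs separate the samples.
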