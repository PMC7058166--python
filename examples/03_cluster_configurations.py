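"""Cluster taxa by subunit copy-number profile and classify configurations.

Reproduces the heatmap organization: taxa hierarchically clustered on their
count vectors, each labeled ancestral / expanded / reduced / mixed relative
to the ancestral profile (2 CDC6/ORC1 + 1 each of ORC2-5), with normalized
genome metrics joined on.
"""

from orcevo import count_distances, heatmap_table, hierarchical_cluster, summarize
from orcevo.simulate import SimulationConfig, simulate_dataset

ds = simulate_dataset(SimulationConfig(n_taxa=20), seed=3)
s = summarize(ds.matrix)
print(f"{s.n_taxa} taxa, mean subunits {s.mean_subunits:.2f} "
      f"(min {s.min_count} in {s.min_taxon}, max {s.max_count} in {s.max_taxon})")
print("configuration classes:", s.class_tally)

dend = hierarchical_cluster(count_distances(ds.matrix), linkage="complete")
table = heatmap_table(dend, ds.matrix, ds.metrics[["genome_size_bp", "gene_count"]])
print("\nheatmap table (dendrogram leaf order):")
print(table.to_string())
print("\nRows are ordered so every cluster is contiguous; gs_norm/gc_norm are")
print("log-genome-size and gene-count normalized to the largest in the set.")
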