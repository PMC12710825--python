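"""Embed cells and measure cluster separation against known labels.

Log-normalizes a gene-by-cell count matrix, computes PCA through the
implicitly centered truncated SVD, and evaluates how well the embedding
separates the true cell types with the Calinski-Harabasz index,
per-cluster mean silhouette, and per-cluster kNN purity.
"""

import numpy as np

import remo

world = remo.generate_world(seed=7)
counts = world.expression.matrix  # genes x cells
norm = remo.log_normalize(counts, scale=10_000)
embedding, singular_values = remo.truncated_svd(norm, n_dims=20, center=True, seed=7)

labels = world.cells.to_numpy()
ch = remo.ch_index(embedding, labels)
sil = remo.silhouette_by_cluster(embedding, labels)
purity = remo.knn_purity(embedding, labels, k=20)
print(f"embedded {embedding.shape[0]} cells into {embedding.shape[1]} PCs")
print(f"Calinski-Harabasz index: {ch:.0f}  (higher = tighter, better-separated clusters)")
print(f"mean per-cluster silhouette: {sil.mean():.3f}  (range -1..1)")
print(f"mean per-cluster kNN purity: {purity.mean():.3f}  (1 = all neighbours share the label)")
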