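"""Discover novel cell types with the unsupervised block.

Builds a mutual kNN graph over cells of types never seen in the label set,
learns node embeddings by local-global mutual-information maximization, and
infers both the number of novel types and the assignments with a Dirichlet
process Gaussian mixture: components whose posterior weight reaches t = 0.05
become novel types.
"""

import numpy as np

from annogcd import SynthConfig, build_knn_graph, fit_dpmm, select_novel_clusters, simulate_cells, train_dgi
from annogcd.unsup import l2_normalize

# 4 novel types, none of them labeled anywhere
ds = simulate_cells(SynthConfig(n_types=4, n_cells=700, n_genes=60,
                                separation=8.0, gini_target=0.4, seed=9))
graph = build_knn_graph(ds.features, k=50)
print(f"kNN graph: {graph.n_nodes} cells, {graph.edge_list().shape[0]} edges")

emb, dgi = train_dgi(graph, dim=32, epochs=500, seed=9, return_model=True)
print(f"infomax discriminator loss: {dgi.loss_history[0]:.3f} -> "
      f"{dgi.loss_history[-1]:.4f}")

fit = fit_dpmm(l2_normalize(emb), max_components=20, seed=9)
state, mapping = select_novel_clusters(fit, t=0.05, K=0)
sig = np.sort(fit.weights[fit.weights >= 0.05])[::-1]
print(f"significant component weights: {np.round(sig, 3)}  "
      f"-> {len(mapping)} novel types (4 were planted)")
for cluster in sorted(set(state.labels)):
    members = state.labels == cluster
    top = max(set(ds.true_type[members]), key=lambda t: (ds.true_type[members] == t).sum())
    purity = np.mean(ds.true_type[members] == top)
    print(f"  cluster {cluster}: {members.sum():4d} cells, "
          f"dominant true type {top} (purity {purity:.2f})")
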