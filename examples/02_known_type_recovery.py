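"""Re-discover known cell types with the semi-supervised block.

Trains the autoencoder + predictor jointly, fits one one-class SVM per known
type on the latent codes of its labeled cells, and labels each unlabeled cell
by the three-case consensus rule (single acceptance -> that type; multiple ->
neighbor vote; none -> left unlabeled for the novel-type block).
"""

import numpy as np

from annogcd import (
    Role, SynthConfig, UNLABELED, consensus_label, encode, fit_occ_bank,
    make_split, reduce_pca, simulate_cells, train_semisup,
)

ds = reduce_pca(simulate_cells(SynthConfig(n_types=8, n_cells=1600, n_genes=100,
                                           separation=8.0, gini_target=0.4,
                                           seed=3)), 64)
split = make_split(ds, seed=3)
model = train_semisup(split, h=32, epochs=500, seed=3)
print(f"joint loss: {model.loss_history[0]:.3f} (epoch 1) -> "
      f"{model.loss_history[-1]:.3f} (epoch 500); learned weights "
      f"alpha={model.weights[0]:.3f}, beta={model.weights[1]:.3f}")

X = split.dataset.features
lab = split.mask(Role.LABELED_KNOWN)
Z = encode(model, X).Z
bank = fit_occ_bank(Z[lab], split.label[lab], split.n_known)
pool = split.unlabeled_mask
state = consensus_label(bank, Z[pool], Z[lab], split.label[lab], N=20)

truth = split.true_label_indices()[pool]
roles = split.role[pool]
uk = roles == int(Role.UNLABELED_KNOWN)
un = roles == int(Role.UNLABELED_NOVEL)
print(f"unlabeled known-type cells correctly labeled: "
      f"{np.mean(state.labels[uk] == truth[uk]):.3f}")
print(f"novel-type cells left unlabeled (as they should be): "
      f"{np.mean(state.labels[un] == UNLABELED):.3f}")
print("Cells the classifiers reject are handed to the unsupervised block, "
      "which clusters them into candidate novel types.")
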