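"""Final nearest-neighbor label refinement and the discovery accuracy metrics.

After both blocks have run, every unlabeled-pool cell carries either a known
class in ``[0, K)`` or a novel cluster id ``>= K``.  A single simultaneous
refinement pass then re-assigns each cell the most common label among its
nearest unlabeled-pool neighbors in the shared PCA feature space, smoothing
isolated disagreements between the two blocks.

Evaluation follows the generalized-category-discovery convention: accuracy on
unlabeled known-type cells is plain classification accuracy (the semi-
supervised block emits true class ids); accuracy on novel-type cells is
clustering accuracy after optimally matching predicted clusters to true novel
classes with the Hungarian algorithm; overall accuracy combines both maps over
the full unlabeled pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.neighbors import NearestNeighbors

from .prep import UNLABELED
from .semisup import LabelState, Provenance

__all__ = [
    "EvaluationReport",
    "refine_labels",
    "hungarian_match",
    "known_accuracy",
    "novel_accuracy",
    "overall_accuracy",
]


@dataclass
class EvaluationReport:
    """Discovery accuracies over the unlabeled pool."""

    known_acc: float
    novel_acc: float
    all_acc: float
    n_known_eval: int
    n_novel_eval: int
    mapping: Dict[int, int]
    n_novel_discovered: int = 0

    def as_dict(self) -> dict:
        return {
            "known_acc": self.known_acc,
            "novel_acc": self.novel_acc,
            "all_acc": self.all_acc,
            "n_known_eval": self.n_known_eval,
            "n_novel_eval": self.n_novel_eval,
            "n_novel_discovered": self.n_novel_discovered,
            "mapping": {int(k): int(v) for k, v in self.mapping.items()},
        }


def refine_labels(features: np.ndarray, labels: LabelState, n_neighbors: int = 10) -> LabelState:
    """One simultaneous nearest-neighbor smoothing pass over the unlabeled pool.

    ``features`` are the (PCA) features of exactly the unlabeled-pool cells and
    ``labels`` their current full labeling.  Each cell's refined label is the
    mode of the *pre*-refinement labels of its ``n_neighbors`` nearest pool
    cells (self excluded); ties break toward the cell's own current label, then
    toward the lowest label id.
    """
    X = np.asarray(features, float)
    lab = labels.labels
    if X.shape[0] != len(lab):
        raise ValueError("features and labels must cover the same cells")
    if np.any(lab == UNLABELED):
        raise ValueError("refinement requires every cell to be labeled")
    n = X.shape[0]
    k = min(n_neighbors, n - 1)
    if k < 1:
        return labels.copy()
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, nbr = nn.kneighbors(X)
    nbr = nbr[:, 1:]  # drop self

    n_labels = int(lab.max()) + 1
    new_labels = lab.copy()
    new_prov = labels.provenance.copy()
    for i in range(n):
        counts = np.bincount(lab[nbr[i]], minlength=n_labels)
        best = counts.max()
        tied = np.flatnonzero(counts == best)
        if len(tied) > 1 and lab[i] in tied:
            winner = lab[i]
        else:
            winner = int(tied[0])
        if winner != lab[i]:
            new_labels[i] = winner
            new_prov[i] = int(Provenance.REFINED)
    return LabelState(new_labels, new_prov)


def hungarian_match(cost: np.ndarray) -> List[Tuple[int, int]]:
    """Minimum-cost assignment on a (possibly rectangular) cost matrix.

    Rectangular inputs behave as if zero-padded to square: every row (or
    column, whichever side is smaller) is matched and the total cost over real
    entries is minimal among all injections.
    """
    C = np.asarray(cost, float)
    if C.ndim != 2 or C.size == 0:
        raise ValueError("cost matrix must be non-empty and 2-D")
    if not np.all(np.isfinite(C)):
        raise ValueError("cost matrix must be finite")
    rows, cols = linear_sum_assignment(C)
    return list(zip(rows.tolist(), cols.tolist()))


def known_accuracy(state: LabelState, truth: np.ndarray, eval_mask: np.ndarray) -> float:
    """Classification accuracy on the unlabeled known-type cells.

    ``truth`` holds the true class index per cell; cells carrying a novel
    cluster id count as errors.
    """
    mask = np.asarray(eval_mask, bool)
    if mask.sum() == 0:
        raise ValueError("evaluation mask for known classes is empty")
    return float(np.mean(state.labels[mask] == np.asarray(truth)[mask]))


def novel_accuracy(state: LabelState, truth: np.ndarray, eval_mask: np.ndarray,
                   K: int = None) -> Tuple[float, Dict[int, int]]:
    """Hungarian-matched clustering accuracy on the novel-type cells.

    Predicted novel cluster ids are matched one-to-one to true novel classes so
    as to maximize agreement over the mask; cells predicted as a *known* class
    have no Hungarian column and always count as errors.  Returns the accuracy
    and the injective cluster-to-class map.
    """
    mask = np.asarray(eval_mask, bool)
    if mask.sum() == 0:
        raise ValueError("evaluation mask for novel classes is empty")
    truth = np.asarray(truth)
    pred = state.labels[mask]
    true = truth[mask]
    if K is None:
        K = int(true.min())  # novel truth ids start at K
    pred_ids = np.unique(pred[pred >= K])
    true_ids = np.unique(true)
    if len(pred_ids) == 0:
        return 0.0, {}
    cont = np.zeros((len(pred_ids), len(true_ids)))
    pi = {p: i for i, p in enumerate(pred_ids)}
    ti = {c: j for j, c in enumerate(true_ids)}
    for p, c in zip(pred, true):
        if p >= K:
            cont[pi[p], ti[c]] += 1
    pairs = hungarian_match(-cont)
    matched = sum(cont[r, c] for r, c in pairs)
    mapping = {int(pred_ids[r]): int(true_ids[c]) for r, c in pairs if cont[r, c] > 0}
    return float(matched / mask.sum()), mapping


def overall_accuracy(state: LabelState, truth: np.ndarray, K: int,
                     novel_mask: np.ndarray = None) -> float:
    """Accuracy over the whole unlabeled pool under the combined label map.

    Known ids are identity-mapped (the semi-supervised block emits true class
    indices); novel cluster ids are mapped through the Hungarian assignment
    computed on the novel-truth cells of the pool.
    """
    truth = np.asarray(truth)
    if novel_mask is None:
        novel_mask = truth >= K
    if novel_mask.sum() > 0:
        _, mapping = novel_accuracy(state, truth, novel_mask, K=K)
    else:
        mapping = {}
    pred = state.labels
    correct = np.zeros(len(pred), bool)
    known_pred = pred < K
    correct[known_pred] = pred[known_pred] == truth[known_pred]
    for cluster, cls in mapping.items():
        sel = pred == cluster
        correct[sel] = truth[sel] == cls
    return float(correct.mean())
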