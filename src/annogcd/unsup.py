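"""Unsupervised block: discover novel cell types among residual unlabeled cells.

Cells left unlabeled by the semi-supervised consensus are assumed to belong to
types never seen in the label set.  This module

1. builds a kNN graph over their (PCA) features — edges connect cells that are
   among each other's k nearest neighbors;
2. learns an unsupervised embedding per cell with a two-layer graph
   convolutional encoder trained by local-global mutual-information
   maximization (the Deep Graph Infomax scheme: a bilinear discriminator is
   trained to tell true (node, graph-summary) pairs from pairs built on
   feature-shuffled corrupted inputs);
3. fits a Dirichlet process Gaussian mixture (stick-breaking, variational,
   diagonal covariances) with a generous component budget, and calls a
   component a novel cell type when its posterior weight reaches a threshold
   ``t``; cells of sub-threshold components are reassigned to their best
   significant component so the block always emits a complete labeling.

The graph encoder is implemented directly in numpy (two message-passing layers
with parametric-ReLU activations, manual gradients, Adam), which is fast at the
graph sizes this block sees after the semi-supervised pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp
from sklearn.mixture import BayesianGaussianMixture

from ._nn import Adam, sigmoid
from .prep import UNLABELED
from .semisup import LabelState, Provenance

__all__ = [
    "CellGraph",
    "DGIModel",
    "DPMMFit",
    "build_knn_graph",
    "corrupt_features",
    "dgi_loss",
    "train_dgi",
    "fit_dpmm",
    "select_novel_clusters",
]


@dataclass
class CellGraph:
    """Symmetric, self-loop-free kNN graph over residual cells."""

    nodes: np.ndarray            # indices of the residual cells in the parent set
    adjacency: sp.csr_matrix     # boolean, symmetric, zero diagonal
    node_features: np.ndarray    # (n_residual, d)

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    def edge_list(self) -> np.ndarray:
        """Undirected edges as (u, v) pairs with u < v."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return np.stack([coo.row, coo.col], axis=1)


def _pairwise_sq_dists(X: np.ndarray, chunk: np.ndarray) -> np.ndarray:
    sq = (X * X).sum(axis=1)
    return np.maximum(sq[chunk][:, None] - 2.0 * X[chunk] @ X.T + sq[None, :], 0.0)


def build_knn_graph(features: np.ndarray, k: int = 50, mutual: bool = True) -> CellGraph:
    """Build the kNN graph (Euclidean) with mutual (default) or union edges.

    Under the mutual rule an edge {u, v} exists iff v is among u's k nearest
    neighbors AND u among v's; the union variant requires either.  Mutuality
    protects small cell populations: a type with fewer than k members is
    otherwise forced to wire into unrelated dominant types, and message
    passing then erases it.  Isolated nodes are harmless downstream because
    the graph-convolution normalization adds self-loops.  Distance ties are
    broken toward the lower cell index.
    """
    X = np.asarray(features, float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two residual cells to build a graph")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    rows, cols = [], []
    step = max(1, int(2e7 // max(n, 1)))
    for start in range(0, n, step):
        idx = np.arange(start, min(start + step, n))
        D = _pairwise_sq_dists(X, idx)
        D[np.arange(len(idx)), idx] = np.inf
        # stable argsort => equal distances keep increasing column index order
        order = np.argsort(D, axis=1, kind="stable")[:, :k]
        rows.append(np.repeat(idx, k))
        cols.append(order.ravel())
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    A = sp.csr_matrix((np.ones(len(r)), (r, c)), shape=(n, n))
    A = (A + A.T) if not mutual else A.multiply(A.T)
    A = (A > 0).astype(np.float64)
    A.setdiag(0)
    A.eliminate_zeros()
    return CellGraph(nodes=np.arange(n), adjacency=A.tocsr(), node_features=X)


def corrupt_features(graph: CellGraph, seed: int) -> np.ndarray:
    """Row-permuted copy of the node features (adjacency left unchanged)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(graph.n_nodes)
    return graph.node_features[perm]


def dgi_loss(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Discriminator binary cross-entropy, averaged over the 2n score terms.

    ``pos_scores`` are the discriminator probabilities for true (node, summary)
    pairs and ``neg_scores`` for corrupted pairs; both must lie in (0, 1)
    (values are clipped away from exactly 0/1 before the log).
    """
    pos = np.asarray(pos_scores, float)
    neg = np.asarray(neg_scores, float)
    if np.any(pos < 0) or np.any(pos > 1) or np.any(neg < 0) or np.any(neg > 1):
        raise ValueError("discriminator scores must lie in (0, 1)")
    eps = 1e-12
    pos = np.clip(pos, eps, 1 - eps)
    neg = np.clip(neg, eps, 1 - eps)
    return float(-(np.log(pos).mean() + np.log1p(-neg).mean()) / 2.0)


def _prelu(x: np.ndarray, a: float) -> np.ndarray:
    return np.where(x > 0, x, a * x)


def l2_normalize(rows: np.ndarray) -> np.ndarray:
    """Scale each row to unit Euclidean norm (zero rows left unchanged).

    Infomax node embeddings encode cluster identity mainly in their direction
    while norms vary within a cluster, so clustering operates on the unit
    sphere.
    """
    X = np.asarray(rows, float)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    return X / np.where(norms == 0, 1.0, norms)


@dataclass
class DGIModel:
    """Two-layer graph-convolutional encoder with bilinear discriminator."""

    W1: np.ndarray
    W2: np.ndarray
    a1: np.ndarray  # PReLU slopes, 1-element arrays so Adam can update in place
    a2: np.ndarray
    Wd: np.ndarray
    loss_history: List[float] = field(default_factory=list)

    def embed(self, A_hat: sp.csr_matrix, X: np.ndarray) -> np.ndarray:
        H1 = _prelu(A_hat @ (X @ self.W1), float(self.a1[0]))
        return _prelu(A_hat @ (H1 @ self.W2), float(self.a2[0]))


def _normalized_adjacency(A: sp.csr_matrix) -> sp.csr_matrix:
    A_tilde = (A + sp.eye(A.shape[0], format="csr")).tocsr()
    deg = np.asarray(A_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    D = sp.diags(d_inv_sqrt)
    return (D @ A_tilde @ D).tocsr()


def train_dgi(
    graph: CellGraph,
    dim: int = 32,
    epochs: int = 500,
    seed: int = 0,
    lr: float = 1e-3,
    return_model: bool = False,
):
    """Train the graph encoder by mutual-information maximization.

    Each epoch scores every node embedding against the sigmoid of the mean
    embedding (the graph summary) via a bilinear discriminator, once for the
    true features and once for a freshly row-shuffled corruption, and minimizes
    the discriminator cross-entropy.  Returns the final node embeddings
    (``(n_residual, dim)``), plus the model when ``return_model``.
    """
    if graph.n_nodes == 0:
        raise ValueError("cannot train on an empty graph")
    X = graph.node_features
    n, d = X.shape
    A_hat = _normalized_adjacency(graph.adjacency)
    rng = np.random.default_rng(seed)
    model = DGIModel(
        W1=rng.normal(0, np.sqrt(2.0 / d), (d, dim)),
        W2=rng.normal(0, np.sqrt(2.0 / dim), (dim, dim)),
        a1=np.array([0.25]),
        a2=np.array([0.25]),
        Wd=rng.normal(0, np.sqrt(1.0 / dim), (dim, dim)),
    )
    params = [model.W1, model.W2, model.a1, model.a2, model.Wd]
    opt = Adam(params, lr=lr)

    def forward(Xb):
        T1 = Xb @ model.W1
        P1 = A_hat @ T1
        H1 = _prelu(P1, float(model.a1[0]))
        T2 = H1 @ model.W2
        P2 = A_hat @ T2
        H2 = _prelu(P2, float(model.a2[0]))
        return P1, H1, P2, H2

    def backward(Xb, P1, H1, P2, dH2):
        a1, a2 = float(model.a1[0]), float(model.a2[0])
        dP2 = dH2 * np.where(P2 > 0, 1.0, a2)
        ga2 = float((dH2 * np.minimum(P2, 0.0)).sum())
        dT2 = A_hat @ dP2            # A_hat is symmetric
        gW2 = H1.T @ dT2
        dH1 = dT2 @ model.W2.T
        dP1 = dH1 * np.where(P1 > 0, 1.0, a1)
        ga1 = float((dH1 * np.minimum(P1, 0.0)).sum())
        dT1 = A_hat @ dP1
        gW1 = Xb.T @ dT1
        return gW1, gW2, ga1, ga2

    for epoch in range(epochs):
        Xc = graph.node_features[rng.permutation(n)]
        P1p, H1p, P2p, Zp = forward(X)
        P1n, H1n, P2n, Zn = forward(Xc)
        m = Zp.mean(axis=0)
        s_vec = sigmoid(m)
        u = model.Wd @ s_vec
        logit_p = Zp @ u
        logit_n = Zn @ u
        model.loss_history.append(
            dgi_loss(sigmoid(logit_p), sigmoid(logit_n))
        )

        dlp = (sigmoid(logit_p) - 1.0) / (2 * n)
        dln = sigmoid(logit_n) / (2 * n)
        zsum = Zp.T @ dlp + Zn.T @ dln
        gWd = np.outer(zsum, s_vec)
        ds = model.Wd.T @ zsum
        dm = ds * s_vec * (1 - s_vec)
        dZp = np.outer(dlp, u) + dm[None, :] / n
        dZn = np.outer(dln, u)

        gW1p, gW2p, ga1p, ga2p = backward(X, P1p, H1p, P2p, dZp)
        gW1n, gW2n, ga1n, ga2n = backward(Xc, P1n, H1n, P2n, dZn)
        opt.step([
            gW1p + gW1n,
            gW2p + gW2n,
            np.array([ga1p + ga1n]),
            np.array([ga2p + ga2n]),
            gWd,
        ])

    embeddings = model.embed(A_hat, X)
    return (embeddings, model) if return_model else embeddings


# ---------------------------------------------------------------------------
# Dirichlet process mixture
# ---------------------------------------------------------------------------

@dataclass
class DPMMFit:
    """Variational stick-breaking Gaussian-mixture fit with truncation level
    ``max_components``; clusters are read off the posterior weights."""

    weights: np.ndarray            # posterior mixture weights, sum to 1
    responsibilities: np.ndarray   # (n_residual, max_components), rows on simplex
    means: np.ndarray
    max_components: int
    model: Optional[BayesianGaussianMixture] = None


def fit_dpmm(embeddings: np.ndarray, max_components: int = 20, seed: int = 0) -> DPMMFit:
    """Fit a Dirichlet-process Gaussian mixture (diagonal covariances).

    The truncated stick-breaking variational approximation is used, with the
    concentration prior weight set to ``1 / max_components`` so the posterior
    prefers to silence unused components.
    """
    Z = np.asarray(embeddings, float)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise ValueError("need at least two residual cells to cluster")
    model = BayesianGaussianMixture(
        n_components=max_components,
        covariance_type="diag",
        weight_concentration_prior_type="dirichlet_process",
        weight_concentration_prior=1.0 / max_components,
        max_iter=500,
        random_state=int(seed) % (2**31),
        reg_covar=1e-6,
    )
    model.fit(Z)
    return DPMMFit(
        weights=model.weights_.copy(),
        responsibilities=model.predict_proba(Z),
        means=model.means_.copy(),
        max_components=max_components,
        model=model,
    )


def select_novel_clusters(fit: DPMMFit, t: float = 0.05, K: int = 0) -> Tuple[LabelState, Dict[int, int]]:
    """Turn the mixture fit into novel-class labels ``K, K+1, ...``.

    Components with posterior weight >= ``t`` are significant and become novel
    classes, ranked by descending weight (label ``K`` for the heaviest).  Every
    cell is assigned the significant component with the largest responsibility,
    so cells of sub-threshold components are absorbed rather than dropped.

    Returns the label fragment for the residual cells and the injective map
    component-index -> novel label.
    """
    if not (0.0 < t < 1.0):
        raise ValueError("threshold t must lie in (0, 1)")
    sig = np.flatnonzero(fit.weights >= t)
    if len(sig) == 0:
        raise ValueError(
            f"no component reaches posterior weight t={t}; largest weight is "
            f"{fit.weights.max():.4f} — lower t"
        )
    order = sig[np.argsort(-fit.weights[sig], kind="stable")]
    comp_to_label = {int(c): K + rank for rank, c in enumerate(order)}
    resp_sig = fit.responsibilities[:, order]
    best = np.argmax(resp_sig, axis=1)
    labels = np.array([K + b for b in best], dtype=int)
    prov = np.full(len(labels), int(Provenance.NOVEL_CLUSTER), dtype=int)
    return LabelState(labels, prov), comp_to_label
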