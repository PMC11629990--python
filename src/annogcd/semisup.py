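"""Semi-supervised block: re-discover known cell types among unlabeled cells.

Three networks are trained jointly on the reduced feature matrix: an encoder
``e`` mapping cells to a latent code, a decoder ``d`` reconstructing the input
from the code, and a predictor ``p`` classifying labeled cells into the K known
types.  The training objective is

    L = alpha * L_mse + beta * L_label

where ``L_mse`` is the mean squared reconstruction error over all cells,
``L_label`` the cross-entropy of the predictor over labeled cells, and the
weights ``alpha, beta`` are learned during training under a homoscedastic
uncertainty parameterization (``alpha = exp(-s1)``, ``beta = exp(-s2)`` with
``s1 + s2`` added to the optimized objective so neither weight collapses to 0).

After training, one one-class SVM (RBF kernel) per known class is fitted on the
latent codes of that class's labeled cells.  Each unlabeled cell is then passed
to all K classifiers and labeled by consensus:

1. exactly one classifier accepts -> that class;
2. several accept -> majority vote of the true labels among the cell's N
   nearest labeled cells in latent space, restricted to the accepting classes
   (falling back to the unrestricted majority when no accepting class appears
   among the neighbors);
3. none accept -> the cell stays unlabeled and is handed to the unsupervised
   block as a candidate member of a novel type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import List, Optional, Tuple, Union

import numpy as np
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import OneClassSVM

from ._nn import MLP, Adam, softmax
from .prep import UNLABELED, CellDataset, Role, SplitDataset

__all__ = [
    "Provenance",
    "LabelState",
    "LatentMatrix",
    "SemiSupModel",
    "OCCBank",
    "mse_loss",
    "label_loss",
    "loss_weights",
    "combined_loss",
    "train_semisup",
    "encode",
    "fit_occ_bank",
    "consensus_label",
]

_EPS = 1e-12  # lower clip for predicted probabilities inside the log


class Provenance(IntEnum):
    """How a cell's current label was produced."""

    GIVEN = 0
    OCC_SINGLE = 1
    OCC_CONSENSUS = 2
    NOVEL_CLUSTER = 3
    REFINED = 4
    UNLABELED = 5


@dataclass
class LabelState:
    """Evolving per-cell label vector over the combined label set.

    Labels in ``[0, K)`` are known classes, labels ``>= K`` are novel clusters,
    and :data:`annogcd.prep.UNLABELED` marks a cell not yet assigned.
    """

    labels: np.ndarray
    provenance: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.provenance = np.asarray(self.provenance, dtype=int)
        if self.labels.shape != self.provenance.shape:
            raise ValueError("labels and provenance must have equal length")

    def copy(self) -> "LabelState":
        return LabelState(self.labels.copy(), self.provenance.copy())


@dataclass
class LatentMatrix:
    """Latent codes for a set of cells, row order matching the source data."""

    Z: np.ndarray
    source: str = "unlabeled"  # "labeled" or "unlabeled"

    @property
    def n_cells(self) -> int:
        return self.Z.shape[0]


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def mse_loss(X: np.ndarray, X_hat: np.ndarray) -> float:
    """Reconstruction loss: mean over cells of the squared Euclidean error.

    The squared norm is summed over features and averaged over the M rows only.
    """
    X = np.asarray(X, float)
    X_hat = np.asarray(X_hat, float)
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_hat.shape}")
    diff = X - X_hat
    return float(np.sum(diff * diff) / X.shape[0])


def label_loss(Y_onehot: np.ndarray, Y_hat: np.ndarray) -> float:
    """Cross-entropy over labeled cells, normalized by the labeled count."""
    Y_onehot = np.asarray(Y_onehot, float)
    Y_hat = np.asarray(Y_hat, float)
    if Y_onehot.shape != Y_hat.shape:
        raise ValueError(f"class-count mismatch: {Y_onehot.shape} vs {Y_hat.shape}")
    probs = np.clip(Y_hat, _EPS, 1.0)
    return float(-(Y_onehot * np.log(probs)).sum() / Y_onehot.shape[0])


def loss_weights(s1: float, s2: float) -> Tuple[float, float]:
    """Loss weights under the uncertainty parameterization: exp(-s)."""
    return float(np.exp(-s1)), float(np.exp(-s2))


def combined_loss(l_mse: float, l_label: float, weights: Tuple[float, float]) -> float:
    """Reported total loss alpha*L_mse + beta*L_label (without the s1+s2
    regularizer that is part of the optimized objective only)."""
    alpha, beta = weights
    return float(alpha * l_mse + beta * l_label)


# ---------------------------------------------------------------------------
# Model and training
# ---------------------------------------------------------------------------

@dataclass
class SemiSupModel:
    """Trained encoder/decoder/predictor with learned loss weights."""

    encoder: MLP
    decoder: MLP
    predictor: Optional[MLP]
    s1: float
    s2: float
    n_features: int
    n_classes: int
    latent_dim: int
    predictor_input: str = "raw"
    loss_history: List[float] = field(default_factory=list)
    mse_history: List[float] = field(default_factory=list)

    @property
    def weights(self) -> Tuple[float, float]:
        alpha, beta = loss_weights(self.s1, self.s2)
        if self.predictor is None:
            beta = 0.0
        return alpha, beta

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Known-class probabilities from the predictor (rows on the simplex)."""
        if self.predictor is None:
            raise ValueError("model was trained without a predictor")
        inp = X if self.predictor_input == "raw" else self.encoder.forward(X)
        return softmax(self.predictor.forward(inp))


def train_semisup(
    split: SplitDataset,
    h: int = 32,
    epochs: int = 500,
    seed: int = 0,
    lr: float = 1e-3,
    use_predictor: bool = True,
    predictor_input: str = "raw",
    hidden_ae: int = 64,
    hidden_pred: int = 32,
    batch_size: Optional[int] = None,
) -> SemiSupModel:
    """Jointly train encoder, decoder and predictor on the split.

    The reconstruction term runs over all cells; the label term over
    LABELED_KNOWN cells only.  Training is full-batch up to 20k cells (else
    seeded mini-batches of 512) with Adam at ``lr`` for ``epochs`` epochs, and
    is repeatable for a fixed seed.

    With ``use_predictor=False`` the label-loss weight is frozen at zero and
    only the autoencoder is trained (ablation of the supervised term).
    """
    X = split.dataset.features
    n, d = X.shape
    K = split.n_known
    lab_mask = split.mask(Role.LABELED_KNOWN)
    lab_idx = np.flatnonzero(lab_mask)
    if use_predictor:
        for k in range(K):
            if not np.any(split.label[lab_idx] == k):
                raise ValueError(f"known class {split.known_classes[k]!r} has no labeled cells")

    rng = np.random.default_rng(seed)
    encoder = MLP([d, hidden_ae, h], rng, relu_after_last=True)
    decoder = MLP([h, hidden_ae, d], rng, relu_after_last=False)
    predictor = MLP([d, hidden_pred, hidden_pred, K], rng) if use_predictor else None

    Y = np.zeros((len(lab_idx), K))
    Y[np.arange(len(lab_idx)), split.label[lab_idx]] = 1.0

    params = encoder.params + decoder.params
    if predictor is not None:
        params = params + predictor.params
    s = np.zeros(2)  # [s1, s2]; alpha=exp(-s1), beta=exp(-s2)
    params = params + [s]
    opt = Adam(params, lr=lr)

    if batch_size is None:
        batch_size = n if n <= 20_000 else 512
    history: List[float] = []
    mse_hist: List[float] = []
    X_lab = X[lab_idx]

    for _ in range(epochs):
        order = np.arange(n) if batch_size >= n else rng.permutation(n)
        epoch_mse = 0.0
        epoch_ce = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            Xb = X[idx]
            m = len(idx)
            alpha, beta = np.exp(-s[0]), np.exp(-s[1])

            # autoencoder forward/backward
            Z = encoder.forward(Xb)
            X_hat = decoder.forward(Z)
            l_mse = mse_loss(Xb, X_hat)
            g_out = alpha * 2.0 * (X_hat - Xb) / m
            encoder.backward(decoder.backward(g_out))
            enc_grads = [g.copy() for g in encoder.grads]

            # predictor on the labeled cells (full labeled set each step)
            l_ce = 0.0
            if predictor is not None:
                inp = X_lab if predictor_input == "raw" else encoder.forward(X_lab)
                logits = predictor.forward(inp)
                probs = softmax(logits)
                l_ce = label_loss(Y, probs)
                d_inp = predictor.backward(beta * (probs - Y) / len(lab_idx))
                if predictor_input == "latent":
                    # classification gradient also shapes the encoder
                    encoder.backward(d_inp)
                    enc_grads = [a + b for a, b in zip(enc_grads, encoder.grads)]

            grads = enc_grads + decoder.grads
            if predictor is not None:
                grads = grads + predictor.grads
            gs = np.array([1.0 - alpha * l_mse,
                           (1.0 - beta * l_ce) if predictor is not None else 0.0])
            grads = grads + [gs]
            opt.step(grads)
            epoch_mse += l_mse * m
            epoch_ce = l_ce
        alpha, beta = np.exp(-s[0]), (np.exp(-s[1]) if predictor is not None else 0.0)
        mse_hist.append(epoch_mse / n)
        history.append(combined_loss(epoch_mse / n, epoch_ce, (alpha, beta)))

    return SemiSupModel(
        encoder=encoder,
        decoder=decoder,
        predictor=predictor,
        s1=float(s[0]),
        s2=float(s[1]) if predictor is not None else 0.0,
        n_features=d,
        n_classes=K,
        latent_dim=h,
        predictor_input=predictor_input,
        loss_history=history,
        mse_history=mse_hist,
    )


def encode(model: SemiSupModel, ds: Union[CellDataset, np.ndarray],
           source: str = "unlabeled") -> LatentMatrix:
    """Deterministic forward map of cells to latent codes, row order preserved."""
    X = ds.features if isinstance(ds, CellDataset) else np.asarray(ds, float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1] if X.ndim == 2 else X.shape} does not "
            f"match training dimension {model.n_features}"
        )
    return LatentMatrix(model.encoder.forward(X), source=source)


# ---------------------------------------------------------------------------
# One-class classifier bank and consensus labelling
# ---------------------------------------------------------------------------

@dataclass
class OCCBank:
    """One trained one-class SVM per known class, operating on latent codes."""

    classifiers: List[OneClassSVM]
    train_sizes: List[int]
    nu: float

    @property
    def K(self) -> int:
        return len(self.classifiers)

    def accepts(self, Z: np.ndarray) -> np.ndarray:
        """Boolean (n_cells, K) matrix: does classifier k accept each row?

        A row is accepted when it lies on or inside the decision boundary;
        the tiny negative slack absorbs solver round-off for boundary support
        vectors, whose decision value is exactly zero in theory.
        """
        if Z.shape[0] == 0:
            return np.zeros((0, self.K), dtype=bool)
        return np.stack(
            [clf.decision_function(Z) >= -1e-7 for clf in self.classifiers], axis=1
        )


def fit_occ_bank(Z_labeled: Union[LatentMatrix, np.ndarray], labels: np.ndarray,
                 K: int, nu: float = 0.05) -> OCCBank:
    """Fit K one-class SVMs (RBF kernel), classifier k on class-k codes only.

    ``nu`` bounds the fraction of genuine class members rejected as outliers
    (0.05 keeps the block's known-type miss rate within its ~10% design
    budget);
    the RBF bandwidth follows the feature-variance scaling rule (sklearn's
    ``gamma='scale'``) on each class's own codes.
    """
    Z = Z_labeled.Z if isinstance(Z_labeled, LatentMatrix) else np.asarray(Z_labeled, float)
    labels = np.asarray(labels, dtype=int)
    classifiers: List[OneClassSVM] = []
    sizes: List[int] = []
    for k in range(K):
        rows = Z[labels == k]
        if rows.shape[0] < 2:
            raise ValueError(f"class {k} has {rows.shape[0]} labeled latent rows; need >= 2")
        clf = OneClassSVM(kernel="rbf", nu=nu, gamma="scale", tol=1e-8)
        clf.fit(rows)
        classifiers.append(clf)
        sizes.append(rows.shape[0])
    return OCCBank(classifiers=classifiers, train_sizes=sizes, nu=nu)


def consensus_label(
    bank: OCCBank,
    Z_unlabeled: Union[LatentMatrix, np.ndarray],
    Z_labeled: Union[LatentMatrix, np.ndarray],
    labels: np.ndarray,
    N: int = 20,
) -> LabelState:
    """Label unlabeled cells by the three-case one-class consensus rule.

    Only known-class labels in ``[0, K)`` (or the UNLABELED sentinel) are ever
    emitted.  Ties in the neighbor vote are broken by the smallest mean
    distance to the tied class's neighbors, then by lowest class index.
    """
    Zu = Z_unlabeled.Z if isinstance(Z_unlabeled, LatentMatrix) else np.asarray(Z_unlabeled, float)
    Zl = Z_labeled.Z if isinstance(Z_labeled, LatentMatrix) else np.asarray(Z_labeled, float)
    labels = np.asarray(labels, dtype=int)
    if Zl.shape[0] == 0:
        raise ValueError("labeled latent set is empty")
    N_eff = min(N, Zl.shape[0])

    out_labels = np.full(Zu.shape[0], UNLABELED, dtype=int)
    out_prov = np.full(Zu.shape[0], int(Provenance.UNLABELED), dtype=int)
    if Zu.shape[0] == 0:
        return LabelState(out_labels, out_prov)

    accept = bank.accepts(Zu)
    nn = NearestNeighbors(n_neighbors=N_eff).fit(Zl)
    multi = np.flatnonzero(accept.sum(axis=1) >= 2)
    if len(multi):
        dist, nbr = nn.kneighbors(Zu[multi])

    single = accept.sum(axis=1) == 1
    out_labels[single] = np.argmax(accept[single], axis=1)
    out_prov[single] = int(Provenance.OCC_SINGLE)

    for row, i in enumerate(multi):
        acc = np.flatnonzero(accept[i])
        neigh_labels = labels[nbr[row]]
        neigh_dist = dist[row]
        sel = np.isin(neigh_labels, acc)
        votes_labels = neigh_labels[sel] if sel.any() else neigh_labels
        votes_dist = neigh_dist[sel] if sel.any() else neigh_dist
        counts = np.bincount(votes_labels, minlength=bank.K)
        best = counts.max()
        tied = np.flatnonzero(counts == best)
        if len(tied) > 1:
            mean_d = np.array([votes_dist[votes_labels == c].mean() for c in tied])
            tied = tied[np.flatnonzero(mean_d == mean_d.min())]
        out_labels[i] = int(tied[0])
        out_prov[i] = int(Provenance.OCC_CONSENSUS)
    return LabelState(out_labels, out_prov)
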