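"""End-to-end orchestration: prep -> semi-supervised -> unsupervised -> refine.

The pipeline takes an annotated expression matrix (or an already-constructed
split), re-discovers known cell types among the unlabeled cells, clusters the
residual cells into novel types, refines all labels by a nearest-neighbor
pass, and — when ground truth is available — reports the three discovery
accuracies.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import prep, refine_eval, semisup, unsup
from .prep import UNLABELED, CellDataset, Role, SplitDataset
from .semisup import LabelState, Provenance

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_replicates",
           "cv_select_hyperparameters"]

log = logging.getLogger("annogcd")

#: Hyperparameter values evaluated during model selection; values outside these
#: sets are permitted but logged as a warning.
_EVALUATED = {
    "n_components": {32, 64, 128},
    "latent_dim": {16, 32, 64},
    "consensus_n": {10, 20, 50},
    "refine_neighbors": {10, 20},
    "knn_k": {20, 50, 100},
}


@dataclass
class PipelineConfig:
    """All pipeline defaults in one place.

    Defaults follow the selected experimental configuration: 64 principal
    components, latent dimension 32, 500 training epochs for both the
    semi-supervised networks and the graph encoder, one-class SVM ``nu`` 0.05,
    consensus over N=20 latent neighbors, kNN-50 graph, mixture truncation at
    20 components with significance threshold t=0.05, and a final refinement
    over 10 neighbors.
    """

    n_components: int = 64
    latent_dim: int = 32
    epochs: int = 500
    nu: float = 0.05
    consensus_n: int = 20
    refine_neighbors: int = 10
    knn_k: int = 50
    dgi_dim: int = 32
    dgi_epochs: int = 500
    dpmm_max_components: int = 20
    dpmm_threshold: float = 0.05
    known_frac: float = 0.5
    labeled_frac: float = 0.7
    min_count: int = 100
    lr: float = 1e-3
    seed: int = 0
    replicates: int = 1
    no_predictor: bool = False
    no_graph_embeddings: bool = False
    mutual_knn: bool = True

    def validate(self) -> None:
        for name, allowed in _EVALUATED.items():
            value = getattr(self, name)
            if value not in allowed:
                log.warning("%s=%r is outside the evaluated range %s", name, value, sorted(allowed))

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class PipelineResult:
    """Labels, provenance and (when truth is available) accuracies."""

    split: SplitDataset
    state: LabelState
    report: Optional[refine_eval.EvaluationReport]
    n_novel_discovered: int
    dpmm_weights: Optional[np.ndarray] = None
    loss_history: List[float] = field(default_factory=list)


def _derive_seeds(seed: int, n: int) -> List[int]:
    ss = np.random.SeedSequence(int(seed) % (2**31))
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


class StageError(RuntimeError):
    """An error raised by a named pipeline stage."""


def _stage(name: str):
    import contextlib

    @contextlib.contextmanager
    def ctx():
        try:
            yield
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    return ctx()


def run_pipeline(cfg: PipelineConfig, data: Union[CellDataset, SplitDataset]) -> PipelineResult:
    """Run the full discovery pipeline.

    A :class:`CellDataset` is first prepared (rare-type filtering when a type
    annotation is present and ``cfg.min_count > 0``, PCA to
    ``cfg.n_components``, seeded known/novel split); a :class:`SplitDataset`
    is consumed as-is, assuming features were already reduced.
    """
    cfg.validate()
    seeds = _derive_seeds(cfg.seed, 4)

    if isinstance(data, CellDataset):
        with _stage("prep"):
            ds = data
            if ds.true_type is not None and cfg.min_count > 0:
                ds = prep.filter_rare_types(ds, cfg.min_count)
            if ds.n_features > cfg.n_components:
                ds = prep.reduce_pca(ds, cfg.n_components)
            split = prep.make_split(ds, cfg.known_frac, cfg.labeled_frac, seed=seeds[0])
    else:
        split = data

    X = split.dataset.features
    K = split.n_known
    lab_mask = split.mask(Role.LABELED_KNOWN)
    pool_mask = split.unlabeled_mask
    log.info("pipeline: %d cells, %d known classes, %d labeled, %d unlabeled",
             split.dataset.n_cells, K, lab_mask.sum(), pool_mask.sum())

    with _stage("semisup"):
        model = semisup.train_semisup(
            split,
            h=cfg.latent_dim,
            epochs=cfg.epochs,
            seed=seeds[1],
            lr=cfg.lr,
            use_predictor=not cfg.no_predictor,
        )
        if cfg.no_predictor:
            log.info("ablation: predictor disabled, label loss weight frozen at 0")
        Z_all = semisup.encode(model, X).Z
        lab_labels = split.label[lab_mask]
        bank = semisup.fit_occ_bank(Z_all[lab_mask], lab_labels, K, nu=cfg.nu)
        pool_state = semisup.consensus_label(
            bank, Z_all[pool_mask], Z_all[lab_mask], lab_labels, N=cfg.consensus_n
        )

    labels = np.full(split.dataset.n_cells, UNLABELED, dtype=int)
    prov = np.full(split.dataset.n_cells, int(Provenance.UNLABELED), dtype=int)
    labels[lab_mask] = split.label[lab_mask]
    prov[lab_mask] = int(Provenance.GIVEN)
    labels[pool_mask] = pool_state.labels
    prov[pool_mask] = pool_state.provenance

    residual = np.flatnonzero((labels == UNLABELED))
    n_novel_discovered = 0
    dpmm_weights = None
    if len(residual) == 1:
        labels[residual] = K
        prov[residual] = int(Provenance.NOVEL_CLUSTER)
        n_novel_discovered = 1
    elif len(residual) >= 2:
        with _stage("unsup"):
            feats_res = X[residual]
            if cfg.no_graph_embeddings:
                log.info("ablation: clustering on PCA features, no graph embeddings")
                emb = feats_res
            else:
                k = min(cfg.knn_k, len(residual) - 1)
                if k < cfg.knn_k:
                    log.warning("residual set smaller than knn_k; using k=%d", k)
                graph = unsup.build_knn_graph(feats_res, k=k, mutual=cfg.mutual_knn)
                emb = unsup.l2_normalize(
                    unsup.train_dgi(graph, dim=cfg.dgi_dim, epochs=cfg.dgi_epochs,
                                    seed=seeds[2])
                )
            max_comp = min(cfg.dpmm_max_components, len(residual))
            fit = unsup.fit_dpmm(emb, max_components=max_comp, seed=seeds[3])
            frag, comp_map = unsup.select_novel_clusters(fit, t=cfg.dpmm_threshold, K=K)
            labels[residual] = frag.labels
            prov[residual] = frag.provenance
            n_novel_discovered = len(comp_map)
            dpmm_weights = fit.weights

    with _stage("refine"):
        pool_pre = LabelState(labels[pool_mask], prov[pool_mask])
        pool_post = refine_eval.refine_labels(X[pool_mask], pool_pre,
                                              n_neighbors=cfg.refine_neighbors)
        labels[pool_mask] = pool_post.labels
        prov[pool_mask] = pool_post.provenance

    state = LabelState(labels, prov)
    report = None
    if split.dataset.true_type is not None:
        with _stage("evaluate"):
            report = evaluate(split, state, n_novel_discovered)
    return PipelineResult(split=split, state=state, report=report,
                          n_novel_discovered=n_novel_discovered,
                          dpmm_weights=dpmm_weights,
                          loss_history=model.loss_history)


def evaluate(split: SplitDataset, state: LabelState,
             n_novel_discovered: int = 0) -> refine_eval.EvaluationReport:
    """Compute the three discovery accuracies for a full labeling."""
    truth = split.true_label_indices()
    K = split.n_known
    known_mask = split.mask(Role.UNLABELED_KNOWN)
    novel_mask = split.mask(Role.UNLABELED_NOVEL)
    pool_mask = split.unlabeled_mask
    known_acc = (refine_eval.known_accuracy(state, truth, known_mask)
                 if known_mask.sum() else float("nan"))
    if novel_mask.sum():
        novel_acc, mapping = refine_eval.novel_accuracy(state, truth, novel_mask, K=K)
    else:
        novel_acc, mapping = float("nan"), {}
    pool_state = LabelState(state.labels[pool_mask], state.provenance[pool_mask])
    all_acc = refine_eval.overall_accuracy(pool_state, truth[pool_mask], K=K)
    return refine_eval.EvaluationReport(
        known_acc=known_acc,
        novel_acc=novel_acc,
        all_acc=all_acc,
        n_known_eval=int(known_mask.sum()),
        n_novel_eval=int(novel_mask.sum()),
        mapping=mapping,
        n_novel_discovered=n_novel_discovered,
    )


def run_replicates(cfg: PipelineConfig, data: Union[CellDataset, SplitDataset],
                   replicates: Optional[int] = None) -> Dict[str, Tuple[float, float]]:
    """Run the pipeline over seed replicates; mean and sd per metric."""
    reps = cfg.replicates if replicates is None else replicates
    rows = []
    for r in range(reps):
        res = run_pipeline(cfg.replace(seed=cfg.seed + r), data)
        if res.report is None:
            raise ValueError("replicate evaluation requires a type annotation")
        rows.append((res.report.known_acc, res.report.novel_acc, res.report.all_acc))
    arr = np.array(rows, dtype=float)
    names = ["known_acc", "novel_acc", "all_acc"]
    return {n: (float(np.nanmean(arr[:, i])), float(np.nanstd(arr[:, i])))
            for i, n in enumerate(names)}


# ---------------------------------------------------------------------------
# Cross-validation hyperparameter selection on known classes only
# ---------------------------------------------------------------------------

def _hide_classes(split: SplitDataset, hidden: Sequence[str]) -> SplitDataset:
    """Re-split with the given known classes hidden (made pseudo-novel)."""
    hidden = list(hidden)
    new_known = [c for c in split.known_classes if c not in hidden]
    new_novel = list(split.novel_classes) + hidden
    tt = split.dataset.true_type.astype(str)
    role = split.role.copy()
    role[np.isin(tt, hidden)] = int(Role.UNLABELED_NOVEL)
    return SplitDataset(dataset=split.dataset, known_classes=new_known,
                        novel_classes=new_novel, role=role)


def cv_select_hyperparameters(
    split: SplitDataset,
    grid: Sequence[dict],
    folds: int = 3,
    seed: int = 0,
    base: Optional[PipelineConfig] = None,
) -> PipelineConfig:
    """Select hyperparameters without touching any truly-unlabeled label.

    Per fold, about half of the known classes are hidden — their labels are
    withdrawn and they become pseudo-novel — the pipeline runs on the modified
    split, and the candidate configuration is scored by Hungarian-matched
    clustering accuracy on the hidden-class cells (whose labels are available).
    Scores are averaged across folds; the best grid point wins, ties going to
    the earlier entry.
    """
    K = split.n_known
    if K < 4:
        raise ValueError(f"cross-validation needs >= 4 known classes, got {K}")
    if len(grid) == 0:
        raise ValueError("empty hyperparameter grid")
    base = base or PipelineConfig()
    rng = np.random.default_rng(seed)
    n_hide = K // 2
    fold_hidden = [list(rng.choice(split.known_classes, size=n_hide, replace=False))
                   for _ in range(folds)]

    scores = np.zeros(len(grid))
    for gi, overrides in enumerate(grid):
        cfg = base.replace(**overrides)
        fold_scores = []
        for fi, hidden in enumerate(fold_hidden):
            fold_split = _hide_classes(split, hidden)
            res = run_pipeline(cfg.replace(seed=seed + fi), fold_split)
            truth = fold_split.true_label_indices()
            pool = fold_split.unlabeled_mask
            tt = fold_split.dataset.true_type.astype(str)
            hid_mask = (np.isin(tt, hidden) & pool)[pool]
            pool_state = LabelState(res.state.labels[pool], res.state.provenance[pool])
            acc, _ = refine_eval.novel_accuracy(pool_state, truth[pool], hid_mask,
                                                K=fold_split.n_known)
            fold_scores.append(acc)
        scores[gi] = float(np.mean(fold_scores))
        log.info("cv grid point %d: %s -> %.4f", gi, overrides, scores[gi])
    best = int(np.argmax(scores))  # argmax takes the first maximum: earliest grid entry
    return base.replace(**grid[best])
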