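"""Synthetic single-cell-like data with known ground truth.

Generates a mixture of cell types as isotropic Gaussian blobs in gene space
with controllable type count, abundance imbalance (targeted Gini index via
geometric-decay proportions), and between-type separation (ratio of minimum
centroid distance to within-type standard deviation).  Real scRNA-seq
artifacts — dropout, batch effects, library-size variation — are deliberately
not modeled; the pipeline consumes PCA features, which are real-valued, so
Gaussian blobs exercise every stage with a known Bayes structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .prep import CellDataset, gini_index

__all__ = ["SynthConfig", "imbalance_proportions", "simulate_cells", "write_csv", "write_mtx"]


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset.

    ``separation`` is the minimum pairwise centroid distance in units of the
    within-type standard deviation; types become linearly separable with high
    probability from about 6 upward.  ``min_cells_per_type`` guarantees every
    configured type is actually realized with enough cells to be a type at all
    (the deficit is taken from the most abundant type), mirroring the fact that
    annotated atlases only retain types above a minimum population.
    """

    n_types: int = 12
    n_cells: int = 3000
    n_genes: int = 200
    separation: float = 8.0
    gini_target: float = 0.8
    seed: int = 0
    nonnegative: bool = False
    min_cells_per_type: int = 20

    def __post_init__(self) -> None:
        if self.n_types < 2:
            raise ValueError("need at least two types")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if not (0.0 <= self.gini_target <= 0.95):
            raise ValueError("gini_target must lie in [0, 0.95]")
        if self.n_cells < self.n_types:
            raise ValueError("need at least one cell per type")


def imbalance_proportions(n_types: int, gini_target: float) -> np.ndarray:
    """Type proportions with geometric decay hitting a target Gini index.

    Solves ``p_i ∝ r**i`` for the decay ``r`` by bisection so that
    ``gini_index(p)`` is within 1e-3 of the target.  The attainable range is
    ``[0, (n_types-1)/n_types)``.
    """
    max_gini = (n_types - 1) / n_types
    if not (0.0 <= gini_target < max_gini):
        raise ValueError(
            f"gini_target={gini_target} unattainable for {n_types} types "
            f"(must lie in [0, {max_gini:.4f}))"
        )
    i = np.arange(n_types)
    if gini_target == 0.0:
        return np.full(n_types, 1.0 / n_types)

    def gini_of(r: float) -> float:
        p = r ** i
        return gini_index(p / p.sum())

    lo, hi = 1e-9, 1.0  # gini_of is decreasing in r
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if gini_of(mid) > gini_target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-15:
            break
    r = 0.5 * (lo + hi)
    if abs(gini_of(r) - gini_target) > 1e-3:
        raise ValueError(f"bisection failed to reach gini_target={gini_target}")
    p = r ** i
    return p / p.sum()


def simulate_cells(cfg: SynthConfig) -> CellDataset:
    """Draw the synthetic dataset described by ``cfg``.

    Type centroids are seeded isotropic Gaussian directions rescaled so the
    minimum pairwise distance equals ``separation`` (within-type sd is 1);
    cells are centroid + isotropic unit noise; per-type counts are multinomial
    from :func:`imbalance_proportions`, then clamped below at
    ``min_cells_per_type``.
    """
    rng = np.random.default_rng(cfg.seed)
    p = imbalance_proportions(cfg.n_types, cfg.gini_target)
    counts = rng.multinomial(cfg.n_cells, p)

    # clamp: every type keeps a viable population, deficit from the largest
    floor = min(cfg.min_cells_per_type, cfg.n_cells // cfg.n_types)
    counts = np.maximum(counts, floor)
    excess = int(counts.sum() - cfg.n_cells)
    while excess > 0:
        j = int(np.argmax(counts))
        take = min(excess, int(counts[j]) - floor)
        counts[j] -= take
        excess -= take
    assert counts.sum() == cfg.n_cells

    centroids = rng.normal(size=(cfg.n_types, cfg.n_genes))
    if cfg.separation > 0 and cfg.n_types > 1:
        diff = centroids[:, None, :] - centroids[None, :, :]
        dists = np.sqrt((diff * diff).sum(axis=2))
        min_dist = dists[np.triu_indices(cfg.n_types, k=1)].min()
        centroids *= cfg.separation / min_dist
    else:
        centroids[:] = 0.0

    slots = np.repeat(np.arange(cfg.n_types), counts)
    slots = slots[rng.permutation(cfg.n_cells)]  # interleave types in row order
    features = centroids[slots] + rng.normal(size=(cfg.n_cells, cfg.n_genes))
    types = np.array([f"type{t:02d}" for t in slots], dtype=object)
    if cfg.nonnegative:
        features = np.log1p(np.exp(features))  # softplus keeps expression-like positivity
    cell_ids = np.array([f"cell{i:05d}" for i in range(cfg.n_cells)], dtype=object)
    return CellDataset(features, cell_ids, types)


def write_csv(ds: CellDataset, path, type_column: str = "cell_type") -> None:
    """Write the dense CSV dialect accepted by :func:`annogcd.prep.load_expression`."""
    import pandas as pd

    df = pd.DataFrame(
        ds.features,
        index=pd.Index(ds.cell_ids, name="cell_id"),
        columns=[f"gene{j}" for j in range(ds.n_features)],
    )
    if ds.true_type is not None:
        df[type_column] = ds.true_type
    df.to_csv(path)


def write_mtx(ds: CellDataset, folder) -> None:
    """Write MatrixMarket triplets with barcodes.tsv / features.tsv sidecars."""
    import pandas as pd
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    mmwrite(str(folder / "matrix.mtx"), csr_matrix(ds.features))
    bc = pd.DataFrame({"barcode": ds.cell_ids})
    if ds.true_type is not None:
        bc["cell_type"] = ds.true_type
    bc.to_csv(folder / "barcodes.tsv", sep="\t", header=False, index=False)
    pd.DataFrame({"gene": [f"gene{j}" for j in range(ds.n_features)]}).to_csv(
        folder / "features.tsv", sep="\t", header=False, index=False
    )
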