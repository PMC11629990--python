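"""Data ingestion, rare-type filtering, imbalance quantification, PCA and split
construction.

The generalized-category-discovery protocol implemented downstream starts from a
cells x features matrix with a per-cell type annotation.  The annotation is used
here only to *construct* the experimental split (which types are "known", which
cells are labeled) and later to evaluate; no pipeline stage reads the true type
of an unlabeled cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "UNLABELED",
    "Role",
    "CellDataset",
    "SplitDataset",
    "load_expression",
    "filter_rare_types",
    "gini_index",
    "reduce_pca",
    "make_split",
    "write_split_manifest",
]

#: Sentinel label for a cell that currently carries no class assignment.
UNLABELED: int = -1


class Role(IntEnum):
    """Role of a cell in the known/novel discovery protocol."""

    LABELED_KNOWN = 0
    UNLABELED_KNOWN = 1
    UNLABELED_NOVEL = 2


@dataclass
class CellDataset:
    """A cells x features matrix with optional per-cell type annotation.

    Parameters
    ----------
    features
        Dense ``(n_cells, n_features)`` float array; no missing values.
    cell_ids
        Unique string identifier per cell.
    true_type
        Categorical type name per cell, or ``None`` for pure inference input.
    """

    features: np.ndarray
    cell_ids: np.ndarray
    true_type: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain missing or non-finite values")
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if len(self.cell_ids) != self.features.shape[0]:
            raise ValueError("cell_ids length does not match number of cells")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids are not unique")
        if self.true_type is not None:
            self.true_type = np.asarray(self.true_type, dtype=object)
            if len(self.true_type) != self.features.shape[0]:
                raise ValueError("true_type length does not match number of cells")

    @property
    def n_cells(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def type_counts(self) -> dict:
        """Number of cells per annotated type (requires ``true_type``)."""
        if self.true_type is None:
            raise ValueError("dataset has no type annotation")
        types, counts = np.unique(self.true_type.astype(str), return_counts=True)
        return dict(zip(types.tolist(), counts.tolist()))

    def subset(self, mask: np.ndarray) -> "CellDataset":
        return CellDataset(
            features=self.features[mask],
            cell_ids=self.cell_ids[mask],
            true_type=None if self.true_type is None else self.true_type[mask],
        )


@dataclass
class SplitDataset:
    """A :class:`CellDataset` plus the known/novel, labeled/unlabeled split.

    ``known_classes`` is the ordered list of K known type names; ``label`` holds
    the class index (position in ``known_classes``) for LABELED_KNOWN cells and
    the :data:`UNLABELED` sentinel for every other cell.
    """

    dataset: CellDataset
    known_classes: list
    novel_classes: list
    role: np.ndarray
    label: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if set(self.known_classes) & set(self.novel_classes):
            raise ValueError("known and novel classes must be non-intersecting")
        if len(self.known_classes) < 1:
            raise ValueError("at least one known class is required")
        self.role = np.asarray(self.role)
        if len(self.role) != self.dataset.n_cells:
            raise ValueError("role length does not match number of cells")
        if self.label is None:
            idx = {c: i for i, c in enumerate(self.known_classes)}
            lab = np.full(self.dataset.n_cells, UNLABELED, dtype=int)
            mask = self.role == Role.LABELED_KNOWN
            lab[mask] = [idx[t] for t in self.dataset.true_type[mask]]
            self.label = lab
        self.label = np.asarray(self.label, dtype=int)
        self._check_roles()

    def _check_roles(self) -> None:
        tt = self.dataset.true_type
        if tt is None:
            return
        known = set(self.known_classes)
        novel = set(self.novel_classes)
        for r, required in (
            (Role.LABELED_KNOWN, known),
            (Role.UNLABELED_KNOWN, known),
            (Role.UNLABELED_NOVEL, novel),
        ):
            bad = [t for t in tt[self.role == r] if t not in required]
            if bad:
                raise ValueError(f"cell with role {r.name} has type outside its class set: {bad[0]!r}")

    @property
    def n_known(self) -> int:
        return len(self.known_classes)

    def mask(self, role: Role) -> np.ndarray:
        return self.role == int(role)

    @property
    def unlabeled_mask(self) -> np.ndarray:
        """All cells of the unlabeled pool (the pipeline's inference targets)."""
        return self.role != int(Role.LABELED_KNOWN)

    def true_label_indices(self) -> np.ndarray:
        """Ground-truth integer labels over the combined label set.

        Known classes map to 0..K-1 by their order in ``known_classes``; novel
        classes map to K..K+G-1 by their order in ``novel_classes``.
        """
        idx = {c: i for i, c in enumerate(self.known_classes)}
        idx.update({c: self.n_known + i for i, c in enumerate(self.novel_classes)})
        return np.array([idx[t] for t in self.dataset.true_type], dtype=int)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_dense_table(path: Path, type_column: Optional[str]) -> CellDataset:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse {path}: {exc}") from exc
    true_type = None
    if type_column is not None:
        if type_column not in df.columns:
            raise ValueError(f"type column {type_column!r} not found in {path}")
        true_type = df[type_column].astype(str).to_numpy()
        df = df.drop(columns=[type_column])
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        bad = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
        raise ValueError(f"non-numeric expression entries in columns {list(bad)}")
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(f"missing expression value at cell {df.index[r]!r}, gene {df.columns[c]!r}")
    return CellDataset(values.astype(float), df.index.astype(str).to_numpy(), true_type)


def _read_mtx(path: Path, type_column: Optional[str]) -> CellDataset:
    from scipy.io import mmread

    try:
        mat = mmread(path)
    except Exception as exc:
        raise ValueError(f"could not parse MatrixMarket file {path}: {exc}") from exc
    dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
    folder = path.parent
    barcodes = folder / "barcodes.tsv"
    if barcodes.exists():
        bc = pd.read_csv(barcodes, sep="\t", header=None)
        cell_ids = bc.iloc[:, 0].astype(str).to_numpy()
        true_type = None
        if type_column is not None:
            cols = list(bc.columns)
            if type_column.isdigit() and int(type_column) < bc.shape[1]:
                true_type = bc.iloc[:, int(type_column)].astype(str).to_numpy()
            elif len(cols) > 1:
                true_type = bc.iloc[:, 1].astype(str).to_numpy()
            else:
                raise ValueError("barcodes.tsv has no annotation column")
    else:
        cell_ids = np.array([f"cell{i}" for i in range(dense.shape[0])], dtype=object)
        true_type = None
    if len(cell_ids) != dense.shape[0]:
        raise ValueError(
            f"barcodes.tsv has {len(cell_ids)} rows but matrix has {dense.shape[0]} cells"
        )
    return CellDataset(dense, cell_ids, true_type)


def _read_h5ad(path: Path, type_column: Optional[str]) -> CellDataset:
    import anndata as ad

    adata = ad.read_h5ad(path)
    X = adata.X
    if hasattr(X, "todense"):
        X = np.asarray(X.todense())
    true_type = None
    if type_column is not None:
        if type_column not in adata.obs.columns:
            raise ValueError(f"type column {type_column!r} not in .obs")
        true_type = adata.obs[type_column].astype(str).to_numpy()
    return CellDataset(np.asarray(X, dtype=float), adata.obs_names.to_numpy(), true_type)


def load_expression(path, format: str = "csv", type_column: Optional[str] = None) -> CellDataset:
    """Read an expression or feature matrix into a :class:`CellDataset`.

    Supported dialects: ``csv`` (dense cells x genes table, first column the
    cell id, optionally a categorical type column), ``mtx`` (MatrixMarket
    triplets, cells on rows, with sidecar ``barcodes.tsv``/``features.tsv``),
    and ``h5-annotated`` (AnnData ``.h5ad`` with the type column in ``.obs``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    readers = {"csv": _read_dense_table, "tsv": _read_dense_table,
               "mtx": _read_mtx, "h5-annotated": _read_h5ad, "h5ad": _read_h5ad}
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(readers)}")
    return readers[format](path, type_column)


def write_split_manifest(split: SplitDataset, path) -> None:
    """Write the split as a TSV with columns cell_id, true_type, role, label."""
    tt = split.dataset.true_type
    df = pd.DataFrame(
        {
            "cell_id": split.dataset.cell_ids,
            "true_type": ["" for _ in split.dataset.cell_ids] if tt is None else tt,
            "role": [Role(r).name for r in split.role],
            "label": split.label,
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def filter_rare_types(ds: CellDataset, min_count: int = 100) -> CellDataset:
    """Drop cells whose annotated type occurs fewer than ``min_count`` times.

    Mirrors the standard practice of removing cell types too rare to support
    either training or evaluation. Cell order is preserved; idempotent for a
    fixed threshold.
    """
    if ds.true_type is None:
        raise ValueError("filter_rare_types requires a type annotation")
    counts = ds.type_counts()
    keep_types = {t for t, c in counts.items() if c >= min_count}
    if not keep_types:
        raise ValueError(
            f"no cell type reaches min_count={min_count}; most abundant has "
            f"{max(counts.values())} cells"
        )
    mask = np.array([t in keep_types for t in ds.true_type])
    return ds.subset(mask)


def gini_index(class_counts: Sequence[float]) -> float:
    """Gini index of the distribution of cells across types.

    Uses the mean-absolute-difference population form over the m per-type
    counts c:  sum_ij |c_i - c_j| / (2 m^2 mean(c)).  0 for perfectly balanced
    types; bounded above by (m-1)/m when a single type holds all cells.
    Scale-invariant, so counts and proportions give the same value.
    """
    c = np.asarray(class_counts, dtype=float)
    if c.ndim != 1 or len(c) == 0:
        raise ValueError("class_counts must be a non-empty 1-D vector")
    if np.any(c < 0):
        raise ValueError("class counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("all class counts are zero")
    m = len(c)
    mad = np.abs(c[:, None] - c[None, :]).sum()
    return float(mad / (2.0 * m * m * c.mean()))


def reduce_pca(ds: CellDataset, n_components: int = 64) -> CellDataset:
    """Replace features by scores on the top principal axes.

    Fitted on all cells (labeled and unlabeled together), mean-centering only.
    Explained variance of the returned columns is non-increasing.
    """
    if n_components > min(ds.n_cells, ds.n_features):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_cells, n_features)="
            f"{min(ds.n_cells, ds.n_features)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(ds.features)
    return CellDataset(scores, ds.cell_ids, ds.true_type)


def make_split(
    ds: CellDataset,
    known_frac: float = 0.5,
    labeled_frac: float = 0.7,
    seed: int = 0,
) -> SplitDataset:
    """Construct the known/novel and labeled/unlabeled split.

    ``ceil(known_frac * n_types)`` types are drawn (seeded, without
    replacement) as known; within each known type, ``round(labeled_frac * n)``
    of its cells are flagged LABELED_KNOWN (per-class stratified, seeded) and
    the rest UNLABELED_KNOWN.  All cells of the remaining types are
    UNLABELED_NOVEL.
    """
    if ds.true_type is None:
        raise ValueError("make_split requires a type annotation")
    if not (0.0 < known_frac <= 1.0) or not (0.0 < labeled_frac <= 1.0):
        raise ValueError("known_frac and labeled_frac must lie in (0, 1]")
    types = sorted({str(t) for t in ds.true_type})
    if len(types) < 2:
        raise ValueError("need at least two distinct types to split")
    rng = np.random.default_rng(seed)
    n_known = math.ceil(known_frac * len(types))
    known = [str(t) for t in rng.choice(types, size=n_known, replace=False)]
    novel = [t for t in types if t not in known]

    role = np.full(ds.n_cells, int(Role.UNLABELED_NOVEL), dtype=int)
    tt = ds.true_type.astype(str)
    for t in known:
        idx = np.flatnonzero(tt == t)
        n_lab = int(math.floor(labeled_frac * len(idx) + 0.5))
        lab_idx = rng.choice(idx, size=n_lab, replace=False)
        role[idx] = int(Role.UNLABELED_KNOWN)
        role[lab_idx] = int(Role.LABELED_KNOWN)
    return SplitDataset(dataset=ds, known_classes=known, novel_classes=novel, role=role)
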