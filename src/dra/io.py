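"""Count-matrix I/O and preprocessing.

Reads cells × genes count matrices from MatrixMarket triplets or dense
CSV/TSV, selects the highest-variance genes, applies the log2(1 + C)
transform, and produces seeded train/test splits. Cells are rows and genes
are columns everywhere in this package.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "CountMatrix",
    "ProcessedMatrix",
    "SplitIndices",
    "LabelVector",
    "read_counts",
    "write_counts",
    "read_labels",
    "write_labels",
    "select_top_variance_genes",
    "log_transform",
    "split_train_test",
]


def _check_unique(ids, axis_name):
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for i in ids:
            if i in seen:
                dup = i
                break
            seen.add(i)
        raise ValueError(f"duplicate {axis_name} id: {dup!r}")


@dataclass
class CountMatrix:
    """Raw cells × genes nonnegative integer expression counts."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    #: indices of these genes in the matrix they were selected from
    #: (None means no selection happened)
    selected_indices: list[int] | None = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("count matrix must be 2-dimensional")
        bad = ~np.isfinite(self.values.astype(np.float64))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(f"non-finite count at cell {i}, gene {j}")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(f"negative count at cell {i}, gene {j}: {self.values[i, j]}")
        if not np.all(np.equal(np.mod(self.values, 1), 0)):
            frac = np.mod(self.values.astype(np.float64), 1) != 0
            i, j = np.argwhere(frac)[0]
            raise ValueError(f"non-integer count at cell {i}, gene {j}: {self.values[i, j]}")
        self.values = self.values.astype(np.int64)
        m, n = self.values.shape
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.cell_ids) != m:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {m} rows")
        if len(self.gene_ids) != n:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n} columns")
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class ProcessedMatrix:
    """log2(1 + C)-transformed expression values with selection metadata."""

    values: np.ndarray
    selected_gene_indices: list[int]
    source_gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if (self.values < 0).any():
            raise ValueError("processed values must be nonnegative")
        if len(self.source_gene_ids) != self.values.shape[1]:
            raise ValueError("gene id count does not match column count")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class SplitIndices:
    """A disjoint train/test partition of cell indices."""

    train: list[int]
    test: list[int]
    seed: int

    def __post_init__(self):
        tr, te = set(self.train), set(self.test)
        if tr & te:
            raise ValueError("train and test indices overlap")
        n = len(self.train) + len(self.test)
        if (tr | te) != set(range(n)):
            raise ValueError("train ∪ test must cover 0..M−1 exactly")


@dataclass
class LabelVector:
    """Per-cell categorical labels (cell types or cluster assignments)."""

    labels: list

    def __post_init__(self):
        self.labels = list(self.labels)

    def __len__(self):
        return len(self.labels)

    def __getitem__(self, i):
        return self.labels[i]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels)

    def subset(self, idx) -> "LabelVector":
        return LabelVector([self.labels[i] for i in idx])

    def n_classes(self) -> int:
        return len(set(self.labels))


# --------------------------------------------------------------------- I/O
def _companion_paths(mtx_path: str) -> tuple[str, str]:
    stem = mtx_path[:-4] if mtx_path.endswith(".mtx") else mtx_path
    return stem + ".cells.txt", stem + ".genes.txt"


def read_counts(path: str, format: str | None = None) -> CountMatrix:
    """Read a cells × genes count matrix.

    ``mtx`` expects a MatrixMarket coordinate file plus companion
    ``<stem>.cells.txt`` / ``<stem>.genes.txt`` id files (one id per line);
    dense ``csv``/``tsv`` expect a header row of gene ids and a first column
    of cell ids.
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        format = ext if ext in ("mtx", "csv", "tsv") else "csv"
    if format not in ("mtx", "csv", "tsv"):
        raise ValueError(f"unsupported format: {format}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)

    if format == "mtx":
        cells_path, genes_path = _companion_paths(path)
        for p in (cells_path, genes_path):
            if not os.path.exists(p):
                raise FileNotFoundError(f"companion id file not found: {p}")
        mat = spio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        cell_ids = [ln.strip() for ln in open(cells_path) if ln.strip()]
        gene_ids = [ln.strip() for ln in open(genes_path) if ln.strip()]
        return CountMatrix(np.asarray(mat), cell_ids, gene_ids)

    sep = "," if format == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return CountMatrix(df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns])


def write_counts(counts: CountMatrix, path: str, format: str | None = None) -> None:
    """Write a count matrix in the dialect :func:`read_counts` reads."""
    if format is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        format = ext if ext in ("mtx", "csv", "tsv") else "csv"
    if format == "mtx":
        cells_path, genes_path = _companion_paths(path)
        spio.mmwrite(path, sparse.coo_matrix(counts.values), field="integer")
        with open(cells_path, "w") as fh:
            fh.write("\n".join(counts.cell_ids) + "\n")
        with open(genes_path, "w") as fh:
            fh.write("\n".join(counts.gene_ids) + "\n")
        return
    sep = "," if format == "csv" else "\t"
    df = pd.DataFrame(counts.values, index=counts.cell_ids, columns=counts.gene_ids)
    df.to_csv(path, sep=sep)


def read_labels(path: str) -> LabelVector:
    """Read a single-column CSV of per-cell labels (no header)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        labels = [ln.strip() for ln in fh if ln.strip() != ""]
    return LabelVector(labels)


def write_labels(labels: LabelVector, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(str(l) for l in labels.labels) + "\n")


# ----------------------------------------------------------- preprocessing
def select_top_variance_genes(counts: CountMatrix, n_genes: int = 720) -> CountMatrix:
    """Restrict to the ``n_genes`` genes of largest across-cell count variance.

    Variance is the population variance of raw counts; genes are returned in
    descending-variance order with ties broken by the lower original index.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if n_genes > counts.n_genes:
        raise ValueError(f"n_genes={n_genes} exceeds available genes ({counts.n_genes})")
    var = counts.values.astype(np.float64).var(axis=0)  # population (ddof=0)
    order = np.argsort(-var, kind="stable")[:n_genes]
    sel = [int(i) for i in order]
    return CountMatrix(
        counts.values[:, sel],
        counts.cell_ids,
        [counts.gene_ids[i] for i in sel],
        selected_indices=sel,
    )


def log_transform(counts: CountMatrix) -> ProcessedMatrix:
    """Map each count c to log2(1 + c), carrying selection metadata through."""
    idx = counts.selected_indices
    if idx is None:
        idx = list(range(counts.n_genes))
    return ProcessedMatrix(
        np.log2(1.0 + counts.values.astype(np.float64)),
        selected_gene_indices=idx,
        source_gene_ids=list(counts.gene_ids),
        cell_ids=list(counts.cell_ids),
    )


def split_train_test(n_cells: int, train_fraction: float = 0.8, seed: int = 0) -> SplitIndices:
    """Seeded uniformly-random partition; |train| = round-half-up(f·M)."""
    if n_cells < 2:
        raise ValueError("need at least 2 cells to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n_train = int(np.floor(train_fraction * n_cells + 0.5))
    n_train = min(max(n_train, 1), n_cells - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_cells)
    return SplitIndices(
        train=[int(i) for i in perm[:n_train]],
        test=[int(i) for i in perm[n_train:]],
        seed=seed,
    )
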