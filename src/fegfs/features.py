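"""Expression preprocessing and cosine-kernel KPCA feature extraction.

Preprocessing removes noise genes (expressed in too few cells; the
threshold scales with the cell count as 3 x max(1, floor(0.01 * n_cells)))
and log-transforms counts as log10(x + 1).

Each functional gene set selects a cells x set-genes submatrix; kernel PCA
with the cosine kernel reduces it, retaining enough leading components to
cover a retention ratio of the positive kernel-eigenvalue mass (40/60/80%
depending on dataset size).  Per-set projections are concatenated
column-wise into the feature matrix that cell clustering consumes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.linalg

from .repetition import FunctionalGeneSet

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """A cells x genes expression matrix with ordered labels."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        for label, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {label} identifiers")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class FeatureMatrix:
    """Cells x concatenated-KPCA-components matrix with block provenance."""

    values: np.ndarray
    cell_ids: list[str]
    block_index: dict[str, tuple[int, int]] = field(default_factory=dict)


def read_expression(path: str | Path, fmt: str | None = None,
                    transpose: bool = False) -> ExpressionMatrix:
    """Read a dense CSV/TSV (cells x genes) or MatrixMarket triplet.

    For MTX input, row and column label files are expected alongside the
    matrix as ``<stem>.rows.txt`` / ``<stem>.cols.txt``.  ``transpose``
    flips a genes x cells file into the cells x genes orientation.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".mtx": "mtx", ".tsv": "tsv"}.get(path.suffix.lower(), "csv")
    if fmt == "mtx":
        values = np.asarray(scipy.io.mmread(path).todense(), dtype=float)
        rows = Path(str(path).removesuffix(".mtx") + ".rows.txt")
        cols = Path(str(path).removesuffix(".mtx") + ".cols.txt")
        cell_ids = rows.read_text().split()
        gene_ids = cols.read_text().split()
    else:
        df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",", index_col=0)
        values = df.to_numpy(dtype=float)
        cell_ids = [str(i) for i in df.index]
        gene_ids = [str(c) for c in df.columns]
    if transpose:
        values, cell_ids, gene_ids = values.T, gene_ids, cell_ids
    return ExpressionMatrix(values=values, cell_ids=cell_ids, gene_ids=gene_ids)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    pd.DataFrame(expr.values, index=expr.cell_ids,
                 columns=expr.gene_ids).to_csv(path)


def filter_noise_genes(expr: ExpressionMatrix, factor: int = 3,
                       pct: float = 0.01) -> ExpressionMatrix:
    """Remove genes expressed (value > 0) in fewer than the threshold cells.

    threshold = factor * max(1, floor(pct * n_cells)); e.g. 301 cells give
    3 * 3 = 9, so a gene positive in fewer than nine cells is dropped.
    """
    if expr.log_transformed:
        raise ValueError("filter noise genes before log transformation")
    threshold = factor * max(1, math.floor(pct * expr.n_cells))
    expressed_in = (expr.values > 0).sum(axis=0)
    keep = expressed_in >= threshold
    if not keep.any():
        raise ValueError(
            f"noise filter (threshold {threshold} cells) removed every gene"
        )
    logger.info("noise filter: threshold %d cells, kept %d/%d genes",
                threshold, int(keep.sum()), len(expr.gene_ids))
    return ExpressionMatrix(
        values=expr.values[:, keep],
        cell_ids=list(expr.cell_ids),
        gene_ids=[g for g, k in zip(expr.gene_ids, keep) if k],
    )


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log10(x + 1)."""
    if np.any(expr.values < 0):
        raise ValueError("expression values must be non-negative")
    out = replace(expr, values=np.log10(expr.values + 1.0),
                  log_transformed=True)
    return out


def retention_ratio(n_cells: int) -> float:
    """Principal-component retention ratio from dataset size.

    0.40 for small datasets (<= 1000 cells), 0.60 up to 3000, 0.80 beyond.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    if n_cells <= 1000:
        return 0.40
    if n_cells <= 3000:
        return 0.60
    return 0.80


def cosine_kernel(X: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity kernel K[i, j] = <x_i, x_j>/(|x_i||x_j|).

    Zero-norm rows get zero off-diagonal entries (diagonal stays 1) with a
    warning rather than NaN.
    """
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if zero.any():
        logger.warning("%d zero-norm rows in cosine kernel", int(zero.sum()))
    safe = np.where(zero, 1.0, norms)
    Xn = X / safe[:, None]
    K = Xn @ Xn.T
    K[zero, :] = 0.0
    K[:, zero] = 0.0
    np.fill_diagonal(K, 1.0)
    return np.clip(K, -1.0, 1.0)


def kpca_reduce(X: np.ndarray, ratio: float,
                kernel: str = "cosine", mode: str = "variance") -> np.ndarray:
    """Kernel PCA projection of a cells x genes submatrix.

    The kernel matrix is double-centered, eigendecomposed, and the smallest
    number of leading components whose eigenvalues sum to at least
    ``ratio`` of the positive eigenvalue mass is retained (at least one).
    ``mode="count"`` instead keeps ceil(ratio * #positive-eigenvalue)
    components, reading the retention ratio as a component-count fraction.
    Projections are the eigenvectors scaled by sqrt(eigenvalue); each
    component's sign is fixed so its largest-magnitude coordinate is
    positive, making repeated runs bit-identical.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("kernel PCA needs at least 2 cells")
    if not 0.0 < ratio <= 1.0:
        raise ValueError(f"retention ratio must be in (0, 1], got {ratio}")
    if kernel != "cosine":
        raise ValueError(f"unsupported kernel {kernel!r}")
    if mode not in ("variance", "count"):
        raise ValueError(f"retain mode must be 'variance' or 'count', got {mode!r}")

    K = cosine_kernel(X)
    row_means = K.mean(axis=1, keepdims=True)
    Kc = K - row_means - row_means.T + K.mean()

    eigvals, eigvecs = scipy.linalg.eigh(Kc)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = 1e-10 * max(eigvals[0], 0.0)
    positive = eigvals > tol
    eigvals, eigvecs = eigvals[positive], eigvecs[:, positive]
    if eigvals.size == 0:
        # constant submatrix: no variation to extract, emit one zero column
        return np.zeros((n, 1))

    if mode == "count":
        d = math.ceil(ratio * eigvals.size)
    else:
        cumulative = np.cumsum(eigvals)
        d = int(np.searchsorted(cumulative, ratio * cumulative[-1]) + 1)
    d = max(1, min(d, eigvals.size))

    proj = eigvecs[:, :d] * np.sqrt(eigvals[:d])
    for k in range(d):
        pivot = np.argmax(np.abs(proj[:, k]))
        if proj[pivot, k] < 0:
            proj[:, k] = -proj[:, k]
    return proj


def build_feature_matrix(
    expr: ExpressionMatrix,
    sets: Sequence[FunctionalGeneSet],
    ratio: float,
    mode: str = "variance",
) -> FeatureMatrix:
    """Concatenate per-gene-set KPCA projections into one feature matrix.

    Gene sets are intersected with the matrix's genes (in matrix order for
    determinism); sets with empty intersection are skipped with a warning.
    """
    if not expr.log_transformed:
        raise ValueError("expression must be log-transformed first")
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    blocks: list[np.ndarray] = []
    block_index: dict[str, tuple[int, int]] = {}
    start = 0
    for s in sets:
        cols = [gene_pos[g] for g in expr.gene_ids if g in s.genes]
        if not cols:
            logger.warning("gene set %s has no genes in the matrix; skipped",
                           s.id)
            continue
        proj = kpca_reduce(expr.values[:, cols], ratio, mode=mode)
        blocks.append(proj)
        block_index[s.id] = (start, start + proj.shape[1])
        start += proj.shape[1]
    if not blocks:
        raise ValueError("no functional gene set overlaps the expression matrix")
    values = np.hstack(blocks)
    logger.info("feature matrix: %d cells x %d components from %d sets",
                values.shape[0], values.shape[1], len(blocks))
    return FeatureMatrix(values=values, cell_ids=list(expr.cell_ids),
                         block_index=block_index)


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """CSV with a block-provenance header comment."""
    with open(path, "w", encoding="utf-8") as fh:
        for sid, (lo, hi) in fm.block_index.items():
            fh.write(f"# block {sid}: columns {lo}..{hi - 1}\n")
        pd.DataFrame(
            fm.values, index=fm.cell_ids,
            columns=[f"pc{i}" for i in range(fm.values.shape[1])],
        ).to_csv(fh)
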