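"""Dataset containers and on-disk formats.

Expression matrices are cells × genes, nonnegative, and may be stored
dense (CSV/TSV with a header of gene names and a leading cell-id column)
or as MatrixMarket triplets with plain-text gene/cell name sidecar files.
Batch metadata is a CSV/TSV table with one row per cell; each requested
factor column becomes a one-hot block, and the blocks are concatenated
into the multi-hot encoding y_i used by the batch-effect graph.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .geometry import ManifoldSpec, on_hyperboloid

__all__ = [
    "ExpressionMatrix", "BatchDesign", "EmbeddingTable",
    "read_expression", "read_metadata", "write_embedding", "read_embedding",
    "write_expression",
]


def _check_unique(ids, what: str):
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})[:5]
        raise ValueError(f"duplicate {what}: {dupes}")
    return ids


@dataclass
class ExpressionMatrix:
    """Cells × genes nonnegative expression matrix.

    ``values`` may be dense (ndarray) or a scipy sparse matrix; rows are
    cells. Use :meth:`dense` where a plain array is needed.
    """

    values: object
    gene_ids: list
    cell_ids: list

    def __post_init__(self):
        n, d = self.values.shape
        if n < 1 or d < 1:
            raise ValueError("matrix must have at least one cell and one gene")
        self.gene_ids = _check_unique([str(g) for g in self.gene_ids], "gene ids")
        self.cell_ids = _check_unique([str(c) for c in self.cell_ids], "cell ids")
        if len(self.gene_ids) != d:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {d} matrix columns")
        if len(self.cell_ids) != n:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n} matrix rows")
        mn = self.values.min() if not sp.issparse(self.values) else self.values.data.min(initial=0.0)
        if mn < 0:
            raise ValueError("expression values must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)


@dataclass
class BatchDesign:
    """Multi-hot batch encoding: one one-hot block per categorical factor."""

    factors: list
    encoding: np.ndarray            # n × m, concatenated one-hot blocks
    levels: dict = field(default_factory=dict)  # factor -> list of level names

    def __post_init__(self):
        self.encoding = np.asarray(self.encoding, dtype=float)
        m = sum(len(self.levels[f]) for f in self.factors)
        if self.encoding.shape[1] != m:
            raise ValueError(f"encoding has {self.encoding.shape[1]} columns, "
                             f"levels imply {m}")
        col = 0
        for f in self.factors:
            k = len(self.levels[f])
            block = self.encoding[:, col:col + k]
            if not np.allclose(block.sum(axis=1), 1.0):
                raise ValueError(f"factor {f!r}: each cell needs exactly one level")
            col += k

    @property
    def n_cells(self) -> int:
        return self.encoding.shape[0]

    def labels(self, factor: str) -> np.ndarray:
        """Per-cell level names for one factor."""
        col = 0
        for f in self.factors:
            k = len(self.levels[f])
            if f == factor:
                idx = np.argmax(self.encoding[:, col:col + k], axis=1)
                return np.asarray(self.levels[f], dtype=object)[idx]
            col += k
        raise KeyError(factor)

    @staticmethod
    def single(n: int) -> "BatchDesign":
        """Trivial design: one factor with a single level (no batch info)."""
        return BatchDesign(["batch"], np.ones((n, 1)), {"batch": ["0"]})

    @staticmethod
    def from_labels(label_arrays: dict) -> "BatchDesign":
        """Build a design from {factor_name: per-cell label array}."""
        factors = list(label_arrays)
        blocks, levels = [], {}
        for f in factors:
            lab = np.asarray(label_arrays[f])
            levs = sorted({str(v) for v in lab})
            levels[f] = levs
            idx = {v: i for i, v in enumerate(levs)}
            block = np.zeros((len(lab), len(levs)))
            for i, v in enumerate(lab):
                block[i, idx[str(v)]] = 1.0
            blocks.append(block)
        return BatchDesign(factors, np.hstack(blocks), levels)


@dataclass
class EmbeddingTable:
    """Per-cell latent coordinates on a declared manifold."""

    coords: np.ndarray
    manifold: ManifoldSpec
    cell_ids: list

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be 2-D")
        if len(self.cell_ids) != self.coords.shape[0]:
            raise ValueError("cell_ids length does not match coords rows")
        if self.coords.shape[1] != self.manifold.ambient_dim:
            raise ValueError(
                f"coords have {self.coords.shape[1]} columns; manifold "
                f"expects {self.manifold.ambient_dim}")
        self.validate()

    def validate(self):
        m = self.manifold
        if m.kind == "poincare":
            r2 = np.sum(self.coords ** 2, axis=1)
            if np.any(m.curvature * r2 >= 1.0):
                raise ValueError("Poincaré rows must satisfy K·‖x‖² < 1")
        elif m.kind == "lorentz":
            if not on_hyperboloid(self.coords, tol=1e-6):
                raise ValueError("Lorentz rows must satisfy ⟨x,x⟩_L=−1, x₀>0")


# ---------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------

def _sidecar(path: Path, suffix: str) -> Path:
    return path.with_name(path.stem + suffix)


def read_expression(path, fmt: str | None = None, genes_path=None,
                    cells_path=None, transpose: bool = False) -> ExpressionMatrix:
    """Read an expression matrix from MTX or dense CSV/TSV.

    MTX input needs gene and cell name files (defaults: ``<stem>_genes.txt``
    and ``<stem>_cells.txt`` next to the matrix, one name per line, in
    on-disk row/column order). Dense input is cells-as-rows with a header
    of gene names and the first column holding cell ids; ``transpose``
    flips a genes-as-rows file into the internal cells-as-rows convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv"}.get(
            path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format from {path.name!r}")
    if fmt == "mtx":
        try:
            mat = mmread(str(path))
        except Exception as e:
            raise ValueError(f"malformed MatrixMarket file {path}: {e}") from e
        mat = sp.csr_matrix(mat)
        if transpose:
            mat = sp.csr_matrix(mat.T)
        genes_path = Path(genes_path) if genes_path else _sidecar(path, "_genes.txt")
        cells_path = Path(cells_path) if cells_path else _sidecar(path, "_cells.txt")
        genes = [l.strip() for l in genes_path.read_text().splitlines() if l.strip()]
        cells = [l.strip() for l in cells_path.read_text().splitlines() if l.strip()]
        if len(genes) != mat.shape[1]:
            raise ValueError(
                f"matrix declares {mat.shape[1]} genes but names file lists "
                f"{len(genes)}")
        if len(cells) != mat.shape[0]:
            raise ValueError(
                f"matrix declares {mat.shape[0]} cells but names file lists "
                f"{len(cells)}")
        return ExpressionMatrix(mat, genes, cells)
    if fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t", index_col=0)
        if transpose:
            df = df.T
        return ExpressionMatrix(df.to_numpy(dtype=float),
                                list(df.columns), list(df.index))
    raise ValueError(f"unknown format {fmt!r}")


def write_expression(X: ExpressionMatrix, path):
    """Write as MatrixMarket triplets plus gene/cell name sidecars."""
    path = Path(path)
    mat = X.values if sp.issparse(X.values) else sp.coo_matrix(X.values)
    mmwrite(str(path), mat)
    _sidecar(path, "_genes.txt").write_text("\n".join(X.gene_ids) + "\n")
    _sidecar(path, "_cells.txt").write_text("\n".join(X.cell_ids) + "\n")


def read_metadata(path, factor_columns, label_column=None, cell_ids=None,
                  id_column=None, sep=None):
    """Read per-cell metadata; returns (BatchDesign, labels-or-None).

    If ``cell_ids`` is given, rows are matched on ``id_column`` (default:
    first column) and must cover every requested cell; otherwise row
    order is taken as the cell order.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if id_column is None:
        id_column = df.columns[0]
    for col in list(factor_columns) + ([label_column] if label_column else []):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not in metadata "
                             f"(has {list(df.columns)})")
    if cell_ids is not None:
        df = df.set_index(df[id_column].astype(str))
        missing = [c for c in cell_ids if c not in df.index]
        if missing:
            raise ValueError(f"metadata missing cell ids: {missing[:10]}"
                             + ("..." if len(missing) > 10 else ""))
        df = df.loc[[str(c) for c in cell_ids]]
    for col in factor_columns:
        if df[col].isna().any():
            raise ValueError(f"factor column {col!r} has missing values")
    design = BatchDesign.from_labels(
        {col: df[col].to_numpy() for col in factor_columns})
    labels = df[label_column].to_numpy() if label_column else None
    return design, labels


def write_embedding(table: EmbeddingTable, path):
    """Write an embedding as CSV; manifold recorded in a header comment.

    Coordinates are printed with round-trippable precision so that
    ``read_embedding(write_embedding(t)) == t`` bit-for-bit.
    """
    table.validate()
    path = Path(path)
    m = table.manifold
    buf = _stdio.StringIO()
    buf.write(f"# manifold={m.kind} curvature={m.curvature!r} "
              f"latent_dim={m.latent_dim}\n")
    cols = [f"z{i}" for i in range(table.coords.shape[1])]
    buf.write("cell_id," + ",".join(cols) + "\n")
    for cid, row in zip(table.cell_ids, table.coords):
        buf.write(str(cid) + "," + ",".join(repr(float(v)) for v in row)
                  + "\n")
    path.write_text(buf.getvalue())


def read_embedding(path) -> EmbeddingTable:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# manifold="):
        raise ValueError(f"{path} is not an embedding CSV (missing header)")
    meta = dict(kv.split("=") for kv in lines[0][2:].split())
    spec = ManifoldSpec(kind=meta["manifold"],
                        curvature=float(meta["curvature"]),
                        latent_dim=int(meta["latent_dim"]))
    df = pd.read_csv(_stdio.StringIO("\n".join(lines[1:])),
                     float_precision="round_trip")
    coords = df[[c for c in df.columns if c.startswith("z")]].to_numpy(float)
    return EmbeddingTable(coords, spec, [str(c) for c in df["cell_id"]])
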