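"""Readers and writers for expression matrices and label files.

Dense matrices are TSV/CSV with a header row of feature ids and a first
column of cell ids.  Sparse matrices are MatrixMarket coordinate files with
newline-delimited sidecar files for row and column names.  Labels are
two-column TSV (cell_id, label); cells absent from a type-label file are
treated as unlabeled.
"""

from __future__ import annotations

import os
import warnings

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .dataset import UNLABELED, ExpressionDataset


def _read_name_file(path):
    with open(path) as fh:
        names = [line.strip() for line in fh if line.strip()]
    return names


def load_labels(path) -> dict:
    """Read a two-column (cell_id, label) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs two columns (cell_id, label)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def load_expression(
    path,
    format: str | None = None,
    cells_axis: str = "rows",
    row_names: str | None = None,
    col_names: str | None = None,
    condition_file: str | None = None,
    type_file: str | None = None,
) -> ExpressionDataset:
    """Read a counts matrix into an :class:`ExpressionDataset`.

    Parameters
    ----------
    format
        ``"dense"`` or ``"matrixmarket"``; inferred from the ``.mtx``
        extension when omitted.
    cells_axis
        Whether cells are ``"rows"`` or ``"cols"`` of the file.
    row_names, col_names
        Sidecar name files for MatrixMarket input; default to
        ``<stem>_rows.txt`` / ``<stem>_cols.txt``.
    condition_file, type_file
        Optional two-column TSVs assigning per-cell condition and cell-type
        labels.  Without a condition file all cells get a single placeholder
        condition (alignment itself requires at least two).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "matrixmarket" if path.endswith(".mtx") else "dense"
    if cells_axis not in ("rows", "cols"):
        raise ValueError("cells_axis must be 'rows' or 'cols'")

    if format == "dense":
        sep = "," if path.endswith(".csv") else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except (pd.errors.ParserError, ValueError) as exc:
            raise ValueError(f"malformed dense matrix {path}: {exc}") from exc
        values = df.to_numpy(dtype=np.float64)
        rows = [str(r) for r in df.index]
        cols = [str(c) for c in df.columns]
    elif format == "matrixmarket":
        stem = path[:-4] if path.endswith(".mtx") else path
        row_names = row_names or stem + "_rows.txt"
        col_names = col_names or stem + "_cols.txt"
        for p in (row_names, col_names):
            if not os.path.exists(p):
                raise FileNotFoundError(f"missing MatrixMarket sidecar {p}")
        try:
            mat = scipy.io.mmread(path)
        except ValueError as exc:
            raise ValueError(f"malformed MatrixMarket file {path}: {exc}") from exc
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=np.float64
        )
        rows = _read_name_file(row_names)
        cols = _read_name_file(col_names)
        if values.shape != (len(rows), len(cols)):
            raise ValueError(
                f"matrix shape {values.shape} does not match name files "
                f"({len(rows)} rows, {len(cols)} cols)"
            )
    else:
        raise ValueError(f"unknown format {format!r}")

    if cells_axis == "cols":
        values = values.T
        rows, cols = cols, rows

    cell_ids, feature_ids = rows, cols
    if len(set(cell_ids)) != len(cell_ids):
        raise ValueError("duplicate cell ids in input")
    if len(set(feature_ids)) != len(feature_ids):
        raise ValueError("duplicate feature ids in input")

    if condition_file is not None:
        cond_map = load_labels(condition_file)
        missing = [c for c in cell_ids if c not in cond_map]
        if missing:
            raise ValueError(f"cells missing from condition file: {missing[:5]}")
        condition_of = np.array([cond_map[c] for c in cell_ids], dtype=object)
    else:
        warnings.warn("no condition file given; assigning all cells one condition")
        condition_of = np.array(["all"] * len(cell_ids), dtype=object)

    type_of = None
    if type_file is not None:
        type_map = load_labels(type_file)
        type_of = np.array(
            [type_map.get(c, UNLABELED) for c in cell_ids], dtype=object
        )

    return ExpressionDataset(
        values=values,
        cell_ids=cell_ids,
        feature_ids=feature_ids,
        condition_of=condition_of,
        type_of=type_of,
        layer="counts",
    )


def write_matrix_tsv(path, values, row_ids, col_ids):
    """Write a dense matrix in the same TSV convention :func:`load_expression`
    reads (header = column ids, first column = row ids)."""
    pd.DataFrame(np.asarray(values), index=list(row_ids), columns=list(col_ids)).to_csv(
        path, sep="\t", index_label="id"
    )


def write_labels_tsv(path, cell_ids, labels):
    pd.DataFrame({"cell_id": list(cell_ids), "label": list(labels)}).to_csv(
        path, sep="\t", index=False, header=False
    )
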