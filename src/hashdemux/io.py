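"""Readers and writers for hashing count matrices and demultiplexing results.

Supported inputs are the 10x-style Matrix Market triplet layout
(``matrix.mtx`` with ``barcodes.tsv`` / ``features.tsv`` sidecars, features
as rows) and a dense CSV in either orientation. Results are written as a
flat CSV, one row per droplet in the original barcode order.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .dataset import HashingDataset
from .errors import AlignmentError, FormatError

__all__ = [
    "read_mtx",
    "write_mtx",
    "read_dense_csv",
    "mrna_library_sizes",
    "write_result",
    "read_result",
]

#: Columns of the result CSV, in order.
RESULT_COLUMNS = [
    "barcode",
    "category",
    "doublet_first",
    "doublet_second",
    "min_md",
    "second_md",
    "md_ratio",
    "reclassified_by_mrna",
]


def _read_sidecar(path: str | os.PathLike) -> list[str]:
    """First column of a one-entry-per-line (optionally tab-separated) file."""
    entries = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                entries.append(line.split("\t")[0])
    return entries


def read_mtx(
    matrix_path: str | os.PathLike,
    barcodes_path: str | os.PathLike,
    features_path: str | os.PathLike,
) -> HashingDataset:
    """Load an HTO count matrix from Matrix Market triplet files.

    The matrix follows the 10x convention of features (hashtags) as rows and
    barcodes as columns; it is transposed so the returned dataset has
    droplets as rows. The features sidecar may carry 1-3 tab-separated
    columns; the first is used as the hashtag identifier.
    """
    mat = spio.mmread(os.fspath(matrix_path))
    if sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)
    if not np.allclose(mat, np.round(mat)):
        raise ValueError(f"{matrix_path}: matrix contains non-integer values")
    if mat.min(initial=0) < 0:
        raise ValueError(f"{matrix_path}: matrix contains negative values")
    hashtags = _read_sidecar(features_path)
    barcodes = _read_sidecar(barcodes_path)
    n_feat, n_bc = mat.shape
    if len(hashtags) != n_feat:
        raise FormatError(
            f"features file has {len(hashtags)} entries but matrix has {n_feat} rows"
        )
    if len(barcodes) != n_bc:
        raise FormatError(
            f"barcodes file has {len(barcodes)} entries but matrix has {n_bc} columns"
        )
    return HashingDataset(
        hto_counts=np.round(mat).astype(np.int64).T,
        hashtag_names=hashtags,
        barcodes=barcodes,
    )


def write_mtx(data: HashingDataset, out_dir: str | os.PathLike) -> None:
    """Write a dataset as matrix.mtx + barcodes.tsv + features.tsv.

    The matrix is stored features x barcodes (10x convention), the inverse
    of :func:`read_mtx`'s transposition, so the round trip is the identity.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(
        os.fspath(out / "matrix.mtx"),
        sparse.coo_matrix(data.hto_counts.T),
        field="integer",
    )
    (out / "barcodes.tsv").write_text("".join(b + "\n" for b in data.barcodes))
    (out / "features.tsv").write_text("".join(h + "\n" for h in data.hashtag_names))


def read_dense_csv(
    path: str | os.PathLike, orientation: str = "cells_rows"
) -> HashingDataset:
    """Load a dense CSV with a header row and an index column of names.

    ``orientation="cells_rows"`` means barcodes index the rows and hashtags
    the columns; ``"hashtags_rows"`` is the transpose.
    """
    if orientation not in ("cells_rows", "hashtags_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate row or column names")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in matrix") from exc
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: non-finite cell in matrix")
    if orientation == "hashtags_rows":
        df = df.T
        values = values.T
    if not np.allclose(values, np.round(values)):
        raise ValueError(f"{path}: counts must be integers")
    return HashingDataset(
        hto_counts=np.round(values).astype(np.int64),
        hashtag_names=list(df.columns),
        barcodes=list(df.index),
    )


def mrna_library_sizes(
    gene_counts: np.ndarray,
    data: HashingDataset | None = None,
    gene_barcodes: list[str] | None = None,
) -> np.ndarray:
    """Per-droplet mRNA library size ``L_c = sum_g Y_{gc}``.

    ``gene_counts`` is genes x droplets. If a paired dataset is given the
    column count (and, when ``gene_barcodes`` is supplied, the barcode
    identity/order) is checked against it.
    """
    gene_counts = np.asarray(gene_counts)
    if gene_counts.ndim != 2:
        raise FormatError("gene_counts must be a 2-D genes x droplets matrix")
    if np.any(gene_counts < 0):
        raise ValueError("gene counts must be non-negative")
    sizes = np.asarray(gene_counts.sum(axis=0), dtype=float).ravel()
    if data is not None:
        if sizes.size != data.n_droplets:
            raise AlignmentError(
                f"gene matrix has {sizes.size} droplets, dataset has {data.n_droplets}"
            )
        if gene_barcodes is not None and list(gene_barcodes) != data.barcodes:
            raise AlignmentError("gene-expression barcodes do not match the dataset")
    return sizes


def write_result(result, path: str | os.PathLike) -> None:
    """Write a :class:`~hashdemux.classification.DemuxResult` to CSV.

    One row per droplet in original barcode order. ``category`` is
    ``Negative``, ``Doublet`` or the hashtag name for singlets; doublet pair
    fields are empty for non-doublets.
    """
    df = result.to_frame()
    df.to_csv(path, index=False, columns=RESULT_COLUMNS, float_format="%.10g")


def read_result(path: str | os.PathLike) -> pd.DataFrame:
    """Read a result CSV back as a DataFrame (doublet fields as strings)."""
    df = pd.read_csv(path, dtype={"doublet_first": str, "doublet_second": str})
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing result columns {missing}")
    for col in ("doublet_first", "doublet_second"):
        df[col] = df[col].fillna("")
    return df
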