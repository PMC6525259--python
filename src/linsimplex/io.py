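"""Reading and writing expression matrices (TSV/CSV, GCT 1.2, matrix-market).

All readers return an :class:`~linsimplex.matrix.ExpressionMatrix` with the
first file column (or the GCT ``Name`` column) as gene ids and the header as
sample ids.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .matrix import ExpressionMatrix

__all__ = ["read_expression", "write_expression", "read_annotation"]

_FORMATS = ("tsv", "csv", "gct", "mtx")

_EXT_TO_FORMAT = {
    ".tsv": "tsv",
    ".txt": "tsv",
    ".csv": "csv",
    ".gct": "gct",
    ".mtx": "mtx",
}


def _infer_format(path: Path) -> str:
    fmt = _EXT_TO_FORMAT.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(
            f"cannot infer format from extension {path.suffix!r}; "
            f"pass format= one of {_FORMATS}"
        )
    return fmt


def _finalize(
    df: pd.DataFrame, path: Path, collapse_duplicates: bool, log_scale: bool
) -> ExpressionMatrix:
    # parse failures surface as object columns -> locate the offending cell
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"{path}: non-numeric value {df.loc[row, col]!r} at "
                f"gene {row!r}, sample {col!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in expression matrix")

    if df.index.has_duplicates:
        if not collapse_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"{path}: duplicate gene ids {dup[:10]}")
        # same rule as preprocessing: keep the highest-expressed duplicate
        from .preprocess import collapse_probes

        ids = [str(i) for i in df.index]
        values, kept = collapse_probes(df.to_numpy(dtype=float), ids, ids, log_scale)
        df = pd.DataFrame(values, index=kept, columns=df.columns)
    if (df.to_numpy() < 0).any():
        warnings.warn(
            f"{path}: negative expression values present; kept as-is",
            UserWarning,
            stacklevel=3,
        )
    return ExpressionMatrix.from_frame(df, log_scale=log_scale)


def read_expression(
    path: str | Path,
    format: str | None = None,
    collapse_duplicates: bool = False,
    log_scale: bool = False,
    gene_ids_file: str | Path | None = None,
    sample_ids_file: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV/CSV, GCT 1.2 or matrix-market.

    Parameters
    ----------
    format : {"tsv", "csv", "gct", "mtx"}, optional
        Inferred from the file extension when omitted.
    collapse_duplicates : bool
        Average rows sharing a gene id instead of raising.
    gene_ids_file, sample_ids_file
        Plain-text label files (one id per line), required for ``mtx``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")

    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=object)
        if df.shape[1] == 0:
            raise ValueError(f"{path}: malformed header (no sample columns)")
        df.index = df.index.astype(str)
        return _finalize(df, path, collapse_duplicates, log_scale)

    if fmt == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1."):
                raise ValueError(f"{path}: not a GCT file (first line {version!r})")
            dims = fh.readline().split()
            if len(dims) < 2:
                raise ValueError(f"{path}: malformed GCT dimension line")
            n_rows, n_cols = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0, dtype=object)
        if "Description" in df.columns:
            df = df.drop(columns=["Description"])
        if df.shape != (n_rows, n_cols):
            raise ValueError(
                f"{path}: GCT dimension line says {(n_rows, n_cols)} "
                f"but table is {df.shape}"
            )
        df.index = df.index.astype(str)
        return _finalize(df, path, collapse_duplicates, log_scale)

    # matrix-market triplet with side-car label files
    if gene_ids_file is None or sample_ids_file is None:
        raise ValueError("mtx format requires gene_ids_file and sample_ids_file")
    mat = scipy.io.mmread(path)
    values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    gene_ids = Path(gene_ids_file).read_text().split()
    sample_ids = Path(sample_ids_file).read_text().split()
    if len(gene_ids) != values.shape[0] or len(sample_ids) != values.shape[1]:
        raise ValueError(
            f"label files ({len(gene_ids)} genes, {len(sample_ids)} samples) "
            f"do not match matrix shape {values.shape}"
        )
    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    return _finalize(df, path, collapse_duplicates, log_scale)


def write_expression(expr: ExpressionMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a matrix as TSV/CSV (gene id first column) or GCT 1.2."""
    path = Path(path)
    fmt = format or _infer_format(path)
    df = expr.to_frame()
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index_label="gene")
    elif fmt == "csv":
        df.to_csv(path, index_label="gene")
    elif fmt == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.n_genes}\t{expr.n_samples}\n")
            out = df.copy()
            out.insert(0, "Description", expr.gene_ids)
            out.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise ValueError(f"unsupported output format {fmt!r}")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation table (columns: gene_id, chromosome[, symbol])."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: annotation table needs a 'gene_id' column")
    return df
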