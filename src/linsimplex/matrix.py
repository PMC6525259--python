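"""Core matrix containers for the deconvolution pipeline.

Genes are rows, samples are columns, everywhere.  Values are linear-scale
(non-log) expression; every downstream stage assumes non-negativity.  All
indices are 0-based internally.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "NormalizedExpressionMatrix",
    "GeneAnnotation",
    "row_normalize",
]

_RIBOSOMAL_RE = re.compile(r"^RP[LS]", re.IGNORECASE)
_SEX_CHROMOSOMES = {"X", "Y", "CHRX", "CHRY"}


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for lab in labels:
        if lab in seen:
            dups.append(lab)
        seen.add(lab)
    if dups:
        raise ValueError(f"duplicate {what} ids: {sorted(set(dups))[:10]}")


@dataclass
class ExpressionMatrix:
    """A genes x samples non-negative expression matrix with labels.

    Parameters
    ----------
    values : ndarray, shape (n_genes, n_samples)
        Linear-scale expression values.
    gene_ids, sample_ids : sequences of unique strings
    log_scale : bool
        True while the values are still log-transformed.  Must be False
        before any deconvolution step.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    log_scale: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, m = self.values.shape
        if len(self.gene_ids) != n:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n} rows")
        if len(self.sample_ids) != m:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {m} columns")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not self.log_scale and np.any(self.values < 0):
            warnings.warn(
                "expression matrix contains negative values; downstream "
                "deconvolution assumes non-negative linear-scale data",
                UserWarning,
                stacklevel=2,
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, log_scale: bool = False) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            log_scale=log_scale,
        )

    def subset_genes(self, keep: Iterable[str] | np.ndarray) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``keep`` (ids or boolean mask)."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array([pos[g] for g in keep], dtype=int)
        return ExpressionMatrix(
            self.values[idx],
            [self.gene_ids[i] for i in idx],
            list(self.sample_ids),
            self.log_scale,
        )

    def subset_samples(self, keep: Iterable[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in keep], dtype=int)
        return ExpressionMatrix(
            self.values[:, idx],
            list(self.gene_ids),
            [self.sample_ids[i] for i in idx],
            self.log_scale,
        )

    def require_deconvolvable(self) -> None:
        """Check the invariants every deconvolution stage relies on."""
        if self.log_scale:
            raise ValueError("matrix is log-scale; de-log before deconvolution")
        if self.n_genes < 2 or self.n_samples < 3:
            raise ValueError(
                f"need at least 2 genes and 3 samples, got {self.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("negative entries present after preprocessing")


@dataclass
class NormalizedExpressionMatrix:
    """Row-normalized expression: every gene row divided by its sum.

    Row normalization maps all genes specific to one cell type onto a single
    point (the simplex corner for that type), because a shared proportionality
    coefficient cancels.  ``row_sums`` keeps the divisors for provenance.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    row_sums: np.ndarray

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class GeneAnnotation:
    """Minimal per-gene annotation used by the preprocessing filters."""

    gene_id: str
    chromosome: str | None = None
    symbol: str | None = None
    is_ribosomal: bool | None = None

    def ribosomal(self) -> bool:
        if self.is_ribosomal is not None:
            return self.is_ribosomal
        name = self.symbol if self.symbol is not None else self.gene_id
        return bool(_RIBOSOMAL_RE.match(name))

    def on_sex_chromosome(self) -> bool:
        if self.chromosome is None:
            return False
        return self.chromosome.upper() in _SEX_CHROMOSOMES


def row_normalize(expr: ExpressionMatrix) -> NormalizedExpressionMatrix:
    """Divide every gene row by its sum across samples.

    Raises if any row sums to zero (or is negative); such genes must be
    filtered out before normalization.
    """
    if expr.log_scale:
        raise ValueError("row normalization operates on linear-scale values")
    sums = expr.values.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        ids = [expr.gene_ids[i] for i in bad[:10]]
        raise ValueError(
            f"{bad.size} gene rows have non-positive sums and cannot be "
            f"normalized (first offenders: {ids}); filter them first"
        )
    return NormalizedExpressionMatrix(
        values=expr.values / sums[:, None],
        gene_ids=list(expr.gene_ids),
        sample_ids=list(expr.sample_ids),
        row_sums=sums,
    )
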