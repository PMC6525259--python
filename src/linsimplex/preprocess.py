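"""Expression preprocessing ahead of deconvolution.

Microarray/RNA-seq matrices are reduced to the strongly expressed, noise-poor
core the downstream geometry needs: probes collapsed per gene, artificial
sources of linearity (sex-chromosome and RPL/RPS ribosomal genes) removed,
top-N genes by average log expression kept, optional quantile normalization,
and a guaranteed linear (non-log) output scale.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import scipy.stats

from .matrix import ExpressionMatrix, GeneAnnotation

__all__ = ["preprocess", "quantile_normalize", "collapse_probes"]

log = logging.getLogger(__name__)


def collapse_probes(
    values: np.ndarray,
    probe_ids: Sequence[str],
    symbols: Sequence[str],
    log_input: bool,
) -> tuple[np.ndarray, list[str]]:
    """Collapse probes mapping to the same gene symbol.

    Keeps, per symbol, the probe with the maximum average log expression;
    exact ties are broken by the lexicographically smallest probe id so the
    result is deterministic.  Rows come back labelled by symbol.
    """
    logs = values if log_input else np.log2(np.maximum(values, 0) + 1.0)
    means = logs.mean(axis=1)
    best: dict[str, int] = {}
    for i, sym in enumerate(symbols):
        j = best.get(sym)
        if (
            j is None
            or means[i] > means[j]
            or (means[i] == means[j] and probe_ids[i] < probe_ids[j])
        ):
            best[sym] = i
    order = sorted(best.values())
    return values[order], [symbols[i] for i in order]


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Classical column-quantile normalization.

    Every sample's empirical distribution is replaced by the mean of the
    per-rank sorted values across samples; ties within a column receive the
    mean of the reference values at their (average) ranks.
    """
    n, m = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=float)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(m):
        ranks = scipy.stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    return out


def preprocess(
    expr: ExpressionMatrix,
    annotations: Sequence[GeneAnnotation] | None = None,
    top_n: int | None = 12_000,
    remove_sex_chromosomes: bool = False,
    remove_ribosomal: bool = False,
    quantile: bool = False,
    delog_base: float | None = None,
    exclude_samples: Sequence[str] = (),
    collapse_duplicates: bool = True,
) -> ExpressionMatrix:
    """Standard preprocessing: collapse, filter, rank, normalize, linearize.

    Parameters
    ----------
    expr : ExpressionMatrix
        Input matrix; may carry duplicate-free or probe-level gene ids.
    annotations
        Per-gene :class:`GeneAnnotation`; required when
        ``remove_sex_chromosomes`` is set.  Ribosomal removal falls back to
        the RPL*/RPS* symbol convention when no annotation is given.
    top_n : int or None
        Keep this many highest-expressed genes (by average log expression),
        after the removals.  ``None`` keeps everything.
    delog_base : float, optional
        When given, the input is log-scale in this base and is exponentiated
        at the end so the output is linear.
    exclude_samples
        Explicit sample-outlier exclusion list (never automatic).

    Returns a linear-scale matrix with exactly ``top_n`` genes (fewer only if
    zero rows had to be dropped, which is warned about).
    """
    log_input = expr.log_scale or delog_base is not None
    values = np.array(expr.values, dtype=float)
    gene_ids = list(expr.gene_ids)
    ann_map = {a.gene_id: a for a in annotations} if annotations else {}

    # 1. probe collapse: probes carrying a symbol annotation are collapsed
    # onto that symbol (max average log expression wins)
    symbols = [
        ann_map[g].symbol if g in ann_map and ann_map[g].symbol else g
        for g in gene_ids
    ]
    if collapse_duplicates and len(set(symbols)) < len(symbols):
        # remember one representative annotation per symbol for the filters
        for g, sym in zip(gene_ids, symbols):
            if g in ann_map and sym not in ann_map:
                a = ann_map[g]
                ann_map[sym] = GeneAnnotation(
                    sym, chromosome=a.chromosome, symbol=a.symbol,
                    is_ribosomal=a.is_ribosomal,
                )
        values, gene_ids = collapse_probes(values, gene_ids, symbols, log_input)

    # 2. removals of artificial linearity sources
    if remove_sex_chromosomes and not ann_map:
        raise ValueError(
            "remove_sex_chromosomes requires gene annotations with chromosomes"
        )
    keep = np.ones(len(gene_ids), dtype=bool)
    for i, g in enumerate(gene_ids):
        ann = ann_map.get(g, GeneAnnotation(g))
        if remove_sex_chromosomes and ann.on_sex_chromosome():
            keep[i] = False
        if remove_ribosomal and ann.ribosomal():
            keep[i] = False
    values = values[keep]
    gene_ids = [g for g, k in zip(gene_ids, keep) if k]

    # 3. top-N by average log expression
    if top_n is not None:
        if top_n > len(gene_ids):
            raise ValueError(
                f"top_n={top_n} exceeds the {len(gene_ids)} genes available "
                "after removals"
            )
        logs = values if log_input else np.log2(np.maximum(values, 0) + 1.0)
        order = np.argsort(-logs.mean(axis=1), kind="stable")[:top_n]
        order.sort()
        values = values[order]
        gene_ids = [gene_ids[i] for i in order]

    # 4. explicit sample exclusion
    sample_ids = list(expr.sample_ids)
    if exclude_samples:
        missing = set(exclude_samples) - set(sample_ids)
        if missing:
            raise ValueError(f"exclude_samples not in matrix: {sorted(missing)}")
        cols = [j for j, s in enumerate(sample_ids) if s not in set(exclude_samples)]
        values = values[:, cols]
        sample_ids = [sample_ids[j] for j in cols]

    # 5. quantile normalization (in the current scale)
    if quantile:
        values = quantile_normalize(values)

    # 6. ensure linear output scale
    if delog_base is not None:
        values = np.power(float(delog_base), values)
    elif expr.log_scale:
        values = np.power(2.0, values)

    # 7. drop zero rows rather than erroring mid-pipeline
    row_sums = values.sum(axis=1)
    zero = row_sums <= 0
    if zero.any():
        dropped = [g for g, z in zip(gene_ids, zero) if z]
        warnings.warn(
            f"dropping {len(dropped)} all-zero gene rows after preprocessing "
            f"(first: {dropped[:5]})",
            UserWarning,
            stacklevel=2,
        )
        values = values[~zero]
        gene_ids = [g for g, z in zip(gene_ids, zero) if not z]

    return ExpressionMatrix(values, gene_ids, sample_ids, log_scale=False)
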