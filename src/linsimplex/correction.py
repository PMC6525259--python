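"""RNA-content correction of deconvolved fractions.

Expression deconvolution recovers *RNA* fractions: the share of a sample's
RNA contributed by each cell type.  Cell types differ in RNA content per
cell (c_i), so RNA fractions systematically overestimate large/RNA-rich
types relative to their cell-count fractions.  With coefficients c known
(e.g. from ERCC spike-in-normalized pure profiles) the bias inverts exactly:

    counts_ij  ∝  rna_fraction_ij / c_i   (renormalized per sample)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RnaContentCoefficients",
    "correct_fractions",
    "derive_rna_coefficients",
    "rna_fractions_from_counts",
]


@dataclass(frozen=True)
class RnaContentCoefficients:
    """Per-cell-type RNA content, defined up to a common scale.

    ``c[reference_type] == 1`` after normalization.
    """

    c: np.ndarray
    reference_type: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=float)
        if c.ndim != 1 or c.size < 1:
            raise ValueError("c must be a 1-D vector")
        if np.any(c <= 0):
            raise ValueError("RNA-content coefficients must be strictly positive")
        if not (0 <= self.reference_type < c.size):
            raise ValueError("reference_type out of range")
        object.__setattr__(self, "c", c / c[self.reference_type])

    @property
    def k_types(self) -> int:
        return self.c.size


def _as_coefficients(
    c: RnaContentCoefficients | np.ndarray | list
) -> RnaContentCoefficients:
    if isinstance(c, RnaContentCoefficients):
        return c
    return RnaContentCoefficients(np.asarray(c, dtype=float))


def correct_fractions(
    H_rna_fractions: np.ndarray,
    c: RnaContentCoefficients | np.ndarray | list,
) -> np.ndarray:
    """Convert RNA fractions into cell-count fractions.

    Divides row i by c_i and renormalizes each sample column to sum to one;
    this is the exact algebraic inverse of the forward RNA-content model, so
    exact RNA fractions map to exact count fractions.  Invariant to
    rescaling c by a positive constant.
    """
    coeffs = _as_coefficients(c)
    H = np.asarray(H_rna_fractions, dtype=float)
    if H.shape[0] != coeffs.k_types:
        raise ValueError(
            f"{H.shape[0]} fraction rows but {coeffs.k_types} coefficients"
        )
    colsums = H.sum(axis=0)
    if np.any(np.abs(colsums - 1.0) > 1e-4):
        raise ValueError(
            "input columns must be fractions summing to 1 (worst deviation "
            f"{np.max(np.abs(colsums - 1.0)):.3g})"
        )
    out = H / coeffs.c[:, None]
    return out / out.sum(axis=0, keepdims=True)


def derive_rna_coefficients(
    pure_endogenous_totals: np.ndarray,
    pure_ercc_totals: np.ndarray,
    reference: int = 0,
) -> RnaContentCoefficients:
    """RNA content per cell from pure-sample totals.

    ERCC spike-ins are added per cell-equivalent at a fixed amount, so the
    endogenous/ERCC total-count ratio of a pure sample is proportional to
    RNA per cell.  Replicate arrays (2-D, replicates in the second axis) are
    averaged before the ratio.  Coefficients are rescaled so
    ``c[reference] == 1``.
    """
    endo = np.asarray(pure_endogenous_totals, dtype=float)
    ercc = np.asarray(pure_ercc_totals, dtype=float)
    if endo.ndim == 2:
        endo = endo.mean(axis=1)
    if ercc.ndim == 2:
        ercc = ercc.mean(axis=1)
    if endo.shape != ercc.shape:
        raise ValueError("endogenous and ERCC totals must align per cell type")
    if np.any(ercc <= 0):
        raise ValueError("zero or negative ERCC totals")
    if np.any(endo <= 0):
        raise ValueError("zero or negative endogenous totals")
    return RnaContentCoefficients(endo / ercc, reference_type=reference)


def rna_fractions_from_counts(
    H_counts: np.ndarray,
    c: RnaContentCoefficients | np.ndarray | list,
) -> np.ndarray:
    """Forward model: count (fractions or absolute counts) -> RNA fractions.

    Scales row i by c_i and column-normalizes; ``correct_fractions``
    inverts it exactly.
    """
    coeffs = _as_coefficients(c)
    H = np.asarray(H_counts, dtype=float)
    if H.shape[0] != coeffs.k_types:
        raise ValueError(
            f"{H.shape[0]} count rows but {coeffs.k_types} coefficients"
        )
    if np.any(H < 0):
        raise ValueError("counts must be non-negative")
    rna = coeffs.c[:, None] * H
    colsums = rna.sum(axis=0)
    if np.any(colsums <= 0):
        raise ValueError("a sample column has zero total counts")
    return rna / colsums[None, :]
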