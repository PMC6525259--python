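"""From simplex corners to proportions and signatures.

The corner matrix H_p (rows = row-normalized proportion estimates) is
rescaled by coefficients alpha so proportion columns sum to one (the
DSA-like step), then the signature matrix W is recovered by non-negative
least squares: ``W = argmin_{W>=0} ||X - W·H||_F``, solved with a fast
combinatorial NNLS that groups genes sharing an active set into one solve.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.optimize

__all__ = [
    "solve_alpha",
    "assemble_H",
    "solve_W",
    "fcnnls",
    "reconstruction_error",
    "annotate_signatures",
    "match_proportions",
]

_ALPHA_FLOOR = 1e-12


def solve_alpha(H_p: np.ndarray) -> np.ndarray:
    """Least-squares coefficients with ``alphaᵀ · H_p ≈ (1, ..., 1)``.

    Negative components indicate corners on the wrong side of the cloud;
    they are floored at a tiny positive value with a warning.
    """
    H_p = np.asarray(H_p, dtype=float)
    k, m = H_p.shape
    if k > m:
        raise ValueError(f"more corners ({k}) than samples ({m})")
    gram = H_p @ H_p.T
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            "corner matrix is rank deficient (corners coincide); cannot "
            "solve for scaling coefficients"
        )
    alpha = np.linalg.solve(gram, H_p @ np.ones(m))
    if np.any(alpha <= 0):
        warnings.warn(
            f"non-positive scaling coefficients {alpha[alpha <= 0]}; flooring "
            f"at {_ALPHA_FLOOR} — the corners are likely misplaced",
            UserWarning,
            stacklevel=2,
        )
        alpha = np.maximum(alpha, _ALPHA_FLOOR)
    return alpha


def assemble_H(H_p: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Scale corner rows by alpha and renormalize columns to sum exactly 1
    (absorbing the least-squares residual)."""
    H_p = np.asarray(H_p, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (H_p.shape[0],):
        raise ValueError("alpha length must equal the number of corners")
    H = alpha[:, None] * H_p
    colsums = H.sum(axis=0)
    if np.any(colsums <= 0):
        raise ValueError("a sample column has non-positive proportion mass")
    return H / colsums[None, :]


def fcnnls(C: np.ndarray, A: np.ndarray, max_iter: int = 200) -> np.ndarray:
    """Solve ``min_{K>=0} ||C·K - A||_F`` column-wise (fast combinatorial
    NNLS).

    The unconstrained normal-equation solution is computed for all columns
    at once; columns already feasible are done.  Remaining columns iterate
    an active-set scheme in which columns sharing a passive set share one
    factorization.  Columns that fail to settle within ``max_iter`` fall
    back to the reference per-column solver, so the result always satisfies
    the NNLS optimality conditions.
    """
    C = np.asarray(C, dtype=float)
    A = np.asarray(A, dtype=float)
    if C.ndim != 2 or A.ndim != 2 or C.shape[0] != A.shape[0]:
        raise ValueError(f"incompatible shapes C {C.shape}, A {A.shape}")
    m, k = C.shape
    n = A.shape[1]
    CtC = C.T @ C
    CtA = C.T @ A
    scale = np.trace(CtC) / k
    tol = 1e-12 * max(scale, 1.0)

    K = np.linalg.solve(CtC, CtA)
    passive = K > 0
    K[~passive] = 0.0

    def _grouped_solve(cols: np.ndarray) -> None:
        """Re-solve the passive-set-restricted LS for the given columns."""
        pats = passive[:, cols]
        # encode each column's passive set as a bit pattern
        codes = np.zeros(cols.size, dtype=np.int64)
        for row in range(k):
            codes |= pats[row].astype(np.int64) << row
        for code in np.unique(codes):
            grp = cols[codes == code]
            mask = np.array([(code >> row) & 1 for row in range(k)], dtype=bool)
            K[:, grp] = 0.0
            if not mask.any():
                continue
            sub = np.linalg.solve(CtC[np.ix_(mask, mask)], CtA[np.ix_(mask, grp)])
            K[np.ix_(mask, grp)] = sub

    unresolved = np.flatnonzero(~passive.all(axis=0))
    # the all-passive columns were solved feasibly already; polish the rest
    active_cols = unresolved
    for _ in range(max_iter):
        if active_cols.size == 0:
            break
        _grouped_solve(active_cols)
        # feasibility: drop the most negative passive variable per column
        infeasible = (K[:, active_cols] < -tol) & passive[:, active_cols]
        bad = infeasible.any(axis=0)
        if bad.any():
            cols_bad = active_cols[bad]
            vals = np.where(passive[:, cols_bad], K[:, cols_bad], np.inf)
            drop = np.argmin(vals, axis=0)
            passive[drop, cols_bad] = False
            continue
        K[:, active_cols] = np.maximum(K[:, active_cols], 0.0)
        # optimality: add the most ascent-worthy excluded variable
        grad = CtA[:, active_cols] - CtC @ K[:, active_cols]
        candidates = np.where(~passive[:, active_cols], grad, -np.inf)
        best = candidates.max(axis=0)
        improvable = best > tol
        done = active_cols[~improvable]
        if done.size:
            pass  # those columns satisfy the KKT conditions
        cols_grow = active_cols[improvable]
        if cols_grow.size:
            add = np.argmax(candidates[:, improvable], axis=0)
            passive[add, cols_grow] = True
        active_cols = cols_grow
    else:
        # stragglers: reference solver, guaranteed optimal
        for j in active_cols:
            K[:, j], _ = scipy.optimize.nnls(C, A[:, j])
    return np.maximum(K, 0.0)


def solve_W(X: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Non-negative signature matrix ``W = argmin_{W>=0} ||X - W·H||_F``."""
    X = np.asarray(X, dtype=float)
    H = np.asarray(H, dtype=float)
    if X.shape[1] != H.shape[1]:
        raise ValueError(f"sample dimensions disagree: X {X.shape}, H {H.shape}")
    if np.linalg.matrix_rank(H) < H.shape[0]:
        raise ValueError("H must have full row rank")
    # rows of X are independent problems: min ||Hᵀ w_i - x_i||
    return fcnnls(H.T, X.T).T


def reconstruction_error(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Frobenius norm of the factorization residual ``X - W·H``."""
    X = np.asarray(X, dtype=float)
    return float(np.linalg.norm(X - np.asarray(W) @ np.asarray(H), "fro"))


def annotate_signatures(
    reference_log_expr: pd.DataFrame,
    corner_gene_sets: dict[str, list[str]] | list[list[str]],
) -> pd.DataFrame:
    """Score corner gene sets against a pure-reference compendium.

    Log expression is standardized per gene across the reference samples
    (z-score; constant genes contribute 0 with a warning), then each gene
    set's average z-score per reference sample is reported: a (gene sets x
    reference samples) table whose maxima identify the cell type behind
    each corner.
    """
    if not isinstance(corner_gene_sets, dict):
        corner_gene_sets = {
            f"corner_{i + 1}": genes for i, genes in enumerate(corner_gene_sets)
        }
    ref = reference_log_expr.astype(float)
    sd = ref.std(axis=1, ddof=0)
    constant = sd <= 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant reference genes score 0",
            UserWarning,
            stacklevel=2,
        )
    z = ref.sub(ref.mean(axis=1), axis=0).div(sd.where(~constant, 1.0), axis=0)
    z[constant] = 0.0
    rows = {}
    for name, genes in corner_gene_sets.items():
        present = [g for g in genes if g in z.index]
        if not present:
            missing = [g for g in genes if g not in z.index][:10]
            raise ValueError(
                f"gene set {name!r} has no overlap with the reference "
                f"(missing e.g. {missing})"
            )
        rows[name] = z.loc[present].mean(axis=0)
    return pd.DataFrame(rows).T


def match_proportions(
    H_est: np.ndarray, H_true: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Match estimated to true proportion rows by optimal assignment
    maximizing summed Pearson correlation.

    Returns ``(row_permutation, per_row_pearson, rmse)`` where
    ``H_est[row_permutation]`` aligns with ``H_true``.
    """
    H_est = np.asarray(H_est, dtype=float)
    H_true = np.asarray(H_true, dtype=float)
    if H_est.shape != H_true.shape:
        raise ValueError("proportion matrices must have equal shapes")
    k = H_true.shape[0]
    corr = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            ti, ej = H_true[i], H_est[j]
            denom = ti.std() * ej.std()
            corr[i, j] = (
                np.mean((ti - ti.mean()) * (ej - ej.mean())) / denom
                if denom > 0
                else -1.0
            )
    _, col = scipy.optimize.linear_sum_assignment(-corr)
    aligned = H_est[col]
    r = np.array([corr[i, col[i]] for i in range(k)])
    rmse = float(np.sqrt(np.mean((aligned - H_true) ** 2)))
    return col, r, rmse
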