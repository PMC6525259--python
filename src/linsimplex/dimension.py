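"""Cell-type number estimation and projection to the simplex subspace.

With K mixing cell types, the row-normalized gene vectors lie on a
(K-1)-dimensional affine subspace of sample space: the transcriptional
simplex.  The singular spectrum of the data estimates K; the projection
model maps genes (as points in M-dimensional sample space) onto the K-1
leading directions of the centered gene cloud, while the projection itself
is applied to the non-centered coordinates so corners can be mapped back.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import NormalizedExpressionMatrix

__all__ = [
    "ProjectionModel",
    "svd_variance",
    "estimate_num_cell_types",
    "scree_table",
    "estimate_k_from_normalized",
    "project",
]


def svd_variance(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Singular values and their explained-variance fractions
    ``alpha_i = sigma_i^2 / sum(sigma_j^2)``."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("empty matrix")
    sigma = np.linalg.svd(matrix, compute_uv=False)
    total = np.sum(sigma**2)
    if total == 0:
        raise ValueError("all-zero matrix has no variance to explain")
    return sigma, sigma**2 / total


def estimate_num_cell_types(
    explained_variance: np.ndarray,
    cumulative_threshold: float = 0.95,
    k_override: int | None = None,
) -> int:
    """Smallest K whose leading components reach the cumulative explained
    variance threshold; ``k_override`` short-circuits the rule.

    K = 1 indicates a degenerate (no-mixture-variation) spectrum and is
    flagged with a warning.
    """
    alpha = np.asarray(explained_variance, dtype=float)
    if k_override is not None:
        if k_override < 1 or k_override > alpha.size:
            raise ValueError(
                f"k_override={k_override} outside 1..{alpha.size} components"
            )
        return int(k_override)
    if not 0 < cumulative_threshold <= 1:
        raise ValueError("cumulative_threshold must be in (0, 1]")
    cum = np.cumsum(alpha)
    k = int(np.searchsorted(cum, cumulative_threshold - 1e-12) + 1)
    k = min(k, alpha.size)
    if k == 1:
        warnings.warn(
            "one component explains the variance threshold: degenerate "
            "spectrum with no mixture variation",
            UserWarning,
            stacklevel=2,
        )
    return k


def scree_table(explained_variance: np.ndarray) -> pd.DataFrame:
    alpha = np.asarray(explained_variance, dtype=float)
    return pd.DataFrame(
        {
            "component": np.arange(1, alpha.size + 1),
            "explained_variance": alpha,
            "cumulative": np.cumsum(alpha),
        }
    )


def estimate_k_from_normalized(
    norm: NormalizedExpressionMatrix,
    cumulative_threshold: float = 0.95,
    k_override: int | None = None,
) -> tuple[int, pd.DataFrame, pd.DataFrame]:
    """Estimate K from a row-normalized matrix.

    The raw scree of a row-normalized matrix is dominated by the simplex
    centroid (all rows sum to one), so the threshold rule is applied to the
    *centered* gene-cloud spectrum: K - 1 affine directions are needed for K
    types, hence K = (components reaching the threshold) + 1.  Returns
    ``(K, centered_scree, raw_scree)``; both tables are kept for inspection.
    """
    X = norm.values
    _, raw_alpha = svd_variance(X)
    centered = X - X.mean(axis=0, keepdims=True)
    _, cen_alpha = svd_variance(centered)
    if k_override is not None:
        k = int(k_override)
    else:
        # a single centered component is not degenerate here: it simply
        # means two mixing cell types, so the spectrum warning is muted
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            k = estimate_num_cell_types(cen_alpha, cumulative_threshold) + 1
    if k > norm.n_samples:
        raise ValueError(
            f"estimated K={k} exceeds the {norm.n_samples} samples available"
        )
    return k, scree_table(cen_alpha), scree_table(raw_alpha)


@dataclass
class ProjectionModel:
    """Projection of row-normalized genes onto the (K-1)-dim simplex space.

    Attributes
    ----------
    singular_values : ndarray
        Non-increasing singular values of the centered gene cloud.
    explained_variance : ndarray
        Their squared-normalized fractions (sum to 1).
    k_types : int
    center : ndarray, (M,)
        Mean gene point subtracted before the SVD.
    basis : ndarray, (K-1, M)
        Orthonormal rows; the projection operator.
    projected : ndarray, (K-1, N)
        Coordinates of the (non-centered) gene points.
    gene_ids : list of str
    """

    singular_values: np.ndarray
    explained_variance: np.ndarray
    k_types: int
    center: np.ndarray
    basis: np.ndarray
    projected: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def backproject(self, coords: np.ndarray) -> np.ndarray:
        """Map projected coordinates back to sample space.

        ``basis.T @ coords`` recovers only the in-subspace component; the
        constant off-subspace part of the affine hull (the centroid's
        residual after projection) is added back so points of the original
        cloud round-trip exactly.
        """
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        offset = self.center - self.basis.T @ (self.basis @ self.center)
        return coords @ self.basis + offset[None, :]


def project(norm: NormalizedExpressionMatrix, k_types: int) -> ProjectionModel:
    """Project row-normalized genes into (K-1)-dimensional coordinates.

    Genes are treated as points in M-dimensional sample space; the basis is
    the K-1 leading left-singular vectors of the *centered* cloud, applied
    to the *non-centered* points.  When N >> M the SVD is computed from the
    M x M Gram matrix (identical result up to numerical tolerance).
    """
    k = int(k_types)
    if k < 2:
        raise ValueError("k_types must be >= 2")
    X = norm.values  # (N, M), genes as rows = points in M-space
    n, m = X.shape
    if k - 1 > min(n, m):
        raise ValueError(f"K-1={k - 1} exceeds min(N, M)={min(n, m)}")
    center = X.mean(axis=0)
    Xc = X - center[None, :]
    # SVD of the centered cloud via the small M x M Gram matrix
    gram = Xc.T @ Xc
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    sigma = np.sqrt(evals)
    total = evals.sum()
    alpha = evals / total if total > 0 else evals
    # the Gram route floors trailing singular values at ~sqrt(eps) * sigma_1
    rank = int(np.sum(sigma > sigma[0] * 1e-7)) if sigma.size else 0
    if k - 1 > rank:
        warnings.warn(
            f"requested K-1={k - 1} exceeds numerical rank {rank}; "
            "proceeding with near-null directions",
            UserWarning,
            stacklevel=2,
        )
    basis = evecs[:, : k - 1].T  # (K-1, M), orthonormal rows
    projected = basis @ X.T  # non-centered projection, (K-1, N)
    return ProjectionModel(
        singular_values=sigma,
        explained_variance=alpha,
        k_types=k,
        center=center,
        basis=basis,
        projected=projected,
        gene_ids=list(norm.gene_ids),
        sample_ids=list(norm.sample_ids),
    )
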