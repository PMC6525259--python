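"""Mutual-linearity scoring and the collinearity network.

Two genes specific to the same cell type satisfy y = k·x across mixtures;
after row normalization the coefficient k cancels, so their normalized
profiles coincide.  The symmetric linearity score of a pair is the average
of the two coefficients of determination of the identity models x̃ = ỹ and
ỹ = x̃ (no fitted slope — the line is y = x by construction).  Genes are
nodes of a weighted network whose edge weights multiply the linearity score
by the (positive) Spearman correlation; genes whose total edge weight
("power") beats a topology-preserving permutation null are kept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats
from sklearn.metrics import silhouette_score

from .matrix import ExpressionMatrix, NormalizedExpressionMatrix, row_normalize

__all__ = [
    "CollinearityNetwork",
    "symmetric_linearity",
    "pairwise_scores",
    "build_network",
    "significance_filter",
    "threshold_filter",
    "cluster_linear_genes",
]

log = logging.getLogger(__name__)

#: returned when a normalized profile is constant (R^2 undefined)
NO_EDGE = np.nan

DEFAULT_GENE_CEILING = 15_000


def symmetric_linearity(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric coefficient of determination of the identity fit between
    two row-normalized gene profiles.

    Both vectors are row-normalized first; the score is the mean of
    ``1 - Σ(ỹ-x̃)²/Σ(ỹ-mean(ỹ))²`` and the same with roles swapped.  May be
    negative (the identity line fits worse than the mean); returns NaN when
    either normalized profile is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length vectors of size >= 3")
    sx, sy = x.sum(), y.sum()
    if sx <= 0 or sy <= 0:
        raise ValueError("gene vectors must have positive sums")
    xn, yn = x / sx, y / sy
    d2 = float(np.sum((xn - yn) ** 2))
    vx = float(np.sum((xn - xn.mean()) ** 2))
    vy = float(np.sum((yn - yn.mean()) ** 2))
    if vx == 0.0 or vy == 0.0:
        log.debug("constant normalized profile; linearity undefined")
        return NO_EDGE
    return 1.0 - 0.5 * d2 * (1.0 / vx + 1.0 / vy)


def pairwise_scores(
    norm: NormalizedExpressionMatrix,
    raw: ExpressionMatrix | None = None,
    gene_ceiling: int = DEFAULT_GENE_CEILING,
    block_size: int = 2_000,
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs symmetric linearity and Spearman correlation matrices.

    Spearman correlation is rank-based and therefore identical on raw or
    row-normalized values; it is computed on the normalized matrix.  Both
    outputs are dense symmetric (N, N) float arrays; rows whose normalized
    profile is constant carry NaN off-diagonal (the no-edge sentinel).
    Computation runs in row blocks to bound peak memory.
    """
    X = norm.values
    n, m = X.shape
    if n > gene_ceiling:
        raise ValueError(
            f"{n} genes exceeds the pairwise ceiling {gene_ceiling}; trim to "
            "the top-N expressed genes first"
        )
    if raw is not None and list(raw.gene_ids) != list(norm.gene_ids):
        raise ValueError("raw and normalized matrices carry different gene sets")

    sq = np.einsum("ij,ij->i", X, X)
    means = X.mean(axis=1)
    var = sq - m * means**2  # Σ(x - mean)²
    var = np.maximum(var, 0.0)
    degenerate = var <= 1e-300
    inv_var = np.empty(n)
    inv_var[~degenerate] = 1.0 / var[~degenerate]
    inv_var[degenerate] = np.nan

    linearity = np.empty((n, n), dtype=float)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        G = X[start:stop] @ X.T  # (b, n)
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * G
        np.maximum(d2, 0.0, out=d2)
        linearity[start:stop] = 1.0 - 0.5 * d2 * (
            inv_var[start:stop, None] + inv_var[None, :]
        )
    np.fill_diagonal(linearity, 1.0)
    linearity[degenerate, :] = NO_EDGE
    linearity[:, degenerate] = NO_EDGE
    diag = np.where(degenerate, NO_EDGE, 1.0)
    linearity[np.arange(n), np.arange(n)] = diag

    # Spearman: Pearson correlation of row ranks
    ranks = scipy.stats.rankdata(X, axis=1).astype(float)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1)
    rank_degenerate = norms <= 1e-300
    norms[rank_degenerate] = 1.0
    ranks /= norms[:, None]
    spearman = np.empty((n, n), dtype=float)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        spearman[start:stop] = ranks[start:stop] @ ranks.T
    np.clip(spearman, -1.0, 1.0, out=spearman)
    spearman[rank_degenerate, :] = NO_EDGE
    spearman[:, rank_degenerate] = NO_EDGE
    diag = np.where(rank_degenerate, NO_EDGE, 1.0)
    spearman[np.arange(n), np.arange(n)] = diag
    return linearity, spearman


@dataclass
class CollinearityNetwork:
    """Undirected weighted gene network (array-backed).

    ``edges`` is an (E, 2) int array of gene indices with i < j; ``weights``
    the matching positive edge weights; ``power`` the per-gene sum of
    incident weights.  ``p_value``/``selected`` are filled by
    :func:`significance_filter`.
    """

    gene_ids: list[str]
    edges: np.ndarray
    weights: np.ndarray
    power: np.ndarray
    p_value: np.ndarray | None = None
    selected: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def gene_table(self) -> pd.DataFrame:
        df = pd.DataFrame({"gene": self.gene_ids, "power": self.power})
        if self.p_value is not None:
            df["p_value"] = self.p_value
        if self.selected is not None:
            df["selected"] = self.selected
        return df

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_a": [self.gene_ids[i] for i in self.edges[:, 0]],
                "gene_b": [self.gene_ids[j] for j in self.edges[:, 1]],
                "weight": self.weights,
            }
        )

    def to_networkx(self):
        """Export as a networkx Graph (convenience; avoid for >1e6 edges)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.gene_ids)
        g.add_weighted_edges_from(
            (self.gene_ids[i], self.gene_ids[j], float(w))
            for (i, j), w in zip(self.edges, self.weights)
        )
        return g


def build_network(
    linearity: np.ndarray, spearman: np.ndarray, gene_ids: list[str] | None = None
) -> CollinearityNetwork:
    """Edge between two genes iff both scores are strictly positive; the
    weight is their product.  Self-edges are excluded; NaN scores never make
    an edge."""
    linearity = np.asarray(linearity, dtype=float)
    spearman = np.asarray(spearman, dtype=float)
    if linearity.shape != spearman.shape or linearity.shape[0] != linearity.shape[1]:
        raise ValueError("score matrices must be square and of equal shape")
    n = linearity.shape[0]
    if gene_ids is None:
        gene_ids = [f"gene_{i}" for i in range(n)]
    iu, ju = np.triu_indices(n, k=1)
    lin = linearity[iu, ju]
    rho = spearman[iu, ju]
    with np.errstate(invalid="ignore"):
        mask = (lin > 0) & (rho > 0)
    edges = np.stack([iu[mask], ju[mask]], axis=1).astype(np.int64)
    weights = lin[mask] * rho[mask]
    power = np.bincount(edges[:, 0], weights=weights, minlength=n) + np.bincount(
        edges[:, 1], weights=weights, minlength=n
    )
    return CollinearityNetwork(list(gene_ids), edges, weights, power)


def significance_filter(
    net: CollinearityNetwork,
    k_iterations: int = 1_000,
    alpha: float = 0.01,
    seed: int = 0,
    bonferroni: bool = False,
) -> CollinearityNetwork:
    """Permutation test of per-gene power against a topology-preserving null.

    Each round shuffles the multiset of edge weights across the fixed edge
    list and recomputes powers; ``Success(x)`` counts rounds whose sampled
    power reaches the actual power, and ``p = (Success + 1) / (K + 1)``.
    Genes with ``p < alpha`` (``alpha / N`` under Bonferroni, which requires
    ``K > N / alpha`` rounds) are selected.  Returns a new network with
    ``p_value`` and ``selected`` filled.
    """
    if k_iterations < 1:
        raise ValueError("k_iterations must be >= 1")
    n = net.n_nodes
    if net.n_edges == 0:
        raise ValueError("network has no edges")
    threshold = alpha
    if bonferroni:
        if k_iterations <= n / alpha:
            raise ValueError(
                f"Bonferroni correction at alpha={alpha} with N={n} genes "
                f"requires K > N/alpha = {n / alpha:.0f} iterations, "
                f"got {k_iterations}"
            )
        threshold = alpha / n
    rng = np.random.default_rng(seed)
    a, b = net.edges[:, 0], net.edges[:, 1]
    actual = net.power
    success = np.zeros(n, dtype=np.int64)
    for _ in range(k_iterations):
        w = rng.permutation(net.weights)
        sampled = np.bincount(a, weights=w, minlength=n) + np.bincount(
            b, weights=w, minlength=n
        )
        success += sampled >= actual
    p = (success + 1.0) / (k_iterations + 1.0)
    return CollinearityNetwork(
        list(net.gene_ids),
        net.edges,
        net.weights,
        net.power,
        p_value=p,
        selected=p < threshold,
    )


def threshold_filter(
    linearity: np.ndarray,
    k1: int = 1,
    t1: float = 0.75,
    k2: int = 10,
    t2: float = 0.25,
) -> np.ndarray:
    """Two-threshold gene filter on the pairwise linearity matrix.

    Negative linearities are zeroed first; a gene is kept when it has at
    least ``k1`` partners with linearity >= ``t1`` AND at least ``k2``
    partners with linearity >= ``t2`` (the first guards against isolated
    genes, the second guarantees clusters of meaningful size).
    """
    if t1 < t2:
        warnings.warn(
            "threshold1 < threshold2; usually threshold1 is the stricter one",
            UserWarning,
            stacklevel=2,
        )
    lin = np.array(linearity, dtype=float)
    np.nan_to_num(lin, copy=False, nan=0.0)
    np.maximum(lin, 0.0, out=lin)
    np.fill_diagonal(lin, 0.0)  # partners only, not the gene itself
    n_t1 = (lin >= t1).sum(axis=1)
    n_t2 = (lin >= t2).sum(axis=1)
    return (n_t1 >= k1) & (n_t2 >= k2)


def cluster_linear_genes(
    linearity: np.ndarray,
    gene_ids: list[str] | None = None,
    max_clusters: int = 12,
    min_cluster_size: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Hierarchically cluster kept genes into linear subnetworks.

    Distance is 1 - Pearson correlation between rows of the (filtered)
    linearity matrix; linkage is average.  The dendrogram is cut at the
    number of clusters (2..max_clusters) maximizing the mean silhouette,
    considering only cuts where every cluster has at least
    ``min_cluster_size`` members.  Returns ``(labels, linkage_matrix)``.
    """
    lin = np.asarray(linearity, dtype=float)
    n = lin.shape[0]
    if n < 2:
        raise ValueError("need at least 2 genes to cluster")
    rows = lin - lin.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rows, axis=1)
    constant = norms <= 1e-300
    if constant.any():
        warnings.warn(
            f"{constant.sum()} genes have constant linearity rows; their "
            "correlation distance is undefined and they are left unclustered "
            "(label 0)",
            UserWarning,
            stacklevel=2,
        )
    ok = ~constant
    labels = np.zeros(n, dtype=int)
    idx = np.flatnonzero(ok)
    if idx.size < 2:
        # degenerate: everything mutually identical (e.g. one tight block)
        return np.ones(n, dtype=int), np.zeros((0, 4))
    corr = (rows[idx] / norms[idx, None]) @ (rows[idx] / norms[idx, None]).T
    np.clip(corr, -1.0, 1.0, out=corr)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    condensed = scipy.spatial.distance.squareform(dist, checks=False)
    Z = scipy.cluster.hierarchy.linkage(condensed, method="average")
    if condensed.max() < 1e-10:  # a single linear subnetwork
        labels[idx] = 1
        return labels, Z
    best_k, best_score, best_labels = None, -np.inf, None
    for k in range(2, min(max_clusters, idx.size - 1) + 1):
        cand = scipy.cluster.hierarchy.fcluster(Z, k, criterion="maxclust")
        if len(np.unique(cand)) < 2:
            continue
        sizes = np.bincount(cand)[1:]
        if (sizes[sizes > 0] < min_cluster_size).any():
            continue
        score = silhouette_score(dist, cand, metric="precomputed")
        if score > best_score:
            best_k, best_score, best_labels = k, score, cand
    if best_labels is None:  # no cut respects min size; fall back to 2 groups
        best_labels = scipy.cluster.hierarchy.fcluster(Z, 2, criterion="maxclust")
    labels[idx] = best_labels
    return labels, Z
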