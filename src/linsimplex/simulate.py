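"""Synthetic mixtures with the statistical structure used to validate the
complete-deconvolution pipeline.

The generative model is X = W·H + E: cell-type signatures W are i.i.d.
log-normal (2 raised to a Normal(6, 1.5) variate per entry), proportion
columns H are uniform on the unit simplex, and the additive noise term E is
2^Normal(0, sd) per entry — strictly positive, equal to exactly 1 when
sd = 0 (the "noiseless" model keeps that deterministic offset, which is
absorbed into the signatures since proportion columns sum to one:
W·H + 1 = (W + 1)·H).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import ExpressionMatrix

__all__ = [
    "SimulationTruth",
    "simulate_signatures",
    "simulate_proportions",
    "simulate_mixture",
    "simulate_dataset",
    "remove_signature_genes",
    "simulate_rna_content_mixture",
    "simulate_pure_profile_grid",
]


@dataclass
class SimulationTruth:
    """Ground truth of a simulated mixture.

    Attributes
    ----------
    W : ndarray, (n_genes, k_types)
        Linear-scale signature matrix actually multiplied into the mixture.
    H : ndarray, (k_types, m_samples)
        Proportion matrix; every column sums to 1.
    noise_sd : float
        The log2-scale standard deviation of the additive noise term.
    rna_content : ndarray, (k_types,)
        Per-type RNA content divisors (all 1 except the RNA-content variant).
    seed : int
    """

    W: np.ndarray
    H: np.ndarray
    noise_sd: float = 0.0
    rna_content: np.ndarray = field(default=None)  # type: ignore[assignment]
    seed: int = 0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if self.rna_content is None:
            self.rna_content = np.ones(self.H.shape[0])
        colsums = self.H.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-10):
            raise ValueError("H columns must sum to 1")
        if np.any(self.W <= 0):
            raise ValueError("W must be strictly positive")

    @property
    def k_types(self) -> int:
        return self.H.shape[0]


def simulate_signatures(
    n_genes: int,
    k_types: int,
    log2_mean: float = 6.0,
    log2_sd: float = 1.5,
    seed: int = 0,
) -> np.ndarray:
    """Draw an (n_genes, k_types) signature matrix, entrywise 2^N(mean, sd)."""
    if n_genes < 1 or k_types < 1:
        raise ValueError("n_genes and k_types must be positive")
    if log2_sd < 0:
        raise ValueError("log2_sd must be non-negative")
    rng = np.random.default_rng(seed)
    return np.exp2(rng.normal(log2_mean, log2_sd, size=(n_genes, k_types)))


def simulate_proportions(k_types: int, m_samples: int, seed: int = 0) -> np.ndarray:
    """Draw proportion columns uniformly from the (k-1)-dimensional unit
    simplex, as a symmetric Dirichlet(1, ..., 1) — equivalent to sorted
    uniform spacings."""
    if k_types < 2:
        raise ValueError("need at least 2 cell types for a mixture")
    if m_samples < 1:
        raise ValueError("m_samples must be positive")
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.ones(k_types), size=m_samples).T


def simulate_mixture(
    W: np.ndarray,
    H: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    literal_offset: bool = True,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Mix signatures and proportions: X = W·H + 2^N(0, noise_sd).

    ``literal_offset=False`` drops the additive term entirely at
    ``noise_sd == 0`` instead of adding the deterministic +1 per entry.
    """
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    if W.shape[1] != H.shape[0]:
        raise ValueError(f"inner dimensions disagree: W {W.shape} vs H {H.shape}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    X = W @ H
    if noise_sd > 0 or literal_offset:
        rng = np.random.default_rng(seed)
        X = X + np.exp2(rng.normal(0.0, noise_sd, size=X.shape))
    n, m = X.shape
    expr = ExpressionMatrix(
        X,
        [f"gene_{i}" for i in range(n)],
        [f"sample_{j}" for j in range(m)],
    )
    truth = SimulationTruth(W=W, H=H, noise_sd=float(noise_sd), seed=seed)
    return expr, truth


def simulate_dataset(
    n_genes: int = 12_000,
    m_samples: int = 40,
    k_types: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    literal_offset: bool = True,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """One-call benchmark generator (defaults: 12,000 genes x 40 samples,
    3 cell types)."""
    W = simulate_signatures(n_genes, k_types, seed=seed)
    H = simulate_proportions(k_types, m_samples, seed=seed + 1)
    return simulate_mixture(W, H, noise_sd, seed=seed + 2, literal_offset=literal_offset)


def remove_signature_genes(W: np.ndarray, threshold: float = 0.85) -> np.ndarray:
    """Boolean keep-mask flagging tissue-specific genes for removal.

    A gene is removed when the Euclidean norm of its row-normalized
    signature vector reaches ``threshold`` (pure genes have norm 1, perfectly
    uniform genes 1/sqrt(K)).
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[1] < 2:
        raise ValueError("W must have at least 2 columns")
    sums = W.sum(axis=1)
    if np.any(sums <= 0):
        raise ValueError("W contains a non-positive row sum")
    wn = W / sums[:, None]
    norms = np.linalg.norm(wn, axis=1)
    return norms < threshold


def simulate_rna_content_mixture(
    n_genes: int = 12_000,
    m_samples: int = 40,
    content_divisors: tuple[float, ...] = (1.0, 2.0, 3.0),
    seed: int = 0,
    equalize_base_columns: bool = True,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Mixture of cell types that differ in per-cell RNA content.

    The base signature matrix is drawn as usual, then column k is divided by
    ``content_divisors[k]`` so the types carry different total RNA; columns
    of X are finally rescaled to a common column sum (mimicking library-depth
    normalization).  H holds true *count* fractions; the pipeline can only
    recover RNA fractions, whose relation to H is recorded in
    ``truth.rna_content`` (= 1/divisors, normalized to the first type).

    ``equalize_base_columns`` rescales the base W to exactly equal column
    sums first, so the true RNA-content coefficients are exactly the
    divisors rather than divisors perturbed by sampling noise.
    """
    k_types = len(content_divisors)
    if k_types < 2:
        raise ValueError("need at least 2 content divisors")
    if any(d <= 0 for d in content_divisors):
        raise ValueError("content divisors must be positive")
    W = simulate_signatures(n_genes, k_types, seed=seed)
    if equalize_base_columns:
        colsums = W.sum(axis=0)
        W = W * (colsums.mean() / colsums)
    div = np.asarray(content_divisors, dtype=float)
    W = W / div
    H = simulate_proportions(k_types, m_samples, seed=seed + 1)
    X = W @ H
    colsums = X.sum(axis=0)
    X = X * (colsums.mean() / colsums)
    expr = ExpressionMatrix(
        X,
        [f"gene_{i}" for i in range(n_genes)],
        [f"sample_{j}" for j in range(m_samples)],
    )
    content = (1.0 / div) / (1.0 / div[0])
    truth = SimulationTruth(W=W, H=H, noise_sd=0.0, rna_content=content, seed=seed)
    return expr, truth


def simulate_pure_profile_grid(
    n_genes: int = 12_000,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Three simulated pure tissue profiles mixed over a designed proportion
    grid (33 mixtures by default), mimicking controlled-mixture benchmark
    experiments with known mixing fractions."""
    if grid is None:
        # 11 designed proportion triples, each in 3 replicates
        base = np.array(
            [
                [1.00, 0.00, 0.00],
                [0.00, 1.00, 0.00],
                [0.00, 0.00, 1.00],
                [0.70, 0.25, 0.05],
                [0.70, 0.05, 0.25],
                [0.25, 0.70, 0.05],
                [0.25, 0.05, 0.70],
                [0.05, 0.70, 0.25],
                [0.05, 0.25, 0.70],
                [0.34, 0.33, 0.33],
                [0.55, 0.30, 0.15],
            ]
        )
        grid = np.repeat(base, 3, axis=0).T
    grid = np.asarray(grid, dtype=float)
    W = simulate_signatures(n_genes, grid.shape[0], seed=seed)
    return simulate_mixture(W, grid, noise_sd=0.0, seed=seed + 2)
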