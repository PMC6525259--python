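"""Model/Results interface orchestrating the complete-deconvolution pipeline.

``SimplexDeconvolution`` is built from an expression matrix; ``fit()`` runs
row normalization -> collinearity network -> significance (or threshold)
filtering -> SVD rank estimation -> projection -> tau-swept corner finding
-> DSA-like proportion/signature solve, and returns a
``DeconvolutionResults`` carrying the estimates, diagnostics, provenance and
a ``summary()`` table.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import collinearity as coll
from . import dimension, simplex
from .config import RunConfig
from .correction import RnaContentCoefficients, correct_fractions
from .deconvolution import (
    assemble_H,
    match_proportions,
    reconstruction_error,
    solve_W,
    solve_alpha,
)
from .matrix import ExpressionMatrix, row_normalize

__all__ = ["SimplexDeconvolution", "DeconvolutionResults", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""


@dataclass
class DeconvolutionResults:
    """Fitted complete deconvolution.

    Attributes
    ----------
    proportions : DataFrame, (K, M)
        Estimated proportion matrix H; columns sum to 1.
    signatures : DataFrame, (N, K)
        Non-negative signature matrix W.
    alpha : ndarray, (K,)
        Corner scaling coefficients.
    reconstruction_error / relative_reconstruction_error
        Frobenius residual of the reported factorization (and divided by
        ||X||_F).
    network, projection, solution
        Stage artifacts (collinearity network or None, projection model,
        simplex solution with the tau sweep table).
    """

    model: "SimplexDeconvolution"
    proportions: pd.DataFrame
    signatures: pd.DataFrame
    alpha: np.ndarray
    k_types: int
    reconstruction_error: float
    relative_reconstruction_error: float
    network: coll.CollinearityNetwork | None
    filtered_gene_ids: list[str]
    projection: dimension.ProjectionModel
    solution: simplex.SimplexSolution
    scree_centered: pd.DataFrame
    scree_raw: pd.DataFrame
    config: RunConfig
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def H(self) -> np.ndarray:
        return self.proportions.to_numpy()

    @property
    def W(self) -> np.ndarray:
        return self.signatures.to_numpy()

    @property
    def corner_gene_lists(self) -> list[pd.DataFrame]:
        return self.solution.corner_gene_lists

    def corrected_proportions(
        self, c: RnaContentCoefficients | np.ndarray | list
    ) -> pd.DataFrame:
        """Cell-count fractions from the (RNA-fraction) estimates, given
        per-type RNA-content coefficients aligned with the proportion rows."""
        out = correct_fractions(self.H, c)
        return pd.DataFrame(
            out, index=self.proportions.index, columns=self.proportions.columns
        )

    def score_against_truth(self, H_true: np.ndarray) -> dict[str, Any]:
        """Align the estimate with a known proportion matrix (optimal
        assignment on Pearson correlation) and report recovery metrics."""
        perm, r, rmse = match_proportions(self.H, np.asarray(H_true, dtype=float))
        return {
            "permutation": perm,
            "pearson_per_type": r,
            "min_pearson": float(r.min()),
            "rmse": rmse,
        }

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Complete deconvolution via transcriptional simplex",
            "=" * 58,
            f"genes x samples        : {self.model.expr.n_genes} x {self.model.expr.n_samples}",
            f"filter method          : {cfg.filter_method}",
            f"genes after filtering  : {len(self.filtered_gene_ids)}",
            f"cell types (K)         : {self.k_types}"
            + ("  [user override]" if cfg.k_types is not None else "  [scree estimate]"),
            f"corner method          : {self.solution.method}",
            f"tau                    : {np.atleast_1d(self.solution.tau)}",
            f"reconstruction error   : {self.reconstruction_error:.6g}"
            f" ({self.relative_reconstruction_error:.3g} of ||X||_F)",
            f"alpha                  : {np.round(self.alpha, 4)}",
            "",
            "Mean proportions per cell type:",
        ]
        means = self.proportions.mean(axis=1)
        for name, val in means.items():
            lines.append(f"  {name:<12} {val:8.4f}")
        lines.append("")
        lines.append("Scree (centered cloud, leading 6 components):")
        head = self.scree_centered.head(6)
        for _, row in head.iterrows():
            lines.append(
                f"  component {int(row['component']):>2}: "
                f"{row['explained_variance']:.4f} (cum {row['cumulative']:.4f})"
            )
        return "\n".join(lines)


class SimplexDeconvolution:
    """Complete-deconvolution model over a preprocessed expression matrix.

    Parameters
    ----------
    expr : ExpressionMatrix
        Linear-scale, non-negative, genes x samples.  Use
        :func:`linsimplex.preprocess` first for raw microarray/RNA-seq data.
    config : RunConfig, optional
        Full pipeline configuration; keyword arguments override single
        fields (e.g. ``SimplexDeconvolution(expr, k_types=3)``).
    """

    def __init__(
        self, expr: ExpressionMatrix, config: RunConfig | None = None, **overrides
    ):
        cfg = config or RunConfig()
        if overrides:
            cfg = RunConfig.from_dict({**cfg.to_dict(), **overrides})
        cfg.validate()
        expr.require_deconvolvable()
        self.expr = expr
        self.config = cfg

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, config: RunConfig | None = None, **overrides
    ) -> "SimplexDeconvolution":
        return cls(ExpressionMatrix.from_frame(df), config=config, **overrides)

    # -- pipeline stages -------------------------------------------------

    def _filter_genes(
        self, norm
    ) -> tuple[np.ndarray, coll.CollinearityNetwork | None]:
        cfg = self.config
        if cfg.filter_method == "none":
            return np.ones(norm.n_genes, dtype=bool), None
        linearity, spearman = coll.pairwise_scores(norm)
        if cfg.filter_method == "threshold":
            mask = coll.threshold_filter(
                linearity, cfg.k1, cfg.threshold1, cfg.k2, cfg.threshold2
            )
            net = coll.build_network(linearity, spearman, list(norm.gene_ids))
            return mask, net
        net = coll.build_network(linearity, spearman, list(norm.gene_ids))
        del linearity, spearman
        net = coll.significance_filter(
            net,
            k_iterations=cfg.n_iterations,
            alpha=cfg.alpha,
            seed=cfg.stage_seed("significance_filter"),
            bonferroni=cfg.bonferroni,
        )
        return net.selected.copy(), net

    def fit(self) -> DeconvolutionResults:
        cfg = self.config
        timings: dict[str, float] = {}

        def stage(name):
            class _Timer:
                def __enter__(self_):
                    self_.t0 = time.perf_counter()

                def __exit__(self_, exc_type, exc, tb):
                    timings[name] = time.perf_counter() - self_.t0
                    if exc is not None and not isinstance(exc, PipelineError):
                        raise PipelineError(f"stage {name!r} failed: {exc}") from exc

            return _Timer()

        with stage("row_normalize"):
            norm = row_normalize(self.expr)

        with stage("gene_filter"):
            mask, net = self._filter_genes(norm)
            if mask.sum() < 2:
                raise ValueError(
                    f"only {int(mask.sum())} genes survive the "
                    f"{cfg.filter_method} filter"
                )
            filtered = self.expr.subset_genes(mask)
            norm_f = row_normalize(filtered)

        with stage("rank_estimate"):
            k, scree_cen, scree_raw = dimension.estimate_k_from_normalized(
                norm_f, cfg.cumulative_threshold, k_override=cfg.k_types
            )
            if k < 2:
                raise ValueError("estimated K < 2: no mixture variation")

        with stage("projection"):
            proj = dimension.project(norm_f, k)

        with stage("corners"):
            corner_kwargs = dict(
                tau_grid=cfg.resolved_tau_grid(),
                method=cfg.corner_method,
                n_restarts=cfg.n_restarts,
                seed=cfg.stage_seed("corners"),
                g_top=min(cfg.g_top, norm_f.n_genes),
            )
            if cfg.use_smart_corners:
                sol = simplex.smart_corners(
                    proj, norm_f, max_combinations=cfg.max_combinations,
                    **corner_kwargs,
                )
            else:
                sol = simplex.sweep_tau(proj, norm_f, **corner_kwargs)

        with stage("deconvolve"):
            H_p = sol.corners_sample_space
            alpha = solve_alpha(H_p)
            H = assemble_H(H_p, alpha)
            target = self.expr if cfg.signature_genes == "all" else filtered
            W = solve_W(target.values, H)
            err = reconstruction_error(target.values, W, H)
            rel = err / np.linalg.norm(target.values, "fro")

        proportions = pd.DataFrame(
            H,
            index=[f"cell_type_{i + 1}" for i in range(k)],
            columns=self.expr.sample_ids,
        )
        signatures = pd.DataFrame(
            W,
            index=target.gene_ids,
            columns=[f"cell_type_{i + 1}" for i in range(k)],
        )
        provenance = {
            "config": cfg.to_dict(),
            "stage_seeds": {
                s: cfg.stage_seed(s) for s in ("significance_filter", "corners")
            },
            "timings_sec": timings,
            "n_genes_input": self.expr.n_genes,
            "n_genes_filtered": filtered.n_genes,
        }
        return DeconvolutionResults(
            model=self,
            proportions=proportions,
            signatures=signatures,
            alpha=alpha,
            k_types=k,
            reconstruction_error=err,
            relative_reconstruction_error=float(rel),
            network=net,
            filtered_gene_ids=list(filtered.gene_ids),
            projection=proj,
            solution=sol,
            scree_centered=scree_cen,
            scree_raw=scree_raw,
            config=cfg,
            provenance=provenance,
        )


def run_pipeline(
    expr: ExpressionMatrix, config: RunConfig | None = None, **overrides
) -> DeconvolutionResults:
    """Functional entry point: build the model and fit it in one call."""
    return SimplexDeconvolution(expr, config=config, **overrides).fit()
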