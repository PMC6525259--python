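"""Simplex corner identification in projected space.

The row-normalized gene cloud, projected to K-1 dimensions, fills a
(K-1)-simplex whose vertices are the row-normalized cell-type proportion
vectors.  Corners are found by minimum-volume simplex estimation: in lifted
(homogeneous) coordinates the inverse corner matrix Q is optimized to
minimize ``-log|det Q| + tau * Σ hinge(-Q·Ỹ)`` subject to the affine
constraint ``1ᵀQ = e_Kᵀ``.  The hinge softly penalizes points left outside
the simplex; small tau shrinks the simplex and treats outliers as noise,
large tau forces enclosure of every point.  The log-det term is linearized
iteratively, each subproblem is solved by an ADMM splitting, and a
backtracking line search guarantees descent of the true objective.

A deterministic extreme-point picker (VCA-style successive orthogonal
projections) serves as initializer and as a contrast method: it can only
return members of the input cloud, so it fails when no near-pure signature
genes exist, while the minimum-volume fit still extrapolates the corners.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .deconvolution import assemble_H, reconstruction_error, solve_W, solve_alpha
from .dimension import ProjectionModel
from .matrix import ExpressionMatrix, NormalizedExpressionMatrix

__all__ = [
    "SimplexSolution",
    "find_corners",
    "sweep_tau",
    "smart_corners",
    "backproject_corners",
    "corner_genes",
    "expand_to_enclose",
    "default_tau_grid",
    "match_corners",
]

log = logging.getLogger(__name__)

CORNER_METHODS = ("sisal", "mvsa", "vca")


def default_tau_grid() -> np.ndarray:
    """The standard noise-tolerance grid 2^i for i in -20..0 (21 values)."""
    return np.exp2(np.arange(-20, 1, dtype=float))


def _lift(points: np.ndarray) -> np.ndarray:
    """Append a row of ones: affine geometry becomes linear algebra."""
    return np.vstack([points, np.ones(points.shape[1])])


def _regular_simplex(k: int) -> np.ndarray:
    """K vertices of a regular simplex centered at the origin in (K-1)-dim,
    as a (K-1, K) array of unit-norm columns."""
    verts = np.eye(k) - 1.0 / k
    u, s, _ = np.linalg.svd(verts, full_matrices=False)
    coords = (u[:, : k - 1] * s[: k - 1]).T  # (K-1, K)
    norms = np.linalg.norm(coords, axis=0)
    return coords / norms.max()


def vca_corners(points: np.ndarray, k_types: int) -> tuple[np.ndarray, np.ndarray]:
    """Pick K extreme data points by successive orthogonal projection.

    Works in lifted coordinates; the first pick is the point of maximal
    lifted norm, each next pick maximizes the residual norm orthogonal to
    the span of the picks so far.  Returns ``(corners (K, K-1), indices)``.
    """
    d, n = points.shape
    k = int(k_types)
    if n < k:
        raise ValueError(f"need at least {k} points, got {n}")
    Y = _lift(points)  # (k, n) when d == k-1
    chosen: list[int] = []
    basis = np.zeros((Y.shape[0], 0))
    residual = Y.copy()
    for _ in range(k):
        norms = np.einsum("ij,ij->j", residual, residual)
        idx = int(np.argmax(norms))
        chosen.append(idx)
        v = residual[:, idx]
        nv = np.linalg.norm(v)
        if nv <= 1e-300:
            # degenerate cloud: fewer extreme directions than corners
            remaining = [i for i in range(n) if i not in chosen]
            chosen[-1] = remaining[0] if remaining else idx
            v = Y[:, chosen[-1]]
            nv = np.linalg.norm(v) or 1.0
        v = v / nv
        basis = np.column_stack([basis, v])
        residual = residual - v[:, None] * (v @ residual)[None, :]
    idx = np.array(chosen)
    return points[:, idx].T.copy(), idx


def _objective(Q: np.ndarray, Ytil: np.ndarray, tau: float) -> float:
    sign, logdet = np.linalg.slogdet(Q)
    if sign == 0:
        return np.inf
    A = Q @ Ytil
    return -logdet + tau * float(np.sum(np.maximum(-A, 0.0)))


def _sisal(
    points: np.ndarray,
    k_types: int,
    tau: float,
    Q0: np.ndarray,
    max_outer: int = 80,
    inner_iters: int = 40,
    tol: float = 1e-8,
) -> tuple[np.ndarray, dict]:
    """Minimum-volume simplex fit (see module docstring).

    Returns ``(Q, info)`` where the inverse of Q holds the lifted corners in
    its columns.
    """
    k = int(k_types)
    Ytil = _lift(points)  # (k, n)
    n = Ytil.shape[1]
    F = Ytil @ Ytil.T
    e_last = np.zeros(k)
    e_last[-1] = 1.0
    rho = max(tau, 1e-4)
    mu = 1e-2 * np.trace(F) / k
    Q = Q0.copy()
    obj = _objective(Q, Ytil, tau)
    n_outer = 0
    for outer in range(max_outer):
        n_outer = outer + 1
        Qt = Q.copy()
        sign, logdet_t = np.linalg.slogdet(Qt)
        G = np.linalg.inv(Qt).T  # gradient of log|det Q| at Qt
        A_sys = mu * np.eye(k) + rho * F
        A_inv = np.linalg.inv(A_sys)
        Z = Qt @ Ytil
        U = np.zeros_like(Z)
        for _ in range(inner_iters):
            B = G + mu * Qt + rho * (Z - U) @ Ytil.T
            R = B @ A_inv
            # shift columns uniformly to meet the affine constraint 1ᵀQ = eᵀ
            Qn = R - np.ones((k, 1)) @ ((R.sum(axis=0) - e_last) / k)[None, :]
            V = Qn @ Ytil + U
            Z = np.where(V >= 0, V, np.where(V < -tau / rho, V + tau / rho, 0.0))
            U = V - Z
        # backtracking line search on the true objective
        best_theta, best_obj = 0.0, obj
        theta = 1.0
        for _ in range(12):
            cand = Qt + theta * (Qn - Qt)
            val = _objective(cand, Ytil, tau)
            if val < best_obj:
                best_theta, best_obj = theta, val
                break
            theta *= 0.5
        if best_theta == 0.0:
            break
        Q = Qt + best_theta * (Qn - Qt)
        rel = abs(best_obj - obj) / max(abs(obj), 1.0)
        obj = best_obj
        if rel < tol:
            break
    sign, _ = np.linalg.slogdet(Q)
    if sign == 0:
        raise RuntimeError(
            f"simplex optimization became singular (tau={tau}, "
            f"outer iterations={n_outer})"
        )
    Q = _polish(Q, Ytil, tau)
    obj = _objective(Q, Ytil, tau)
    return Q, {"objective": obj, "outer_iterations": n_outer, "n_points": n}


def _polish(
    Q0: np.ndarray,
    Ytil: np.ndarray,
    tau: float,
    eps_schedule: tuple[float, ...] = (1e-2, 1e-4, 1e-6),
) -> np.ndarray:
    """Refine a simplex by quasi-Newton descent on the smoothed objective.

    The hinge is replaced by a softplus of width eps (continuation over a
    decreasing schedule); the affine constraint is eliminated by optimizing
    a column-centered additive update of Q.  Returns the refined Q only when
    it improves the true (non-smoothed) objective.
    """
    k = Q0.shape[0]

    def make_fun(eps):
        def fun(d):
            D = d.reshape(k, k)
            V = D - np.ones((k, 1)) @ D.mean(axis=0)[None, :]
            Q = Q0 + V
            sign, logdet = np.linalg.slogdet(Q)
            if sign == 0:
                return 1e100, np.zeros(k * k)
            A = Q @ Ytil
            x = -A / eps
            softplus = np.where(x > 30, x, np.log1p(np.exp(np.minimum(x, 30))))
            f = -logdet + tau * eps * softplus.sum()
            sigmoid = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
            gQ = -np.linalg.inv(Q).T - tau * sigmoid @ Ytil.T
            gD = gQ - np.ones((k, 1)) @ gQ.mean(axis=0)[None, :]
            return f, gD.ravel()

        return fun

    d = np.zeros(k * k)
    for eps in eps_schedule:
        res = scipy.optimize.minimize(
            make_fun(eps), d, jac=True, method="L-BFGS-B",
            options={"maxiter": 300, "ftol": 1e-15, "gtol": 1e-12},
        )
        d = res.x
    D = d.reshape(k, k)
    Q = Q0 + (D - np.ones((k, 1)) @ D.mean(axis=0)[None, :])
    if _objective(Q, Ytil, tau) < _objective(Q0, Ytil, tau):
        return Q
    return Q0


def _corners_from_Q(Q: np.ndarray) -> np.ndarray:
    M = np.linalg.inv(Q)  # columns are lifted corners [m_k; ~1]
    scale = M[-1, :]
    M = M / scale[None, :]  # exact homogeneous normalization
    return M[:-1, :].T.copy()  # (K, K-1)


def find_corners(
    points: np.ndarray,
    k_types: int,
    tau: float = 2.0**-10,
    method: str = "sisal",
    n_restarts: int = 3,
    seed: int = 0,
    max_outer: int = 80,
) -> np.ndarray:
    """Find K simplex corners in (K-1)-dimensional projected coordinates.

    Parameters
    ----------
    points : ndarray, (K-1, N)
        Projected gene coordinates (columns are genes).
    tau : float
        Noise tolerance of the soft containment penalty (ignored by
        ``vca``).
    method : {"sisal", "mvsa", "vca"}
        ``mvsa`` is the near-hard-containment variant (hinge weight scaled
        up 1000x); ``vca`` returns extreme data points.
    n_restarts : int
        Seeded random perturbations of the initializer; best objective wins.

    Returns
    -------
    corners : ndarray, (K, K-1), rows are corner coordinates.
    """
    points = np.asarray(points, dtype=float)
    k = int(k_types)
    if k < 2:
        raise ValueError("k_types must be >= 2")
    if points.ndim != 2 or points.shape[0] != k - 1:
        raise ValueError(
            f"points must be (K-1, N) = ({k - 1}, N), got {points.shape}"
        )
    if points.shape[1] < k:
        raise ValueError(f"need at least K={k} points")
    if method not in CORNER_METHODS:
        raise ValueError(f"method must be one of {CORNER_METHODS}")
    if tau <= 0:
        raise ValueError("tau must be positive")

    vca_c, _ = vca_corners(points, k)
    if method == "vca":
        return vca_c
    eff_tau = tau * 1000.0 if method == "mvsa" else tau

    spread = float(points.std(axis=1).mean()) or 1.0
    centroid = points.mean(axis=1)
    rng = np.random.default_rng(seed)
    best_Q, best_obj = None, np.inf
    Ytil = _lift(points)
    for restart in range(max(1, n_restarts)):
        init = vca_c.copy()
        if restart > 0:
            init = init + rng.normal(0.0, 0.1 * spread, size=init.shape)
        # expand slightly about the centroid so the start encloses the picks
        init = centroid[None, :] + 1.05 * (init - centroid[None, :])
        M0 = _lift(init.T)
        if abs(np.linalg.det(M0)) < 1e-12:
            reg = _regular_simplex(k) * (2.0 * spread) + centroid[:, None]
            M0 = _lift(reg)
        Q0 = np.linalg.inv(M0)
        try:
            Q, info = _sisal(points, k, eff_tau, Q0, max_outer=max_outer)
        except RuntimeError:
            continue
        if info["objective"] < best_obj:
            best_Q, best_obj = Q, info["objective"]
    if best_Q is None:
        raise RuntimeError(
            f"corner optimization failed to converge for tau={tau} "
            f"after {n_restarts} restarts"
        )
    corners = _corners_from_Q(best_Q)
    # flag coincident corners
    for i, j in itertools.combinations(range(k), 2):
        if np.linalg.norm(corners[i] - corners[j]) < 1e-10 * max(spread, 1e-30):
            warnings.warn(
                f"corners {i} and {j} coincide; solution is degenerate",
                UserWarning,
                stacklevel=2,
            )
    return corners


def expand_to_enclose(corners: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Expand a simplex facet-by-facet until it encloses every point (the
    tau -> infinity limit of the soft containment penalty).

    A negative barycentric coordinate ``a_k`` means the point lies beyond
    facet k; translating each facet outward to its most violating point
    maps barycentric coordinates as ``a' = (a - m) / (1 - sum(m))`` with
    ``m_k = min(0, min_n a_kn)``.  Facet orientations are preserved, so a
    fit whose facets were merely pushed inward by the soft penalty is
    restored exactly.  Returns the input unchanged when all points are
    already inside.
    """
    corners = np.asarray(corners, dtype=float)
    k = corners.shape[0]
    Mt = _lift(corners.T)
    A = np.linalg.solve(Mt, _lift(points))
    m = np.minimum(A.min(axis=1), 0.0)
    if not (m < 0).any():
        return corners
    # a = (1 - sum(m)) a' + m, i.e. M' = M @ T with T = (1-sum m) I + m 1^T
    T = (1.0 - m.sum()) * np.eye(k) + np.outer(m, np.ones(k))
    Mt_new = Mt @ T
    return (Mt_new[:-1] / Mt_new[-1:, :]).T.copy()


def match_corners(reference: np.ndarray, corners: np.ndarray) -> np.ndarray:
    """Optimally assign ``corners`` rows to ``reference`` rows (Hungarian on
    Euclidean distances); returns the permuted copy of ``corners``."""
    cost = np.linalg.norm(reference[:, None, :] - corners[None, :, :], axis=2)
    _, col = scipy.optimize.linear_sum_assignment(cost)
    return corners[col]


def backproject_corners(
    corners_projected: np.ndarray, model: ProjectionModel
) -> np.ndarray:
    """Map projected corners back to sample space as row-normalized
    proportion estimates H_p (K, M).

    Negative coordinates are clipped to zero (warning when below -1e-6, the
    threshold separating numerical dust from genuinely bad geometry); rows
    are renormalized to sum to one.
    """
    H_p = model.backproject(np.asarray(corners_projected, dtype=float))
    if np.any(H_p < -1e-6):
        warnings.warn(
            f"corner back-projection produced coordinates as low as "
            f"{H_p.min():.3g}; clipping to 0",
            UserWarning,
            stacklevel=2,
        )
    H_p = np.maximum(H_p, 0.0)
    sums = H_p.sum(axis=1)
    if np.any(sums <= 0):
        raise ValueError(
            "a back-projected corner row has non-positive sum: pathological "
            "simplex geometry"
        )
    return H_p / sums[:, None]


def corner_genes(
    points: np.ndarray,
    corners: np.ndarray,
    gene_ids: list[str] | None = None,
    g_top: int = 100,
) -> list[pd.DataFrame]:
    """Per corner, the ``g_top`` genes closest in projected space.

    Returns one DataFrame (gene, distance; ascending) per corner.
    """
    points = np.asarray(points, dtype=float)
    corners = np.asarray(corners, dtype=float)
    n = points.shape[1]
    if g_top > n:
        raise ValueError(f"g_top={g_top} exceeds {n} genes")
    if gene_ids is None:
        gene_ids = [f"gene_{i}" for i in range(n)]
    gene_ids = list(gene_ids)
    out = []
    for c in corners:
        dist = np.linalg.norm(points - c[:, None], axis=0)
        order = np.argsort(dist, kind="stable")[:g_top]
        out.append(
            pd.DataFrame(
                {"gene": [gene_ids[i] for i in order], "distance": dist[order]}
            ).reset_index(drop=True)
        )
    return out


@dataclass
class SimplexSolution:
    """A fitted transcriptional simplex.

    ``tau`` is a scalar for single-tau solutions or a per-corner vector for
    Smart Corners.  ``tau_table`` records the full tau -> reconstruction
    error sweep.
    """

    corners_projected: np.ndarray
    corners_sample_space: np.ndarray  # H_p, (K, M), rows sum to 1
    tau: float | np.ndarray
    reconstruction_error: float
    corner_gene_lists: list[pd.DataFrame] = field(default_factory=list)
    tau_table: pd.DataFrame | None = None
    method: str = "sisal"

    @property
    def k_types(self) -> int:
        return self.corners_sample_space.shape[0]


def _evaluate_corners(
    corners: np.ndarray,
    model: ProjectionModel,
    values: np.ndarray,
) -> float:
    """Reconstruction error of a corner set on the matrix being deconvolved."""
    H_p = backproject_corners(corners, model)
    alpha = solve_alpha(H_p)
    H = assemble_H(H_p, alpha)
    W = solve_W(values, H)
    return reconstruction_error(values, W, H)


def _matrix_values(
    expr: ExpressionMatrix | NormalizedExpressionMatrix,
) -> np.ndarray:
    return expr.values


def sweep_tau(
    model: ProjectionModel,
    expr: ExpressionMatrix | NormalizedExpressionMatrix,
    tau_grid: np.ndarray | None = None,
    method: str = "sisal",
    n_restarts: int = 3,
    seed: int = 0,
    g_top: int = 100,
) -> SimplexSolution:
    """Sweep the noise tolerance and keep the corner set with the smallest
    reconstruction error.

    For each tau the corners are found, back-projected to sample space,
    the proportion/signature factorization is solved, and the Frobenius
    reconstruction error on ``expr`` (the matrix actually deconvolved) is
    recorded; the full table is kept on the returned solution.
    """
    if tau_grid is None:
        tau_grid = default_tau_grid()
    tau_grid = np.asarray(tau_grid, dtype=float)
    if tau_grid.size == 0:
        raise ValueError("tau grid is empty")
    values = _matrix_values(expr)
    points = model.projected
    k = model.k_types
    rows = []
    best = None
    failures = []
    for tau in tau_grid:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                corners = find_corners(
                    points, k, tau=tau, method=method,
                    n_restarts=n_restarts, seed=seed,
                )
                err = _evaluate_corners(corners, model, values)
        except (RuntimeError, ValueError, np.linalg.LinAlgError) as exc:
            failures.append((tau, str(exc)))
            rows.append(
                {"tau": tau, "reconstruction_error": np.inf,
                 "reconstruction_error_enclosed": np.inf}
            )
            continue
        # the tau->infinity limit (full containment) competes as a candidate
        # refinement at every tau; selection stays purely error-driven
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                enclosed = expand_to_enclose(corners, points)
                err_enc = (
                    err
                    if enclosed is corners
                    else _evaluate_corners(enclosed, model, values)
                )
        except (ValueError, np.linalg.LinAlgError):
            enclosed, err_enc = corners, np.inf
        rows.append(
            {"tau": tau, "reconstruction_error": err,
             "reconstruction_error_enclosed": err_enc}
        )
        if best is None or err < best[1]:
            best = (corners, err, tau)
        if err_enc < best[1]:
            best = (enclosed, err_enc, tau)
    if best is None:
        raise RuntimeError(
            "corner identification failed for every tau: "
            + "; ".join(f"tau={t:g}: {m}" for t, m in failures[:3])
        )
    table = pd.DataFrame(rows)
    finite = table["reconstruction_error"][np.isfinite(table["reconstruction_error"])]
    if len(finite) and (finite > 10 * finite.median()).any():
        log.warning(
            "tau sweep contains errors >10x the grid median; the optimizer "
            "may have failed for some tolerances"
        )
    corners, err, tau = best
    H_p = backproject_corners(corners, model)
    genes = corner_genes(points, corners, model.gene_ids, g_top=min(g_top, points.shape[1]))
    return SimplexSolution(
        corners_projected=corners,
        corners_sample_space=H_p,
        tau=float(tau),
        reconstruction_error=float(err),
        corner_gene_lists=genes,
        tau_table=table,
        method=method,
    )


def smart_corners(
    model: ProjectionModel,
    expr: ExpressionMatrix | NormalizedExpressionMatrix,
    tau_grid: np.ndarray | None = None,
    max_combinations: int = 256,
    method: str = "sisal",
    n_restarts: int = 3,
    seed: int = 0,
    g_top: int = 100,
) -> SimplexSolution:
    """Choose a separate tau per corner.

    Corner sets from every tau run are matched to the best single-tau
    solution (optimal assignment on distances), then per-corner tau
    combinations are enumerated — most promising taus first, truncating the
    grid when the combination budget is exceeded — and scored by
    reconstruction error.  The best single-tau solution is always a member
    of the search space, so the result can only improve on it.
    """
    if tau_grid is None:
        tau_grid = default_tau_grid()
    tau_grid = np.asarray(tau_grid, dtype=float)
    single = sweep_tau(
        model, expr, tau_grid, method=method, n_restarts=n_restarts,
        seed=seed, g_top=g_top,
    )
    if max_combinations <= 1:
        return single
    k = model.k_types
    values = _matrix_values(expr)
    points = model.projected

    # collect matched corner sets per tau, ordered by single-tau error
    table = single.tau_table.sort_values("reconstruction_error")
    usable: list[tuple[float, np.ndarray]] = []
    for tau in table["tau"]:
        row_err = table.loc[table["tau"] == tau, "reconstruction_error"].iloc[0]
        if not np.isfinite(row_err):
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                c = find_corners(
                    points, k, tau=tau, method=method,
                    n_restarts=n_restarts, seed=seed,
                )
        except (RuntimeError, np.linalg.LinAlgError):
            continue
        usable.append((float(tau), match_corners(single.corners_projected, c)))
    n_taus = max(1, int(np.floor(max_combinations ** (1.0 / k))))
    if n_taus < len(usable):
        warnings.warn(
            f"truncating tau grid to the {n_taus} best tolerances to respect "
            f"max_combinations={max_combinations}",
            UserWarning,
            stacklevel=2,
        )
        usable = usable[:n_taus]
    best_corners = single.corners_projected
    best_err = single.reconstruction_error
    best_tau: np.ndarray | float = np.full(k, float(single.tau))
    for combo in itertools.product(range(len(usable)), repeat=k):
        corners = np.vstack([usable[c][1][i] for i, c in enumerate(combo)])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                err = _evaluate_corners(corners, model, values)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if err < best_err:
            best_err = err
            best_corners = corners
            best_tau = np.array([usable[c][0] for c in combo])
    H_p = backproject_corners(best_corners, model)
    genes = corner_genes(
        points, best_corners, model.gene_ids, g_top=min(g_top, points.shape[1])
    )
    return SimplexSolution(
        corners_projected=best_corners,
        corners_sample_space=H_p,
        tau=best_tau,
        reconstruction_error=float(best_err),
        corner_gene_lists=genes,
        tau_table=single.tau_table,
        method=method,
    )
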