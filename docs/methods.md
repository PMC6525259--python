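# Methods

## Mixture model and assumptions

Observed bulk expression is modeled as `X = W·H (+ E)`: non-negative
cell-type signatures `W` (N genes × K types, linear scale) mixed by
proportions `H` (K × M, columns on the unit simplex). The method assumes

- linear mixing in non-log space (expression of a mixture is the
  proportion-weighted sum of pure profiles);
- proportions vary across samples (a cell type with constant fraction is
  unidentifiable from mixtures alone);
- at least a few more samples than cell types (M ≥ K + 1; in practice
  M ≳ 20 for stable corner geometry);
- strictly positive gene rows (zero rows are dropped before
  normalization).

No signature genes are required: identifiability comes from geometry, not
markers, although genes highly specific to one type sharpen the corners.

## Row normalization and the simplex

Dividing gene row `x_i` by its sum gives `x̃_i = Σ_k a_ik · h̃_k` where
`h̃_k` are the row-normalized rows of H and the weights `a_ik ≥ 0` sum
to 1 — every gene is a point inside a (K−1)-simplex whose corners are the
`h̃_k`. Two consequences drive the pipeline: genes specific to the same
type collapse onto the same corner (mutual linearity: their raw profiles
are proportional, and the proportionality constant cancels), and
recovering the corners recovers the proportions up to the DSA-like
rescaling below.

The simulators' additive `+1` term at noise SD = 0 (`2^N(0,0)` per entry)
is absorbed exactly by this algebra: since proportion columns sum to one,
`W·H + 1 = (W+1)·H`, so the "noiseless" benchmark is still an exact
rank-K mixture with shifted signatures.

## Mutual-linearity scores and gene filtering

For genes x, y the symmetric linearity is the mean of the two coefficients
of determination of the *identity* model on row-normalized profiles:
`R²(y|x) = 1 − Σ(ỹ−x̃)² / Σ(ỹ−mean(ỹ))²` and vice versa. No slope is
fitted — the line y = x is forced, which is what makes the score specific
to shared-proportion tracking; it can be negative. SS_tot uses deviations
from the dependent vector's mean. Edges exist where both the linearity and
the Spearman correlation are strictly positive; the weight is their
product. A gene's power is its total incident weight.

Significance: K_iter rounds shuffle the multiset of edge weights over the
fixed topology; `p = (Success + 1)/(K_iter + 1)` with Success counting
rounds whose sampled power is ≥ the actual power (ties count against the
gene, per the one-sided ≥ convention). Genes with p < α are kept.
Bonferroni mode divides α by N and enforces K_iter > N/α. The null has
power only when the edge-weight multiset is heterogeneous: in a degenerate
toy where all edges weigh exactly 1, every shuffle ties and nothing is
ever significant — a property the test suite asserts explicitly. The
two-threshold filter (≥ k₁ partners above t₁ and ≥ k₂ above t₂, negatives
zeroed; defaults 1/0.75 and 10/0.25) is the cheap deterministic
alternative for very large matrices.

Pairwise matrices are dense and blocked; at the default 15,000-gene
ceiling each matrix is ~1.8 GB in float64, and the pipeline holds two.

## Rank (cell-type number) estimation

The literal rule — smallest K whose cumulative explained variance
`α_i = σ_i²/Σσ_j²` reaches a threshold (default 0.95) — is exposed as
`estimate_num_cell_types`. Applied to a row-normalized matrix directly it
is misleading: all rows sum to one, so the first singular vector is the
simplex centroid and dominates the spectrum regardless of K. The pipeline
therefore applies the threshold rule to the *centered* gene-cloud
spectrum, whose rank is K−1 for a K-type mixture, and reports
K = (components reaching the threshold) + 1. Both the centered and raw
scree tables are attached to the results for inspection; with noisy data
the automatic K should be treated as a suggestion and overridden when
external knowledge exists (`k_types=`).

## Projection and back-projection

Genes (rows of the row-normalized matrix) are treated as points in
M-dimensional sample space. The basis is the K−1 leading left singular
vectors of the centered cloud, computed from the M × M Gram matrix
(identical to a full SVD to ~1e-8 relative on the leading components;
trailing near-zero singular values only to √machine-epsilon). The
projection is applied to the *non-centered* points. Back-projection is
`Bᵀy` **plus** the constant off-subspace component of the affine hull
(`center − BᵀB·center`): the centered basis is orthogonal to the all-ones
direction, so without this offset back-projected points would sum to zero
and could never be renormalized into proportions. Back-projected corner
rows are clipped at zero (warning below −1e-6) and renormalized to sum
to one.

## Corner identification

Minimum-volume simplex estimation in lifted (homogeneous) coordinates:
with `Ỹ = [Y; 1ᵀ]` and Q the inverse of the lifted corner matrix,
minimize

    f(Q) = −log|det Q| + tau · Σ max(−QỸ, 0)    s.t.  1ᵀQ = e_Kᵀ.

`QỸ` are barycentric coordinates, so the hinge charges points left outside
the simplex; small tau lets the simplex shrink past outliers (noise
tolerance), large tau forces enclosure. The solver:

1. VCA-style initializer — successive orthogonal projections picking
   extreme data points (also exposed as `method="vca"`; it can only return
   cloud members, which is exactly why it fails when signature genes are
   absent). The initial simplex is inflated by 5% about the centroid.
2. Successive linearization of the log-det with an ADMM splitting
   (Z = QỸ) for each convex subproblem; closed-form Q-updates enforce the
   affine constraint exactly; backtracking line search on the true
   objective guarantees descent.
3. A quasi-Newton polish: the hinge is smoothed by a softplus of width ε
   (continuation ε = 1e-2 → 1e-4 → 1e-6), the constraint is eliminated by
   optimizing a column-centered additive update, and L-BFGS refines Q.
   The refinement is kept only if it lowers the true objective. Without
   this stage the linearized iteration stalls a few percent of edge length
   short of the optimum.
4. Seeded random restarts (default 3) perturb the initializer; the best
   objective wins. Convergence: 1e-8 relative objective change, 80 outer
   iterations. Coincident corners are flagged as degenerate.

`method="mvsa"` reuses the solver with the hinge weight scaled ×1000 — a
near-hard-containment variant.

**Tau sweep.** Tau runs over `2^i, i = −20…0`. For each tau the corners
are scored by the reconstruction error of the induced factorization on the
matrix being deconvolved (the row-normalized filtered matrix in the
pipeline: scoring on the raw matrix over-weights bright genes and
empirically drags the selection toward over-large simplices). Each tau
also contributes its *enclosure refinement*: facets are translated outward
to the most violating point (`a' = (a − m)/(1 − Σm)` in barycentric
coordinates), the tau → ∞ limit of the soft penalty. Selection over all
candidates is purely by reconstruction error. On noiseless data the
enclosed candidate wins and recovery is exact to machine precision; on
noisy data enclosure chases outliers, its back-projected corners clip and
its error rises, so the raw SISAL corners win — no separate noise switch
is needed.

**Smart Corners** matches corner sets across tau runs (Hungarian
assignment on distances), enumerates per-corner tau combinations (grid
truncated to respect `max_combinations`, most promising taus first) and
keeps the best-scoring combination; the single-tau optimum is a member of
the search space, so the result never regresses.

Per corner, the `g_top` (default 100) nearest genes in projected space are
reported with distances — the de novo signature genes, suitable for
average-z-score annotation against a pure-profile reference compendium.

## DSA-like solve and signatures

Corner rows H_p (row-normalized proportion estimates) are rescaled by the
least-squares solution of `αᵀH_p = 1ᵀ` (pseudo-inverse; non-positive
components floored at 1e-12 with a warning — they indicate misplaced
corners); columns of `α_i·H_p` are then renormalized to sum exactly to
one, absorbing the residual. W solves `min_{W≥0} ‖X − W·H‖_F` by fast
combinatorial NNLS: one normal-equation solve for all genes, then an
active-set iteration in which genes sharing a passive set share a
factorization; genes that fail to settle within the iteration cap fall
back to the reference per-gene solver, so the result always satisfies the
NNLS optimality conditions (asserted against `scipy.optimize.nnls` at
1e-10 in the tests). By default W is solved on all preprocessed genes
using the H derived from filtered genes (`signature_genes="filtered"`
restricts it). Reconstruction error is the Frobenius norm of `X − W·H`.

## RNA-content correction

Deconvolution under the column-sum-one convention recovers **RNA
fractions**: the share of each sample's RNA contributed by each type. If
type i carries `c_i` RNA per cell, count fractions follow by
`(H_ij/c_i)/Σ_i(H_ij/c_i)` — the exact algebraic inverse of the forward
bias, invariant to rescaling c. Coefficients come from pure profiles as
the endogenous/ERCC-spike-in total-count ratio (replicates averaged,
reference type scaled to 1). Estimating c from mixtures without pure
samples is out of scope.

## Simulators and what they do (not) capture

`simulate_signatures` draws W entrywise as `2^N(6, 1.5)` (log2-normal);
`simulate_proportions` draws H columns from the flat Dirichlet — the
uniform distribution on the simplex; `simulate_mixture` adds independent
`2^N(0, SD)` noise per entry (kept literally at SD = 0, where it is the
constant 1 — see above). The RNA-content variant divides W's columns by
(1, 2, 3) and rescales sample columns to a common sum, mimicking
library-depth normalization; the base W is first rescaled to exactly equal
column sums so the true content coefficients are exactly (1, 1/2, 1/3)
(disable with `equalize_base_columns=False` for the raw recipe, where they
hold only to ~1.5% at 12,000 genes). `remove_signature_genes` drops genes
whose row-normalized signature norm is ≥ 0.85, producing clouds with empty
corners. `simulate_pure_profile_grid` mixes three simulated pure profiles
over a designed 33-sample proportion grid, mimicking controlled-mixture
benchmark experiments.

These generators reproduce the mixing algebra and a heavy-tailed additive
noise, but not platform effects real data carry: probe saturation,
batch structure, correlated (gene × sample) noise, within-type expression
heterogeneity, or compositional shifts between conditions. Passing the
simulation suite therefore demonstrates correctness of the geometry and
estimators, not performance on any particular platform.

## Numerical choices and edge cases

- Row normalization requires strictly positive row sums; offending genes
  are reported by id. Zero rows arising during preprocessing are dropped
  with a warning.
- Constant normalized profiles have undefined linearity (zero variance):
  scored NaN, never edges.
- Probe collapse keeps the probe with maximum average log-expression; exact
  ties go to the lexicographically smallest probe id.
- Quantile normalization uses the classical column-quantile-averaging
  dialect, ties receiving the mean reference value at their average rank.
- The dendrogram over filtered genes (1 − Pearson of linearity rows,
  average linkage) is cut at the 2–12-cluster solution maximizing mean
  silhouette, subject to a minimum cluster size; an all-identical block
  short-circuits to a single cluster.
- One global seed fans out to per-stage seeds via a CRC32 hash of the
  stage name, so stages are independently reproducible; a saved config
  re-run is bit-identical.
- Benchmark problem sizes used by the tests and the acceptance script:
  12,000 × 40 for noiseless, no-signature and RNA-content checks;
  4,000 × 40 for the SD = 4 noisy benchmark (the permutation filter and
  21-point tau sweep dominate runtime, and recovery behavior at 4,000
  genes matches the full size); 50 genes for null calibration.

## Known limitations

- The SD = 4 noise regime sits at the edge of identifiability: the
  permutation-filtered gene set still carries enough heavy-tailed noise
  that the cumulative-variance rule at 0.95 lands on K = 3 only for a
  minority of simulation draws (the unfiltered spectrum is always
  inconclusive, and proportion recovery with K fixed at 3 stays below
  0.1 RMSE). Automatic rank selection under heavy noise should be
  reviewed against the reported scree tables.
- The minimum-volume objective is non-convex; restarts mitigate but do not
  eliminate dependence on initialization for adversarial clouds.
- Corner accuracy on clean data is bounded by how closely the most
  type-specific genes approach the simplex facets (~1e-3 in proportion
  units at 10⁴ genes for log-normal signatures).
- Smart Corners is combinatorial; it is disabled beyond the
  `max_combinations` budget rather than approximated.
- K is assumed ≤ 15; the dense pairwise stage assumes ≤ 15,000 genes.
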