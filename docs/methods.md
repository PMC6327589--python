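# Methods

## Whitening family and the CCA solution

A whitening matrix for covariance `Σ = V^{1/2} P V^{1/2}` is any
`W = Q P^{-1/2} V^{-1/2}` with `Q` (semi-)orthogonal; the companion
matrices are the mixing matrix `Φ = Q P^{1/2} V^{1/2}` (with `Φᵀ = W^{-1}`
for square transforms) and the correlation-loadings `Ψ = Q P^{1/2}`, whose
squared entries per original variable sum to one.  Matrix square roots are
taken via the symmetric eigendecomposition (never Cholesky), because the
symmetric `P^{±1/2}` is what makes the family above well defined.
Eigenvalues are sorted descending with stable tie-breaking by original
index; in the PCA-cor rotation the eigenvector sign ambiguity is resolved
by flipping rows of `Q` so its diagonal is nonnegative.

CCA arises by choosing the rotations from the SVD of
`K = P_X^{-1/2} P_XY P_Y^{-1/2}`.  The per-component sign convention is:
`s_i = sign((Q_X)_ii)`, `t_i = sign((Q_Y)_ii)`, row `i` of each rotation is
scaled by its own sign, and `λ_i = s_i t_i d_i` where `d_i ≥ 0` are the
singular values.  Diagonal entries within round-off of zero (|·| ≤ 1e-12)
count as positive: without that tolerance a diagonal entry of magnitude
1e-16 — which occurs systematically in degenerate cases such as Y = X,
where all singular values tie — would flip signs arbitrarily.  For exactly
tied singular values the decomposition is not unique; the component order
of the underlying SVD is kept, and no claim is made that tied components
match other software.

Components are ordered by decreasing `|λ_i|` (the regression view ranks
them by `λ_i²`), ties keeping SVD order.  Fitting is location-invariant;
the fitted center is stored so that population-mode and data-mode agree.
Canonical correlations are invariant under positive rescaling of columns,
while directions scale inversely; a `standardize` flag z-scores the inputs
first (default on in the CLI, off in the library, since interpretation of
directions is easier in standardized units but silent rescaling is wrong
for a library primitive).

## Degenerate and singular inputs

`decompose_covariance` rejects non-positive variances, naming the
offending variable.  There is no canonical tolerance for declaring a
correlation matrix singular, so both behaviours are exposed: in strict
mode (used by the empirical estimator) eigenvalues below `1e-10 ×` the
largest raise an error that points at shrinkage estimation; in lenient
mode they are floored at that cutoff.  The empirical estimator also
refuses outright when `n ≤ max(p, q)`, since the empirical correlation
matrix is then rank-deficient by construction.

## Shrinkage estimation

The joint correlation matrix of the column-concatenated `[X | Y]` data is
shrunk toward the identity, `R* = λ_cor I + (1−λ_cor) R̂`, with the
analytic variance-minimizing intensity

    λ_cor = Σ_{i≠j} var̂(r_ij) / Σ_{i≠j} r_ij²,   clipped to [0, 1],

where, for ddof=1-standardized data `xs` and products `w_kij = xs_ki xs_kj`,
`r_ij = n/(n−1) · mean_k(w_kij)` and
`var̂(r_ij) = n/(n−1)³ · Σ_k (w_kij − w̄_ij)²`.  A zero denominator (all
off-diagonal correlations exactly zero) is defined as full shrinkage,
λ_cor = 1.  One joint intensity is estimated and reused for the X-block,
Y-block and cross-block, so the three shrunk blocks are sub-blocks of one
PSD matrix.  Variances are *not* shrunk: the unbiased empirical variances
form `V`, keeping the variance/correlation separation of the whitening
family intact.  No minimum-intensity floor is applied by default; an
optional floor promotes an exact zero to a configurable minimum for users
who need a strictly positive definite estimate.

The shrunk correlation is represented as `R* = λ_cor (I + U N Uᵀ)` with
`U` the right singular vectors of the standardized data (singular values
below `1e-12 × d_1` dropped) and `N_k = (1−λ_cor)/λ_cor · d_k²/(n−1)`.
Symmetric powers then reduce to
`R*^e = λ_cor^e (I + U ((I+N)^e − I) Uᵀ)`, so `R*^{-1/2} M` costs
`O(p·r·d)` with `r ≤ min(n−1, p)` and never allocates a `p×p` array.  The
intensity λ_cor = 0 is rejected in this representation (the identity part
vanishes and, below full rank, the estimate is singular); such users want
the empirical estimator.  The dense small-`p` reconstruction
`λI + (1−λ)R̂` serves as the in-repo oracle pinning the two code paths to
each other.  The low-rank path is selected automatically when
`n ≤ max(p, q)` and can be forced either way; both paths agree to ~1e-8,
which is also the tolerance used in the cross-path tests.

## Regression view

The best linear predictor of `Y` from `X` has `b = Σ_X^{-1} Σ_XY`,
`a = μ_Y − bᵀμ_X`, and improves the predictive MSE by
`Δ = Tr(Σ_YX Σ_X^{-1} Σ_XY)` over the intercept-only model.  Between
CCA-whitened vectors `b` is `diag(λ_i)`, and `Δ = Σ λ_i² = Tr(KᵀK)`; these
identities are asserted in the tests at 1e-8–1e-10.

## Generative model and simulator

Level-1 latents are i.i.d. mean-0 variance-1 (Gaussian, or t(df) rescaled
by `√((df−2)/df)` with df > 2 required; default df = 5 gives a visibly
heavy tail while keeping fourth moments finite for the variance checks).
Level 2 mixes them with weights `√(1−|λ_i|)` and `√|λ_i|` (shared part
signed by `sign(λ_i)`; components beyond `m` are non-shared), which by
construction yields unit variances and `cov(X̃_i, Ỹ_i) = λ_i`.  Level 3
colors and translates: `X = Φ_Xᵀ X̃ + μ_X`, so `var(X) = Φ_Xᵀ Φ_X`.

The benchmark synthetic design is `p = 60`, `q = 10`, identity within-set
covariances, and cross-covariance `diag(λ_i)` with alternating signs
`+λ, −λ, …` for `λ ∈ (0, 1)` — realized through the generative model with
identity mixing, which is an equivalent construction of the corresponding
multivariate normal.  One global seed expands into counter-based
per-replicate substreams (`numpy.random.SeedSequence.spawn`), so
experiments are reproducible and order-independent.

**Scoring sign recovery.**  In this design all ten true `|λ_i|` are equal,
so truth and estimate cannot be paired by magnitude rank: under sampling
noise the fitted components are arbitrary rotations within the
near-degenerate subspaces, and any index-based pairing would score ~50%
even for perfect fits.  Instead, a fitted component's sign counts as
correct when `sign(λ̂_i)` equals the sign of the *population* correlation
of its own estimated canonical variates under the true moments,
`sign(ŵ_X,iᵀ Σ_XY ŵ_Y,i)` — the direct meaning of "the sign of the
association between this pair of canonical variates was estimated
correctly", needing no pairing at all.  Proportions are pooled per
component across replicates (not per-dataset majorities).  Where the true
`|λ_i|` are distinct (the parameter-recovery check), truth and estimate
*are* paired by magnitude rank, both sorted descending.

The experiment defaults to 500 replicates per `(n, λ)` cell; the automated
checks use 100 replicates and two cells — (λ=0.9, n=500) and (λ=0.5,
n=20) — which keeps the whole suite in seconds while leaving the
Monte-Carlo standard error of a pooled proportion near 1%.

**What the simulator does not emulate.**  Real omics tables have blockwise
within-set correlation, non-Gaussian marginals (counts, compositions),
batch structure and missingness; the synthetic design has none of these
(identity within-set covariance, clean Gaussian or t latents).  Passing
the simulation checks therefore demonstrates correctness of the estimator
and of sign recovery under the stated model, not robustness to real-data
pathologies.  The nutrimouse analysis (real measurements, n=40 < p=120) is
the complementary check that the full pipeline reproduces published
reference values on actual data: joint intensity 0.16, 16 of 21 negative
canonical correlations, λ range [−0.96, 0.87].

## Parameter-recovery settings

The round-trip check simulates `λ = (0.9, −0.7, 0.5, −0.3, 0)` at
`n = 10^5` with dimensions `p = 8`, `q = 5` and random diagonally-dominant
mixing matrices (`standard normal + 3I`, keeping the coloring well
conditioned so the check isolates estimation rather than conditioning).
Sampling error of a correlation at this `n` is ~0.003, comfortably inside
the 0.02 acceptance margin.

## I/O and CLI conventions

Tables are CSV/TSV with a header and a first column of unique sample IDs;
missing or non-numeric cells are rejected rather than imputed.  Samples
are inner-joined on IDs preserving the X table's order, requiring at least
3 common samples.  All numeric output uses 12 significant digits so reruns
can be compared byte-for-byte; rerunning a fit with the same inputs
produces byte-identical numbers.  Reported `λ` are signed by default; a
`--nonnegative` flag absorbs each sign into the corresponding Y direction
(and Y scores/loadings) for comparison with classical software.

## Known limitations

- The shrinkage intensity is estimated once from the joint matrix; no
  per-block intensities, and no alternative regularizers (a user-supplied
  intensity is the escape hatch).
- No inference: no permutation p-values or confidence intervals for the
  canonical correlations.
- Sparse or Bayesian canonical directions are out of scope.
- For exactly tied singular values, component identity (not the fitted
  subspace) is implementation-defined.
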