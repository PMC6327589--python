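# whitecca

Canonical correlation analysis (CCA) for two-table data integration —
gene expression against lipid concentrations, methylation levels, or any
pair of numeric feature tables measured on the same samples — formulated as
a *whitening transformation* rather than the classical generalized
eigenproblem.

## The model

For random vectors `X` (dim `p`) and `Y` (dim `q`) with correlation blocks
`P_X`, `P_Y`, `P_XY` and variances `V_X`, `V_Y`, every whitening (sphering)
matrix has the form `W = Q P^{-1/2} V^{-1/2}` with a free rotation `Q`.
CCA is the one member of this family that is fully determined by the data:
the singular value decomposition of the correlation-adjusted
cross-correlation matrix

```
K = P_X^{-1/2} P_XY P_Y^{-1/2} = Q_X' Λ Q_Y        (Λ = diag(λ_1, …, λ_m))
```

yields the rotations `Q_X` (m×p) and `Q_Y` (m×q), `m = min(p, q)`, and the
canonical correlations `λ_i`.  The rows of `W_X = Q_X P_X^{-1/2} V_X^{-1/2}`
and `W_Y` are the canonical directions; projecting centered data on them
gives the canonical scores.

Two things distinguish this formulation from classical CCA:

* **Signed canonical correlations.**  The per-component sign ambiguity of
  the SVD is fixed by requiring both rotations to have a nonnegative
  diagonal (the minimal rotation, closest to the identity) and absorbing
  the signs into the `λ_i`.  The `λ_i` are then exactly the regression
  coefficients of the multivariate linear model between the CCA-whitened
  vectors, so a negative `λ_i` reports an inverse association — information
  the classical all-positive convention throws away.  `Δ = Σ λ_i² =
  Tr(KᵀK)` is the resulting decrease in predictive mean squared error, and
  `λ_i²` ranks the components by predictive importance.
* **A generative interpretation.**  The package includes the matching
  two-layer latent-variable model: unit-variance latents `Z^X`, `Z^Y`,
  `Z^shared` are mixed as `X̃_i = √(1−|λ_i|) Z^X_i + √|λ_i| Z^shared_i`
  (and `Ỹ_i` likewise, with `sign(λ_i)` on the shared part), then colored
  and translated into the observations via the mixing matrices `Φ`.  The
  signed `λ_i` are direct model parameters; the latents may be Gaussian or
  rescaled-t (heavy-tailed).

For `n ≪ p, q` the correlation matrices are estimated by analytic shrinkage
toward the identity, `R* = λ_cor I + (1−λ_cor) R̂`, with the
variance-minimizing intensity computed from the data.  `R*` is held in the
low-rank form `λ_cor (I + U N Uᵀ)`, and products such as `R*^{-1/2} M` are
computed in `O(p·r·d)` without ever materializing a `p×p` matrix, so fits
with thousands of variables and tens of samples are cheap.

## Worked example

Simulate the identity-covariance benchmark design — `p = 60`, `q = 10`,
within-set correlations zero, true canonical correlations alternating
`+0.7, −0.7, …` — and refit with shrinkage estimation:

```python
import numpy as np
from whitecca import simulate_synthetic_design, cca_fit, delta_mse

(X, Y), = simulate_synthetic_design(n=1000, lam=0.7, seed=42)
model = cca_fit(X, Y, estimator="shrinkage")
print("shrinkage intensity:", round(model.estimator_meta["lambda_shrink"], 4))
print("signed canonical correlations:", np.round(model.lambdas, 3))
print("predictive MSE reduction:", round(delta_mse(model.lambdas), 3))
```

prints

```
shrinkage intensity: 0.3322
signed canonical correlations: [ 0.532 -0.517  0.513 -0.498  0.493 -0.465  0.463 -0.458 -0.438 -0.434]
predictive MSE reduction: 2.326
```

Both signs are recovered, and the magnitudes are pulled toward zero by the
shrinkage (the price of a stable estimate at `p + q = 70` dimensions).
Because the ten true `|λ_i|` are equal in this design, the fitted
components mix the near-degenerate true components, so the positive /
negative split need not be exactly 5/5; each fitted sign is still the
correct sign of the association between its own pair of canonical variates.

The same analysis from the shell, writing a TSV/JSON bundle
(canonical correlations, directions, scores, correlation loadings):

```
whitecca simulate --n 1000 --lam 0.7 --seed 42 --out sim
whitecca fit --x sim/X_rep1.tsv --y sim/Y_rep1.tsv --estimator shrinkage --out cca_out
```

`whitecca signsim` runs the full Monte-Carlo sign-recovery experiment over
grids of `n` and `λ`.

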