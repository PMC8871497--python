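# Methods

## Model

`fkmr` fits a semi-parametric scalar-on-multiple-functions regression

    y_i = x_i' beta + h(gamma o z_i) + eps_i,      eps_i ~ N(0, sigma^2),

where `z_i` stacks the probit-transformed functional principal component
(FPC) features of `p` functional predictors (group `l` contributes `s_l`
features, `s = sum s_l` in total), `h` lives in the reproducing kernel
Hilbert space of a Gaussian kernel, and `gamma` is a non-negative-garrote
scaling vector applied to the features inside the kernel.  A zero entry of
`gamma` removes a feature from the kernel; a zero group removes the whole
functional predictor.  Estimation minimizes the penalized representer
objective

    J2(alpha, beta, gamma) = (1/2n) ||Y - X beta - K(gamma) alpha||^2
                             + (lambda1/2) alpha' K(gamma) alpha
                             + lambda2 rho(gamma; delta),

with `[K(gamma)]_ik = exp(-(1/s) sum_j gamma_j^2 (z_ij - z_kj)^2)` and the
sparse-group-lasso penalty
`rho(v; delta) = (1 - delta) sum_l ||v_l||_2 + delta ||v||_1`
(`delta = 0` is the group lasso, `delta = 1` the lasso; MCP and group-MCP
composites are also available).  The bandwidth denominator is held fixed at
the total feature count `s`: the garrote scales and the bandwidth are not
jointly identifiable, so all adaptivity in kernel sharpness is carried by
`gamma`.

## Feature extraction

Curves observed on a common dense grid are decomposed by eigendecomposition
of the sample covariance under trapezoid quadrature (`FPCA`).  Scores are
standardized by the square root of the eigenvalues (floored at 1e-12) and
mapped to (0, 1) by the standard-normal CDF.  Eigenfunction signs are fixed
by requiring a positive quadrature integral (largest-magnitude value
positive on near-zero integrals), which makes the decomposition
deterministic; a sign flip only relabels `zeta` as `1 - zeta` and the
downstream model refits, so accuracy is unaffected.  FPCA is estimated on
training subjects only; new subjects are projected on the training mean and
eigenfunctions.  This dense-design estimator intentionally omits the
covariance smoothing used by sparse-design FPCA software: the intended
inputs are densely sampled curves (e.g. 100 points, or minute-epoch
accelerometer summaries) where smoothing adds nothing.

## Fitting

At fixed `gamma` the problem is a least-squares kernel machine, equivalent
to the linear mixed model `Y = X beta + h + eps`, `h ~ N(0, tau K)`, with
`lambda1 = sigma^2 / (n tau)`.  `reml_fit` eigendecomposes `K` once and
maximizes the restricted likelihood over `log(theta)`, `theta = tau/sigma^2`,
on [-12, 12] with bounded Brent iterations (`xatol` 1e-8), then recovers
`beta` (GLS), `alpha = theta (theta K + I)^{-1} (Y - X beta)` and `lambda1`.
A kernel that is numerically a multiple of the identity triggers a
degeneracy warning; boundary fits are flagged as "no kernel effect".

At fixed `(beta, alpha, lambda1)` the `gamma` subproblem is equivalent to
penalized least squares on `F(gamma) = K(gamma) alpha` against the pseudo
response `Ytil = Y - X beta - (n lambda1/2) alpha`.  Each proximal
Gauss-Newton iteration linearizes `F` at the current point, solves the
resulting sparse-group problem by FISTA (step `1/L`, `L` the squared
spectral norm of the design over `n`; plain proximal gradient for the
concave MCP families), and step-halves toward the reference point until the
exact subproblem objective does not increase — this enforces the descent of
`J2` that the alternation relies on.  Inner iterations stop at relative
`gamma` change below 1e-4 (cap 50); a step that fails 30 halvings keeps the
reference point and flags the update as stalled.

Two orchestrations are provided.  The default fast scheme (`algorithm=2`)
runs REML once at `gamma = 1`, performs one CV-tuned `gamma` update, and
re-solves the kernel machine at the selected support.  The full scheme
(`algorithm=1`) alternates the two steps to convergence for every pair on a
`(lambda1, lambda2)` grid and picks the pair by K-fold prediction error.

### Choosing lambda2

Cross-validating the linearized subproblem directly is not meaningful: its
design (the gradient of `F`) and response both depend on `alpha`, which was
fitted to *all* training subjects, so every held-out fold has already seen
its own outcomes through `alpha` and the apparent CV error decreases
monotonically in model size.  `FKMRRegressor` instead holds out 20% of the
training subjects and, for each candidate `lambda2` on a log-spaced path
(12 points from the zero-solution bound down to 1e-5 of it), re-runs the
full pipeline on the remaining 80% — kernel solve at `gamma = 1`, full
Gauss-Newton update restarted from `gamma = 1` (exact zeros are absorbing
under the update map, so warm starts down the path would lock features
out), REML re-solve at the updated `gamma` — and scores held-out prediction
MSE.  The selected value is the largest `lambda2` within 2% of the minimum
error: the error curve is flat across a wide plateau and then rises steeply
once noise features enter, so near-ties are resolved toward the sparser
model.  Path evaluation stops early once the error has doubled past its
minimum.

### Global kernel scale

With the bandwidth denominator fixed at `s`, a fit in which only a few
features survive leaves the kernel nearly flat, and the Gauss-Newton update
— which holds `alpha` fixed — stalls in the corresponding basin with
`||gamma|| ~ 1`.  The overall sharpness along the ray `c * gamma` is a
one-dimensional lengthscale-type parameter that the restricted likelihood
identifies cleanly: it rises to an interior optimum and collapses beyond it
as the kernel approaches the identity.  The final kernel-machine re-solve
therefore profiles `c` over a log grid (1 to 32, 11 points) by REML on a
400-subject subsample before the full-data REML refresh.  Rescaling never
changes the support of `gamma`, hence never changes the selection sets; it
substantially improves the recovery of `h` when few features survive.

### Null guard

At `gamma = 1` the restricted likelihood-ratio statistic for `tau = 0` is
computed (under the null it is a 50:50 mixture of 0 and chi-square(1); the
5% point is 2.71).  If the kernel variance component is not significant,
the garrote sets `gamma = 0` and no feature is selected.  Without this
guard a pure-noise outcome keeps `gamma ~ 1`: `tau` is estimated tiny but
positive, the penalty path degenerates, and every group would count as
"selected" despite a vanishing kernel effect.

## Synthetic data

The generator reproduces the two study designs used throughout the tests.
Functional predictors are Karhunen-Loeve sums over the orthonormal Fourier
system on [0, 1] (`phi_1 = 1`, then sin/cos pairs), with scale coefficients
`varsigma_j = 45 * 0.64^j` multiplying iid standard-normal scores, sampled
on 100 equally spaced points jittered by N(0, 0.001), clipped and sorted
(one common grid per replicate).  Features are `zeta = Phi(xi)`; the
outcome is `y = 2x + h(zeta) + eps` with `x, eps ~ N(0,1)`.  Scenario 1:
one predictor, 15 components, signals `zeta_2, zeta_9` in a cosine/sine
model.  Scenario 2: four predictors, 9 components each, five signals
(`zeta_11, zeta_31, zeta_41` of predictor 1; `zeta_22, zeta_72` of
predictor 2) entering a strongly nonlinear, non-additive model.  Subjects
split 75/25 into train/test in simulation order (paths are iid).

The generator draws noiseless curves on a dense common grid; real
accelerometer data add measurement noise, irregular sampling, and
within-subject dependence that the simulations do not emulate, so passing
tests certify the estimation machinery, not robustness to those features.
Because `varsigma_j` multiplies unit-variance scores, the covariance
eigenvalues are `varsigma_j^2` and the leading component carries
`1 - 0.64^2 ~ 0.59` of the curve variance.

## Evaluation

Accuracy is reported on the held-out quarter as quasi-R^2
(`1 - SSE/SST`) and its size-adjusted version with
`k = (#selected features) + (#scalar covariates)`.  Surface recovery is
summarized by regressing the true `h` (centered — the kernel machine
absorbs its level) on the estimated kernel part at the test design points:
intercept near 0, slope near 1 and R^2 near 1 indicate good recovery.
`replicate_study` repeats simulate / FPCA / fit / evaluate over seeded
replicates (replicate `r` uses generator seed `seed + r`; method-internal
CV seeds derive from `(seed, r)`, so all methods see identical data) and
aggregates means and selection frequencies.  The linear baselines fit
`y ~ x + zeta` with the same penalty families, standardized feature
columns, and an unpenalized intercept and covariate block.  Oracle variants
fit on the true `zeta` (group-MCP) or run an unpenalized kernel machine on
the true signal features only.

## Numerical choices and problem sizes

* Selection threshold on `|gamma|`: 1e-6.  SGL default `delta = 0.05`
  (group-dominant); MCP concavity `a = 3`.
* Gram matrices are symmetrized and their diagonals clipped to 1; `K` gets
  a 1e-10 jitter before factorization.
* `gamma` is unconstrained in the solver (the kernel depends on
  `gamma_j^2` and the penalties are symmetric); the reported `gamma` is
  `|gamma|`.
* The replicate study used for the packaged acceptance checks runs 20
  replicates of Scenario 2 at n = 1000 (750 train / 250 test); per-replicate
  Monte-Carlo spread of the summary means is well inside the tolerances
  asserted in the tests.
* Neither algorithm is guaranteed to reach a global minimizer of the
  non-convex objective; the descent property along the trace and the
  profiled scale step are safeguards, not guarantees.

## Known limitations

* Dense, commonly gridded curves only — no sparse/irregular FPCA.
* Gaussian outcomes only; a single kernel effect (no additive per-group
  kernels); no per-group bandwidths.
* The `gamma` update's selection behavior is tied to the validation-split
  tuner; with very small training sets (n below ~150) the split becomes
  noisy and a fixed `lambda2` may be preferable.
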