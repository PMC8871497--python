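# fkmr — functional kernel machine regression with sparse feature selection

`fkmr` models a nonlinear, **non-additive** relationship between a scalar
outcome and several functional predictors (densely sampled curves such as
wearable-device activity counts) in the presence of scalar covariates, and
simultaneously selects which functional predictors — and which features
within them — matter.  It is aimed at biostatisticians analyzing
scalar-on-function regressions where additive-per-component models are too
restrictive.

## The model

Each functional predictor is reduced by functional principal component
analysis; the standardized scores are probit-transformed onto (0, 1) and
stacked into a grouped feature vector `z in R^s` (one contiguous group per
functional).  The regression is

    y_i = x_i' beta + h(gamma o z_i) + eps_i,

where `h` lies in the RKHS of a Gaussian kernel
`K(u, v) = exp(-||u - v||^2 / s)` and `gamma >= 0` is a non-negative-garrote
scaling vector inside the kernel: `gamma_j = 0` deletes feature `j`, and a
whole zero group deletes its functional predictor.  Estimation minimizes

    (1/2n) ||Y - X beta - K(gamma) alpha||^2
        + (lambda1/2) alpha' K(gamma) alpha + lambda2 rho(gamma; delta),

with the sparse-group-lasso penalty
`rho(v; delta) = (1-delta) sum_l ||v_l||_2 + delta ||v||_1` (group lasso,
lasso, MCP and group-MCP variants are available).  For fixed `gamma` the
problem is a least-squares kernel machine, solved through its linear
mixed-model form with `lambda1` estimated by REML; for fixed `(beta, alpha)`
the `gamma` update is a proximal Gauss–Newton iteration on a linearized
sparse-group problem with a step-halving descent safeguard.  See
`docs/methods.md` for the full account.

## Worked example

Simulate the built-in four-predictor scenario (n = 1000, five signal
features spread over the first two functional predictors, true covariate
effect 2), fit FKMR with the SGL penalty, and evaluate on the held-out
quarter:

```python
import numpy as np
from fkmr import (ScenarioConfig, simulate_dataset, fit_fpca,
                  build_feature_blocks, FKMRRegressor)
from fkmr.evaluate import quasi_r2, adjusted_quasi_r2, concordance_regression

ds = simulate_dataset(ScenarioConfig(scenario=2, n_subjects=1000, seed=1))
tr, te = ds.train_index, ds.test_index
fpcas = [fit_fpca(c[tr], ds.grid, n_components=9) for c in ds.curves]
Ztr = build_feature_blocks([f.features_ for f in fpcas]).matrix
Zte = build_feature_blocks([f.transform(c[te])
                            for f, c in zip(fpcas, ds.curves)]).matrix

model = FKMRRegressor(group_sizes=(9, 9, 9, 9), penalty="sgl", random_state=1)
model.fit(np.hstack([ds.x[tr][:, None], Ztr]), ds.y[tr])

X_test = np.hstack([ds.x[te][:, None], Zte])
rq2 = quasi_r2(ds.y[te], model.predict(X_test))
k = len(model.selected_features_) + 1
h = ds.true_h[te]
_, slope, r2 = concordance_regression(h - h.mean(), model.predict_h(X_test))
print("selected groups:   ", list(model.selected_groups_))
print("selected features: ", list(model.selected_features_))
print("beta_x: %.3f" % model.beta_[0])
print("test quasi-R2: %.3f   adjusted: %.3f"
      % (rq2, adjusted_quasi_r2(rq2, 250, k)))
print("concordance slope: %.3f   R2: %.3f" % (slope, r2))
```

Output:

```
selected groups:    [0, 1]
selected features:  [0, 2, 3, 10, 15]
beta_x: 1.827
test quasi-R2: 0.950   adjusted: 0.949
concordance slope: 1.005   R2: 0.956
```

The fit selects exactly the two signal functionals (groups 0 and 1) and the
five true signal features (`zeta_1, zeta_3, zeta_4` of the first predictor,
`zeta_2, zeta_7` of the second; 0-based indices above), recovers the
covariate effect near its true value 2, explains ~95% of held-out outcome
variance, and reproduces the surface `h` almost perfectly (slope ~ 1,
R² ~ 0.96 when regressing the true `h` on the estimate).

`FKMRRegressor` and the companion `FPCA` transformer and
`PenalizedLinearModel` baseline follow scikit-learn conventions
(`fit`/`predict`/`transform`, `get_params`, trailing-underscore fitted
attributes), so they compose with sklearn pipelines and model selection.

A CLI covers the same workflow from the shell:

```sh
fkmr simulate --scenario 2 --n 1000 --seed 7 --out data/
fkmr fpca --curves data/curves.csv --n-components 9 --out data/features.csv
fkmr fit --features data/features.csv --scalars data/scalars.csv \
         --groups 9,9,9,9 --penalty sgl --seed 1 --out fit.json
fkmr replicate --scenario 2 --methods fkmr:sgl,lm:sgl --reps 20 \
               --n 1000 --seed 42 --out tables/
```

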