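# downwood

Spatially varying coefficient models for the occurrence and abundance of
down wood (wind-felled or broken stems) in point-referenced forest
inventory data.

Forest stands respond to their local terrain and structure: the same
increase in stand density or slope can raise the chance of windthrow in
one part of a reserve and lower it in another. Global regression models
average these relationships away. This package implements a three-stage
model ladder for a binary occurrence response (ODW) and a count response
(NDW, stems/ha) observed at projected planar locations with five
stand/terrain covariates (living-tree density NLT, canopy closure, mean
height H, slope, mean diameter DBH):

1. **Global GLMs** — logistic and Poisson regression by maximum
   likelihood (IRLS with step-halving), with bidirectional stepwise
   covariate selection on Wald p-values (α = 0.05):

   logit P(y_i = 1) = β₀ + Σₖ βₖ x_ik,    log E(Y_i) = β₀ + Σₖ βₖ x_ik

2. **Geographically weighted regression (GWLR / GWPR)** — a local ML fit
   at every location i, with observation j weighted by a Gaussian or
   bisquare kernel K(d_ij / b). The bandwidth b (fixed metric or adaptive
   nearest-neighbor) is selected by minimizing the corrected AIC,
   AICc = deviance + 2·enp + 2·enp·(enp+1)/(n − enp − 1), where enp is
   the trace of the Fisher-scoring hat matrix:

   logit P(y_i = 1) = β₀(u_i, v_i) + Σₖ βₖ(u_i, v_i) x_ik

3. **Geographically neural-network-weighted regression (GNNWLR /
   GNNWPR)** — a spatially weighted neural network (SWNN) maps each
   location's vector of distances to the training locations onto one
   weight per coefficient, which multiplies the frozen global ML
   coefficients inside the link:

   η_i = Σₖ βₖ · wₖ(u_i, v_i) · x_ik,    w(u_i, v_i) = SWNN([d_i1, …, d_in])

   The SWNN (fully connected, LeakyReLU, dropout, linear output) is
   trained with minibatch Adam on a Huber loss computed on the response
   scale, with early stopping on validation MAE.

Diagnostics cover R², RMSE, MAE, per-class accuracy for the binary
models, global Moran's I with a randomization Z-test, and residual
correlograms over 300-m distance bands. Because the original survey data
are not public, a calibrated synthetic-study generator reproduces the
study's structure (443 units, 355/88 train/validation split, published
covariate marginals, smooth non-stationary coefficient surfaces) and
doubles as a parameter-recovery harness.

## Worked example

```python
import numpy as np
from downwood import (
    generate_default_study, split_train_validation, standardize,
    fit_glm, predict_glm, select_bandwidth, fit_gwr_glm, predict_gwr,
    train_gnnwr, predict_gnnwr, regression_metrics, first_lag_moran,
)
from downwood.gnnwr import SWNNConfig, TrainConfig

ds, truth = generate_default_study(seed=1)
train, val = split_train_validation(ds, 355, seed=1)
train_std, params = standardize(train)
val_std, _ = standardize(val, params)
y_val = val_std.response("ndw")

glm_fit = fit_glm(train_std, "poisson")
print("global beta:", np.round(glm_fit.beta, 3))
print("global val R2:", round(regression_metrics(y_val, predict_glm(glm_fit, val_std.X)).r2, 3))

spec = select_bandwidth(train_std, "poisson")
gw_val = fit_gwr_glm(train_std, "poisson", spec, targets=val_std.coords)
print("GWPR bandwidth (m):", round(spec.bandwidth))
print("GWPR val R2:", round(regression_metrics(y_val, predict_gwr(gw_val, val_std.X)).r2, 3))

nn_fit = train_gnnwr(
    train_std, val_std, "poisson",
    swnn_cfg=SWNNConfig(input_dim=355, hidden=(96, 64), dropout=0.2, output_dim=6),
    train_cfg=TrainConfig(learning_rate=0.002, batch_size=32, max_epoch=400,
                          patience=60, seed=1),
)
pred = predict_gnnwr(nn_fit, val_std.coords, val_std.X)
print("GNNWPR val R2:", round(regression_metrics(y_val, pred).r2, 3))
print("residual Moran z:", round(first_lag_moran(y_val - pred, val_std.coords).z_value, 2))
```

prints (seed 1):

```
global beta: [ 2.303 -0.379  0.147 -0.137 -0.026  0.134]
global val R2: 0.107
GWPR bandwidth (m): 1041
GWPR val R2: 0.874
GNNWPR val R2: 0.909
residual Moran z: -0.64
```

The global Poisson model explains almost none of the held-out count
variation because the true coefficients vary over space; the local models
recover most of it, and the GNNWPR residuals show no first-lag spatial
autocorrelation (|z| < 1.96).

The same pipeline is available from the shell:

```sh
downwood --seed 1 simulate --out data.csv --truth truth.csv
downwood --seed 1 fit --model gwpr --data data.csv --out-prefix run
downwood correlogram --data data.csv --predictions run_gwpr_predictions.csv \
    --response ndw --out correlogram.csv
```

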