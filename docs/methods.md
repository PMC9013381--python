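# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Models

All three model stages share the same observation model: a binary
occurrence indicator follows a Bernoulli distribution through the logit
link, and a count response follows a Poisson distribution through the log
link, with five standardized stand/terrain covariates plus an intercept
(k + 1 = 6 coefficients).

**Global GLM.** Maximum likelihood via iteratively reweighted least
squares (IRLS) with step-halving: whenever a Fisher-scoring step would
decrease the log-likelihood, the step is halved (up to 30 times), so the
likelihood trace is non-decreasing. Convergence is declared when the
relative log-likelihood change or the infinity norm of the score drops
below 1e-8, within 100 iterations. Logistic fits whose fitted
probabilities are fully degenerate (all events above 1 − 1e-6, all
non-events below 1e-6) with very large coefficients are flagged as
non-converged with a complete-separation diagnostic rather than reported
as estimates. The covariance of the estimates is the inverse observed
Fisher information; stepwise selection runs bidirectionally on Wald
z-test p-values (add the smallest p < α, drop any retained p ≥ α, iterate
to a fixed point, lexicographic tie-break) with α = 0.05 by default.

**GWLR / GWPR.** At each target location the same IRLS core is run with
kernel observation weights, warm-started at the global fit. Two kernels
are provided — Gaussian exp(−½(d/b)²) and bisquare (1 − (d/b)²)² with
compact support — in fixed (metric bandwidth, meters) or adaptive
(bandwidth = neighbor rank; the metric bandwidth at a location is the
distance to its b-th nearest training point) mode. The default is a fixed
Gaussian kernel. The effective number of parameters is the trace of the
Fisher-scoring hat matrix at convergence,
S_ii = x_iᵀ (Xᵀ G_i X)⁻¹ x_i g_ii with G_i the product of kernel and IRLS
working weights, and the deviance is −2× the log-likelihood of the
per-location predictions. Bandwidth selection minimizes
AICc = deviance + 2·enp + 2·enp(enp+1)/(n − enp − 1) by golden-section
search between the 1st percentile and the maximum pairwise training
distance (the AICc profile is treated as approximately unimodal; an
explicit grid can be supplied instead). Out-of-sample prediction refits
the local model at each validation coordinate using training data only.

**GNNWLR / GNNWPR.** The local linear predictor multiplies the *frozen*
global ML coefficients by location-specific weights,
η_i = Σ_k β_k · w_k(u_i, v_i) · x_ik (x_i0 = 1), where the weight vector
is the output of a spatially weighted neural network applied to the
vector of distances from location i to the training locations, normalized
by the maximum pairwise training distance. With every weight equal to 1
the model is exactly the global GLM; the network learns departures from
stationarity. Note the weights enter the linear predictor, not the
response: this is the only reading under which the intercept weight w₀
and the diagonal weight matrix are meaningful, and it makes the
stationary model an exact special case.

The SWNN is a plain fully connected stack with LeakyReLU (negative slope
0.01) and inverted dropout after every hidden layer and a *linear* output
layer, so weights may be negative. Published default architectures:
hidden widths 512/512/256/128/64 with dropout 0.2, learning rate 0.0005,
batch size 10 for the binary model; 512/128/64/32, dropout 0.2, learning
rate 0.0008, batch size 20 for the count model; maximum 20 000 epochs for
both. Hidden layers use He-normal initialization; the output layer starts
at zero weights with unit offsets, so training begins exactly at the
stationary global model — a neutral, reproducible starting point.

Training minimizes a Huber loss (δ = 1.0 by default) between the observed
response and the predicted mean on the response scale (label vs
probability; count vs mean), the same criterion for both families, by
minibatch Adam with global-norm gradient clipping at 5 (the exponential
link can produce transiently large gradients). After every epoch the
validation MAE is computed in evaluation mode (dropout off); training
stops at the epoch cap or after `patience` epochs (default 500) without
improvement, and the returned model is the checkpoint with the best
validation MAE. All randomness (initialization, batch order, dropout)
derives from the training seed, so histories are bit-identical across
runs on one platform. The linear predictor is clipped at ±30 before the
inverse link purely as numerical overflow protection.

## Diagnostics

R² = 1 − SS_res/SS_tot, RMSE and MAE are computed on the response scale
for both families (for a balanced binary response this puts RMSE near
0.5 for an uninformative model, which is the natural scale for comparing
the two model families side by side). Per-class accuracy thresholds the
predicted probability at 0.5; an absent class yields an undefined (NaN)
accuracy, never zero.

Global Moran's I uses an arbitrary non-negative weight matrix with zero
diagonal; the Z-value is computed under the randomization (permutation)
variance, which requires n ≥ 4, against the null expectation −1/(n − 1),
with 1.96 as the two-sided 5% critical value. Residual correlograms use
binary distance-band weights on contiguous half-open bins of 300 m
(matching the survey's average inter-unit distance); the headline
single-number statistic is the first band [0, 300 m). Empty or degenerate
bins are reported with a pair count and an undefined statistic rather
than dropped. Local-coefficient tables report Mean, Min, Q1, Median, Q3,
Max per coefficient with linear-interpolation quantiles.

## Synthetic-data generator

The generator emulates the survey's statistical structure:

- **Coordinates** uniform over a 10 km × 10 km square — large enough that
  300-m lag bins yield a multi-bin correlogram, comparable to the actual
  reserve's extent.
- **Covariates** drawn from truncated normals with the published
  (min, mean, sd, max) per column, then mildly smoothed toward the mean
  of the 5 nearest neighbors (mixing fraction 0.3) to create gentle
  spatial trends. An affine moment correction afterwards restores the
  target mean and sd (truncation biases the mean, smoothing shrinks the
  sd), followed by re-clipping to the published bounds.
- **Coefficient surfaces** are mixtures of six signed Gaussian bumps with
  a 3-km length-scale, normalized on a 50×50 grid so a surface with mean
  m and amplitude a has grid mean m and grid sd a. Amplitude 0 yields a
  stationary coefficient.
- **Responses** are Bernoulli/Poisson draws through the logit/log links
  from separate surface models for occurrence and count (they are modeled
  separately downstream); an optional switch instead derives occurrence
  as 1[count > 0] for users who want the strict empirical coupling.
- **Calibration.** The default intercept levels (0.22 logistic, 1.92
  Poisson) were chosen from the lognormal/logit-normal moment
  relationships so that the ensemble mean count is ≈ 12.6 stems/ha and
  the occurrence share ≈ 0.54, matching the published response moments;
  the surface amplitudes place the dominant spatial signal on the
  intercept and the living-tree-density effect. A convenient side effect
  of the non-stationary log-intercept is count overdispersion (sd ≈ 20 at
  mean ≈ 12.6), in line with the published summary statistics.

What the generator does **not** emulate: the actual reserve geometry
(rivers, roads, the nine-orientation structure), anisotropic or
covariate-dependent non-stationarity, measurement error in the angle-gauge
survey, and any empirical dependence between covariates beyond shared
smoothing. Passing recovery tests therefore demonstrate that the
estimators recover smooth isotropic coefficient surfaces from
Bernoulli/Poisson data at this sample size — not that the original
survey's estimates are reproduced.

## Recovery harness and problem sizes

The recovery experiment fits all six models per seed on fresh 443-unit
studies with a 355/88 split. For it, the package uses a compact SWNN
(hidden 96/64, batch 32, learning rate 0.002, ≤ 400 epochs with patience
60) rather than the published architecture: at n_train = 355 the distance
input has 355 features and the compact network reaches the same
qualitative result (local models dominate the global ones; coefficient
surfaces recovered with correlation ≈ 0.95) in a few seconds per fit,
which keeps a ten-seed experiment to a couple of minutes. The published
architecture remains the package default for real-scale runs.

## Known limitations

- Golden-section bandwidth search assumes a unimodal AICc profile; a
  multimodal profile can return a local minimum (supply an explicit grid
  to be safe).
- The Poisson models have no overdispersion correction; the count data
  the package targets are overdispersed, so standard errors of the global
  Poisson fit are optimistic. The local models absorb much of the excess
  variance through the spatially varying intercept.
- Adaptive-kernel AICc uses the same hat-matrix trace as the fixed
  kernel; no correction for bandwidth-selection uncertainty is made.
- GNNWR local coefficients are point estimates; no uncertainty
  quantification is provided.
- Coordinates are assumed already projected in meters (the study area
  spans a few kilometers); there is no geodesic support.
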