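# Methods

## Model

For each of J outcome variables sharing one N x p design matrix X, the
model is the linear mixed-effects regression

    y_j = X beta_j + eps_j,     eps_j ~ N(0, V_j),

where the residual covariance decomposes into variance components
attributable to known structure in the data:

    V_j / sigma_j^2 = theta_{j,F} Z_F Z_F' + theta_{j,S} Z_S Z_S'
                      + sum_k theta_{j,k} K_k + theta_{j,E} I.

`Z_F` and `Z_S` are indicator matrices of family and subject membership
(random intercepts), each `K_k` is an optional symmetric relatedness kernel
(e.g. a genetic relatedness matrix, GRM), and `theta_{j,E}` is the
uncorrelated measurement-error fraction.  `sigma_j^2 = trace(V_j)/N` is the
total residual variance; the fractions are normalized so the average
diagonal of `V_j / sigma_j^2` is one, which for unit-diagonal kernels means
`sum_e theta_e + theta_E = 1`.  Subjects must be nested within families and
kernels must be zero across families, so `V_j` is block-diagonal with one
block per family.

Assumptions: Gaussian residuals; random intercepts only (no random slopes,
no covariances between effects); continuous outcomes; no missing values.

## Estimation

1. **OLS.** `beta_ols = (X'X)^{-1} X' y_j` for all J columns with a single
   QR factorization; `sigma_j^2 = RSS_j / (N - p)`.
2. **Method-of-moments variance components.**  For a pair of observations
   (i, i') the expected scaled residual product is
   `E[r_i r_i' / sigma_j^2] = sum_e theta_e K_e(i, i') + theta_E 1{i = i'}`.
   Regressing the empirical products on the kernel columns over the set of
   informative pairs (all diagonal pairs plus off-diagonal pairs with at
   least one nonzero kernel entry — the others contribute nothing to the
   normal equations and are dropped exactly) gives the one-shot estimator
   `(L'L)^{-1} L'R` for all J outcomes in a single matrix product.
   Outcomes whose unconstrained solution has a negative fraction are
   re-solved exactly under `theta >= 0` by non-negative least squares on
   the (E+1)-dimensional normal equations (a clamp-at-zero mode exists for
   speed comparisons, `negative_mode="clamp"`).  Estimates are then
   rescaled so the normalization above holds; an all-zero solution
   degenerates to pure error, `theta_E = 1`.
3. **Binning.**  Outcome j is assigned to grid cell
   `floor(theta_{j,e} * K)` per modeled effect (half-open cells, the top
   edge mapped into the last cell).  All outcomes in a cell share one
   covariance; the cell representative is the renormalized mean of the
   members' fractions, so it deviates from any member by less than `1/K`
   per coordinate.  The default `K = 20` keeps the number of
   factorizations at most `min(J, K^E)` while leaving fixed-effect
   accuracy indistinguishable from per-outcome GLS (see the binning study).
4. **GLS + Wald.**  Per occupied cell,
   `beta_j = (X'V^{-1}X)^{-1} X'V^{-1} y_j` with
   `Var(beta_j) = sigma_j^2 (X'V^{-1}X)^{-1}` (V is normalized, so the
   per-outcome scalar multiplies one shared matrix).  Wald ratios
   `z = beta/se` are referred to the standard normal; with the sample sizes
   this engine targets the normal and t references are indistinguishable.
   Contrasts `c'beta` use the same retained `(X'V^{-1}X)^{-1}`.

An optional refinement loop (`iterations > 1`) recomputes residuals from
the GLS fit and repeats stages 2-4; one pass is the default, and in our
simulations further passes change estimates only marginally.  A per-outcome
profile maximum-likelihood estimator (`estimator="ml"`) maximizes the
Gaussian likelihood over the raw component variances with the fixed effects
profiled out at each candidate, initialized at the moment estimate; it is
orders of magnitude slower and intended for when the variance components
themselves are of scientific interest.

### Numerical choices

- Family blocks are grouped by size and factorized/solved as stacked
  batches (`numpy.linalg.cholesky` / `solve` on (k, m, m) arrays), so a
  cell costs a handful of LAPACK calls regardless of the number of
  families.  A Cholesky factorization doubles as the positive-definiteness
  guard.
- `theta_E` is floored at 1e-4 when composing V to guarantee positive
  definiteness; simulated and realistic data have `theta_E >= 0.2`, so the
  floor is inert there.
- Kernel entries equal to zero are dropped from the pair index
  (`zero_tol = 0` by default); simulated GRMs place exact zeros between
  families.  A positive `zero_tol` trades a small bias for sparsity on
  dense kernels.
- `sigma_j^2` in the Wald variance is the OLS-based estimate, which is
  consistent and available before GLS; recomputing it from GLS residuals is
  possible but changes nothing at the target sample sizes.
- p-values are floored at the smallest positive normal double so they stay
  in (0, 1] when the normal survival function underflows (|z| > ~38).
- Grid ties: cells are lower-inclusive half-open intervals; `theta = 1`
  maps to the top cell.

## Wild bootstrap

Confidence intervals for the variance components come from a wild
bootstrap: each draw multiplies every family block of OLS residuals by an
i.i.d. multiplier, rebuilds the outcomes, re-runs OLS and the moment
estimator, and the CI is the empirical percentile band over draws.  The
family is the resampling unit because it is the exchangeable block of the
model.  The default multiplier is Mammen's two-point weight
(E w = 0, E w^2 = 1, E w^3 = 1).  This is a deliberate choice: a
variance-component draw depends on the residual products within a block,
which are scaled by the squared multiplier; Rademacher signs have
`w^2 = 1` identically, leave every within-block product unchanged, and
collapse the component CIs to near-zero width (we measured ~7% coverage of
a nominal 95% interval before making Mammen the default, and ~nominal
coverage after).  Rademacher remains available (`weights="rademacher"`)
for fixed-effect-style resampling.

## Synthetic data

The generator emulates a longitudinal family cohort:

- **Structure** — families with 1-5 members, each member observed 1-5
  times, both uniform; generation stops exactly at `n_obs` by truncating
  the last subject.  These ranges mirror a multi-site developmental cohort
  with twins/siblings and repeated visits.
- **Covariates** — i.i.d. standard normal, optionally with an intercept
  column; one X shared by all outcomes.
- **Truth** — slopes uniform on (-0.02, 0.02) by default (small effects
  typical of population imaging; a (-0.2, 0.2) range is used in the
  convergence study); fractions (theta_F, theta_S, theta_E) uniform on the
  simplex subject to `theta_F + theta_S >= 0.2` and `theta_E >= 0.2`,
  total residual variance 1.  A "narrow" regime draws theta_F, theta_S
  uniform on [0.3, 0.4] to force many outcomes into shared bins.
- **Residuals** — drawn in factor form: `sqrt(v_e) Z_e u_e` with
  `u_e ~ N(0, I)` per categorical effect plus white noise, which is an
  exact draw from `N(0, V_j)` and fully vectorized over outcomes; kernel
  effects use a per-family-block Cholesky square root shared across
  outcomes.
- **GRM** — ones on the diagonal and between repeated observations of a
  subject, `0.5 +` Gaussian noise (sd 0.05, clipped to [0, 1]) between
  distinct subjects of a family, exact zeros between families.  The noise
  scale is a documented guess; it is exposed as `noise_sd`.

What the generator does **not** emulate: spatial smoothness or anatomy of
real images, non-Gaussian heavy tails, missing data, covariate-dependent
heteroskedasticity, cross-family relatedness, and twin/maternal/home
kernels beyond the generic kernel pathway.  Passing simulations therefore
validate the estimator algebra and its sampling behaviour under the model,
not robustness to model violations.

## Validation studies and problem sizes

The studies in `momlme.evaluation` re-create the validation designs at
configurable scale; the defaults of each `run_*` function are the
full-scale designs, and the acceptance script and test suite run reduced
versions chosen so everything completes on a single CPU in minutes:

- **Type-I error**: N = 10,000, 50 outcomes x 100 zero-slope covariates,
  bin 20, 25 repeats (full design: 100 repeats).  False-positive counts
  are summed across outcomes per repeat, averaged, and rounded up.
- **Binning**: N = 10,000, 200 outcomes, 10 repeats, bins
  {1, 5, 10, 20, 50, 100} (full design: 2,000 outcomes, 50 repeats, a
  20-value ladder).  Total MSE sums over outcomes, so reduced-outcome runs
  are rescaled by 2000/200 when compared with the full-scale figure.
- **ML agreement**: N = 10,000, 50 outcomes, intercept + 4 covariates;
  reference is statsmodels `MixedLM` (ML, family intercept + subject
  variance component), fitted per outcome.
- **Bin robustness**: narrow-regime components, 500 outcomes x 100
  zero-slope covariates, bins 1-30, 5 repeats (full design: 100 repeats).
- **Convergence**: ladder of sample sizes up to 10,000; squared errors
  against the truth summed over outcomes for the engine and the ML
  reference.

## Known limitations

- The moment estimator is consistent but less statistically efficient than
  ML for the variance components; at N = 10,000 its component errors remain
  modestly above the ML errors even though the fixed effects are
  ML-equivalent.  Use `estimator="ml"` when components are the quantity of
  interest.
- Crossed random effects, random slopes, effect covariances, BLUPs, REML,
  and categorical outcomes are out of scope.
- Per-outcome missing-data patterns are rejected rather than handled by
  complete-case fitting, which would break the shared-design vectorization.
- Kernels with nonzero cross-family entries are rejected; supporting them
  would require a global (non-block) factorization.
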