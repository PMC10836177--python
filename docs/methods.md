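# Methods

`stcar` implements a small-area disease-mapping workflow for mortality
panels: a balanced table of death counts per area and year, populations and
age-stratum populations, and area-level covariates, together with area
polygons and (optionally) facility capacities and an origin–destination
travel-time matrix. This note records the models, the numerical choices, and
what the synthetic-data machinery does and does not emulate.

## Rates, indirect standardization, SMR

Raw mortality is `deaths / pop_total × 100,000`; service supply measures are
`count / pop_15plus × 1,000`. Expected deaths come from indirect
standardization over three 10-year age bands (50–59, 60–69, 70–79; the bands
are configurable): reference rates `r_a` are the whole-region stratum death
rates, and `E_kt = Σ_a n_{kta} r_a`.

Two conventions needed a decision:

* **Reference scope.** Rates are pooled over the full study window by
  default, so `Σ E = Σ O` exactly over the whole panel (conservation, tested
  to 1e-9). A `per-year` scope recomputes rates within each calendar year
  and conserves within year.
* **Stratum-level observed deaths.** The panel carries one aggregate death
  count per area-year. Stratum-level counts are imputed proportionally to
  stratum population before pooling. Any apportionment that sums to the
  area-year total preserves the conservation identity; the proportional rule
  is the neutral choice when no stratum-level registry extract is available.

SMR is `O/E`; zero expected counts are an error rather than an infinite
ratio.

## 2SFCA accessibility

Two-step floating catchment area with dichotomous weights and a closed
60-minute catchment (`t ≤ 60`), the travel radius consistent with keeping
total reperfusion time for ST-elevation infarction under two hours. Step 1:
each facility `j` gets `R_j = S_j / Σ_{i: t_ij ≤ θ} P_i` (bed capacity over
catchment population, default capacity 100 beds); an empty catchment yields
`R_j = 0` with a warning. Step 2: `A_i = Σ_{j: t_ij ≤ θ} R_j`.

When every facility has a non-empty catchment, `Σ_i P_i A_i = Σ_j S_j`
(total weighted access equals total supply) — asserted to 1e-9 on random
instances. Note that individual `A_i` are *not* monotone in the radius: a
wider catchment also inflates each facility's demand, so some areas can lose
access when the threshold rises. The monotone quantities are per-area access
under facility addition, and total weighted access under radius increase;
the tests assert exactly those. Accessibility is treated as time-invariant
across the study window and attached to every panel year as one covariate.
Travel times are consumed precomputed; no routing is performed.

## Screening

* **VIF**: `1/(1−R²_j)` from an intercept-included OLS of covariate `j` on
  the rest (statsmodels OLS behind the interface; an independent `lstsq`
  oracle backs the tests). Values above 5 are flagged and, by default, halt
  the pipeline.
* **Poisson GLM**: `deaths ~ covariates + offset(log E)`, IRLS via
  statsmodels with deviance tolerance 1e-8. Using `log E` as the offset puts
  the exploratory model on the same standardized baseline as the Bayesian
  model; `log population` can be supplied as an explicit offset instead.
* **Residual autocorrelation**: Pearson residuals `(O−μ)/√μ` are split by
  calendar year and each year's vector is tested with global Moran's I on
  row-standardized queen weights, with a two-sided permutation test
  (999 permutations by default; pseudo p `(#{|I_perm| ≥ |I_obs|}+1)/(n_perm+1)`).
  Moran's I is also computed on yearly SMR values; both tables are reported
  side by side. The implementation is validated against an O(n²) double-loop
  oracle to 1e-12 and against the permutation-null mean `−1/(n−1)`.

## The Bayesian spatiotemporal model

```
Y_kt ~ Poisson(E_kt θ_kt),   ln θ_kt = x_kt'β + ψ_kt
ψ_·1 ~ MVN(0, τ² Q(W, ρ_S)⁻¹)
ψ_·t = ρ_T ψ_·(t−1) + ε_t,   ε_t ~ MVN(0, τ² Q(W, ρ_S)⁻¹)
Q(W, ρ_S) = ρ_S (diag(W1) − W) + (1 − ρ_S) I
```

Leroux CAR spatial prior interpolating between independence (ρ_S = 0) and
intrinsic CAR (ρ_S = 1), with first-order autoregressive evolution of the
spatial surface. Priors: `β ~ N(0, 10⁵)`, `τ² ~ IG(1, 0.01)`,
`ρ_S, ρ_T ~ U(0,1)`; all overridable. The ρ_T support is restricted to
(0,1) in the fitted model (persistent year-to-year risk surfaces); the
simulator accepts (−1,1) for edge-case testing.

### Sampler

Metropolis-within-Gibbs:

* **β** — per-coefficient random-walk Metropolis against the Poisson
  likelihood and Gaussian prior.
* **ψ** — the joint prior precision of `vec(ψ)` is `(M(ρ_T) ⊗ Q(ρ_S))/τ²`
  with `M` the tridiagonal AR(1) precision, so two cells interact only if
  they are within one year of each other and are the same area or spatial
  neighbours. Random-walk Metropolis updates are therefore applied
  *simultaneously to colour classes* of this interaction graph (a greedy
  proper colouring of `W` crossed with time parity): within a class the
  full conditionals are mutually independent, so the vectorised
  accept/reject step is exact. This is what makes 5,000-iteration chains on
  a 100-area × 10-year panel run in seconds.
* **β/ψ interweaving** — an additional translation move per coefficient,
  `β_j → β_j + d`, `ψ → ψ − d X_j`, which leaves the linear predictor (and
  hence the likelihood) exactly invariant; acceptance depends only on the
  β prior and the CAR–AR prior, whose sum-of-squares change is quadratic in
  `d` with cheap coefficients. Smooth, slowly varying covariates are
  near-collinear with the CAR surface, and this move is what lets their
  coefficients (and the intercept) traverse that ridge; without it,
  short-chain R̂ for such coefficients routinely exceeds 1.1.
* **τ²** — conjugate Gibbs, `IG(a + KT/2, b + SS/2)` with
  `SS = ψ_·1'Qψ_·1 + Σ_{t≥2}(ψ_·t − ρ_Tψ_·(t−1))'Q(·)`.
* **ρ_S, ρ_T** — random-walk Metropolis on the logit scale against the
  exact MVN log-densities. `log det Q(ρ_S) = Σ log(ρ_S λ_i + 1 − ρ_S)` uses
  the eigenvalues of the graph Laplacian, computed once, so each ρ_S
  proposal costs O(K). `M(ρ_T)` has unit determinant, so ρ_T needs only the
  quadratic form, which is quadratic in ρ_T with precomputable
  coefficients.

When fitting from a panel, covariates are z-scored internally before
sampling and the retained β draws are mapped back to the per-unit scale
(the transform is linear, so this is exact); registry covariates span
orders of magnitude in scale, and random-walk samplers mix poorly on such
anisotropic posteriors. Reported coefficients and RRs are always per
original covariate unit.

Proposal scales adapt multiplicatively toward 30–50% acceptance during
burn-in only and are frozen afterwards, preserving detailed balance for the
retained draws. Chains are initialised with small independent jitter; all
randomness flows from per-chain generators spawned from one seed, and runs
are exactly reproducible. Default configuration: 220,000 iterations,
20,000 burn-in, thinning 100, two chains; experiments and tests use reduced
profiles (see below). Non-finite states abort with a state dump; the cached
mean surface is refreshed every 500 sweeps to prevent multiplicative drift.

### Diagnostics and fit criteria

Gelman–Rubin is the classic between/within-chain PSRF with the 1.1
threshold (two chains minimum; the pipeline fails, configurably, on any
R̂ ≥ 1.1). Geweke compares the first 10% with the last 50% of each chain,
`z = (m₁−m₂)/√(s₁/n₁ + s₂/n₂)`, with segment variances estimated by a
Newey–West (Bartlett-kernel) long-run variance with lag `n^{1/3}`; |z| > 2
is flagged. DIC uses the plug-in penalty `p_D = D̄ − D(θ̄)` at the posterior
means of β and ψ; WAIC uses the pointwise variance penalty
`p_WAIC = Σ var log p(y_kt|·)`; the posterior-mean log-likelihood is
reported alongside (labelled as a posterior mean).

### Posterior summaries

Covariate relative risk is `exp(mean β_j)` with an equal-tailed 95% CrI
from the exponentiated sample quantiles. The risk surface summarises
per-draw `θ_kt = exp(x_kt'β + ψ_kt)` by mean, 2.5/97.5% quantiles, and
`PEP = Pr(θ_kt > 1)` with ties at exactly 1 counted as non-exceedance. The
yearly trend averages θ across areas within each draw. Percent decline
between two RRs is `100(RR_start − RR_end)/RR_start`; a covariate's
protective effect size is `100(1 − RR)`, both rounded to one decimal for
reporting.

## Synthetic region

The generator produces an entire study system on an `nx × ny` lattice of
square cells (10 km by default, municipality scale): stratified female
populations (log-normal totals around 20,000; stratum fractions near
0.12/0.08/0.05 of the total for ages 50–59/60–69/70–79), expected counts
from a fixed reference-rate schedule (60/180/500 deaths per 100,000
person-years across the three bands — the steep age gradient of coronary
mortality), smooth covariate fields (one independent CAR draw each, rescaled
into realistic ranges: performance index in [0,1], primary-care coverage in
[0,100], service rates per 1,000 positive), facilities with 100-bed
capacities at random cell centroids, straight-line car travel times at
60 km/h, accessibility from an actual 2SFCA pass (stored as beds per 1,000
residents so per-unit relative risks are interpretable), and deaths drawn
from the CAR–AR(1) Poisson model above. Default effect sizes are the reported
covariate relative risks on the log scale (e.g. ln 0.46 per unit of the
performance index), with ρ_S = 0.7, ρ_T = 0.8, τ² = 0.1. Generating
parameters and the realized ψ are retained for recovery tests; one scenario
seed reproduces the panel bit for bit.

What the generator does *not* emulate: the real region's geography and
adjacency graph, population growth and yearly covariate drift, registry
under-reporting, and road-network travel times. Passing tests demonstrate
that the estimators recover the generative process under idealised
conditions; they do not certify the substantive estimates of any particular
registry analysis.

## Validation experiments

* **Parameter recovery** (`experiments.recovery_experiment`): 20 replicate
  panels on a 10×10 lattice, T = 10, generated at β = (0.5, −0.5) on
  standardized covariates, ρ_S = 0.7, ρ_T = 0.8, τ² = 0.1, refitted with
  5,000 iterations / 1,000 burn-in / two chains. Scored on 95% CrI coverage
  of the five generating parameters (≥ 18/20 each) and worst R̂ < 1.1.
  The experiment covariates mix a smooth spatial component with
  equal-variance independent yearly variation, as yearly registry
  covariates do. This matters: a purely time-constant smooth covariate is
  confounded with the CAR surface (spatial confounding) and its coefficient
  is weakly identified — a known limitation of CAR regression adjustment
  rather than of the sampler.
* **Null calibration** (`experiments.null_calibration_experiment`): 20
  replicates at β = 0, τ² = 0.01, refitted with 2,500/500, one chain;
  covariate CrIs should cover RR = 1 in ≥ 18/20 replicates and per-cell
  exceedance probabilities should centre near 0.5.

Problem sizes throughout (lattice sides, replicate counts, reduced MCMC
profiles) are chosen so the full suite and the acceptance script each run
in minutes on a single CPU; the full-scale 220,000-iteration default is the
production configuration for real panels.

## Degenerate inputs and tie-breaks

Islands (zero-neighbour areas) are rejected before any CAR computation;
`ρ_S = 1` is rejected in the simulator and surfaces as a clear error in the
sampler. Zero-variance vectors are an error for Moran's I. Catchment
membership uses closed inequalities (`t ≤ θ`). Exact collinearity in VIF is
reported as an infinite, flagged value rather than an exception, while a
rank-deficient GLM design is an error. Unknown configuration keys are
rejected before any computation, and a missing (area, year) cell names the
gap.

## Known limitations

* Single aggregate death count per area-year; stratum-level observed counts
  are imputed proportionally (see above).
* Dichotomous 2SFCA only; no distance-decay kernels.
* The ψ field and the intercept (and any smooth, time-constant covariate)
  are weakly identified relative to each other — only their sum enters the
  likelihood, and the proper Leroux prior resolves the ridge but does not
  remove it. The interweaving move makes the sampler traverse it, yet
  posterior uncertainty for such coefficients is intrinsically larger, and
  their Geweke z is the most frequently flagged on short chains.
* No shapefile reader; polygons are exchanged as GeoJSON.
* Moran's I uses dense weights; adequate to a few thousand areas.
* Replicate refits show covariate posterior means are unbiased, but the
  across-replicate scatter of the posterior mean can modestly exceed the
  average posterior standard deviation (ratios up to ~1.2 observed), so
  frequentist coverage of the 95% CrIs sits slightly below nominal
  (roughly 90–95%) at the experiment's information level — a known property
  of hierarchical CAR models with many random effects, not specific to this
  implementation.
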