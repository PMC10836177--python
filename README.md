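# stcar

Bayesian spatiotemporal mapping of small-area mortality risk.

`stcar` is for epidemiologists and health-services researchers who have a
balanced panel of death counts over administrative areas and years —
municipality-level coronary-artery-disease mortality is the motivating use
case — plus area polygons, covariates, and (optionally) facility capacities
with a travel-time matrix. It turns those inputs into standardized mortality
ratios, an accessibility index, exploratory regression diagnostics, and a
fully Bayesian relative-risk surface with exceedance probabilities and a
yearly trend curve.

## The model

Observed deaths `Y_kt` in area `k` and year `t` are compared with expected
deaths `E_kt` from indirect age standardization:

```
Y_kt ~ Poisson(E_kt θ_kt),        ln θ_kt = x_kt'β + ψ_kt
ψ_·1 ~ MVN(0, τ² Q(W, ρ_S)⁻¹)
ψ_·t = ρ_T ψ_·(t−1) + ε_t,        ε_t ~ MVN(0, τ² Q(W, ρ_S)⁻¹)
Q(W, ρ_S) = ρ_S (diag(W1) − W) + (1 − ρ_S) I
```

`θ_kt` is the area-year relative risk, `β` are covariate effects
(reported as relative risks `exp β` with 95% credible intervals), and the
random-effect surface `ψ` carries a Leroux conditional-autoregressive (CAR)
spatial prior on the queen-contiguity graph `W`, evolving through time as a
first-order autoregression. The model is fitted by Metropolis-within-Gibbs
MCMC (adaptive proposals, conjugate τ² updates, colour-block ψ updates, and
an interweaving move for coefficients confounded with the spatial surface),
with Gelman–Rubin (R̂ < 1.1) and Geweke (|z| ≤ 2) convergence gates and
DIC/WAIC fit criteria. Around the model sit:

* **standardization** — raw rates per 100,000, service rates per 1,000,
  expected counts and SMR `O/E` (pooled reference conserves `ΣE = ΣO`);
* **accessibility** — two-step floating catchment area (2SFCA) index of
  access to cardiology centres, 60-minute catchments, 100-bed capacities;
* **screening** — VIF collinearity gate (flag > 5), Poisson GLM with
  `log E` offset, and yearly Moran's I permutation tests on residuals;
* **synthetic_region** — a generator that builds a whole study system
  (lattice, populations, covariates, facilities, travel times, counts from
  the generative model with known parameters) so everything is testable
  without registry downloads.

## Worked example

Run the whole pipeline on a simulated 10×10 region, ten years, eight
cardiology centres, with a short two-chain MCMC profile:

```python
from stcar.cli_pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig.model_validate({
    "output_dir": "runs/demo",
    "seed": 7,
    "simulate": {"nx": 10, "ny": 10, "n_years": 10, "n_facilities": 8},
    "covariates": ["ipdm", "stress_test_rate", "accessibility"],
    "mcmc": {"n_iter": 5000, "burn_in": 1000, "thin": 2, "n_chains": 2},
    "screening": {"n_perm": 199},
})
run_pipeline(cfg)
```

(or equivalently `stcar run config.yaml` from a shell; `stcar simulate`,
`standardize`, `access`, `screen`, `fit` and `summarize` run single stages.)

The run directory then contains, among other outputs, `covariate_rr.csv`:

```
       covariate     rr  ci_lo  ci_hi
       intercept 2.1781 1.5827 2.9531
            ipdm 0.3692 0.2670 0.5148
stress_test_rate 0.9436 0.9096 0.9769
   accessibility 0.9187 0.5396 1.5829
```

The generating truth for this scenario put the municipal performance index
(ipdm) at RR 0.46 per unit, exercise stress testing at 0.96, and
accessibility at 0.92 per bed-per-1,000-residents: each credible interval
covers its generating value, and ipdm is correctly the dominant protective
factor. `vif.csv` shows all VIFs near 1 (no collinearity), `diagnostics.csv`
has every R̂ below 1.1 (worst 1.03 here), and `trend.csv` holds the yearly
average-risk curve with its 95% band (this particular simulation drifts
from 1.06 down to 0.96; the trend has no built-in direction). The risk
surface — posterior mean RR, credible bounds, and exceedance probability
`PEP = Pr(θ_kt > 1)` per area-year — is written as `risk_surface.csv` and
as a GeoJSON joined to the area polygons, ready for any GIS.

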