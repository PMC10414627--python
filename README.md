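# mc2dose

Two-dimensional Monte Carlo (2DMC) dose reconstruction with **shared** and
**unshared** uncertainties, for cohorts exposed to environmental
radioactive contamination — riverside releases and fallout-trace
deposition in the Southern Urals style of exposure.

Epidemiological dose-response studies need more than a point estimate of
each person's organ dose: they need to know how dose errors are
*correlated* across people. A systematic error in a village-average intake
estimate shifts every resident's dose together (shared error); a person's
idiosyncratic behavior or measurement noise does not (unshared error).
`mc2dose` propagates both kinds through an annual organ-dose model and
produces an ensemble of dose *realizations* — complete alternative dose
histories for the whole cohort — from which the downstream risk models can
estimate the effect of dose uncertainty on risk-estimate uncertainty.

The real parameter databases behind such dosimetry systems are not public,
so the package ships a synthetic-data generator that emulates their
dimensioning and statistical structure; every stage is testable end to end
with no external data.

## The model

Annual doses are sums of four components. Riverside (Techa-type) internal
dose starts from the annual intake of radionuclide *r* for person *i*:

    I_i(r, y) = I_ref(y) · f_L · α(τ) · ξ_i · R_{r:90Sr}(L)

where `I_ref` is the reference-settlement adult ⁹⁰Sr intake time series,
`f_L` the settlement-to-reference ratio, `α(τ)` the child-to-adult ratio
at age τ, `ξ_i` an individual scaling factor from ⁹⁰Sr body-burden
measurements (IMR, or household-average HSR), and `R` the
nuclide-to-⁹⁰Sr intake ratio. Intakes convert to cumulative organ dose via
dose-coefficient kernels `DF_ro(lag, age at intake)` (Gy/Bq):

    D_io(y) = Σ_r Σ_{t≤y} I_i(r, t) · DF_ro(y − t, τ(t))

External riverside dose couples the shoreline dose rate in air `D_riv`
with behavioral time fractions (T1 riverbank, T2 outdoors, T3 indoors) and
shielding ratios:

    d_io(y) = A_o(τ) · D_riv(y, L) · [T1 + R_out/riv·T2 + R_in/out·T3]

Fallout-trace (EURT-type) doses use the ⁹⁰Sr surface deposition `G` with a
deposition-to-intake conversion `E_r(y, τ)` internally and a normalized
outdoor dose-rate table externally, with the bracket
`(1 − T3) + T3·R_in/out`.

Each model parameter carries multiplicative error factors catalogued in a
registry (1,436 shared and 422 unshared scalar parameters at the default
dimensioning). The 2DMC scheme samples all shared factors once per
realization by Latin hypercube (exactly one sample per equiprobable
stratum per scalar), then perturbs each person with unshared factors from
streams keyed by (individual, realization, parameter) so results never
depend on processing order. Per-person summaries (AM, CV, GM, GSD over
realizations), population percentile tables, a realization-ratio CDF
diagnostic for shared error, and a Kolmogorov–Smirnov best-fit classifier
(lognormal, scaled beta, GEV, gamma, generalized logistic, Weibull, or
"none") complete the pipeline.

## Worked example

```python
from mc2dose import ScenarioConfig, generate_scenario_bundle, run_ensemble
from mc2dose.summaries import cohort_records, population_summary, internal_fraction

bundle = generate_scenario_bundle(ScenarioConfig(cohort_size=100, seed=11))
ensemble = run_ensemble(bundle, 300, seed=11)
records = cohort_records(ensemble, "marrow")
print(population_summary(records).round(4).to_string(index=False))
frac, _ = internal_fraction(ensemble, "marrow")
print(f"internal fraction of mean marrow dose: {frac:.2f}")
```

prints

```
                statistic   mean     cv  p5    p25    p50    p75    p95    max
          population_mean 0.0256 1.6142 0.0 0.0006 0.0081 0.0302 0.1241 0.2452
population_geometric_mean 0.0223 1.6365 0.0 0.0005 0.0067 0.0246 0.1142 0.2135
            individual_cv 0.6244 0.6319 0.0 0.4718 0.5962 0.7909 0.9685 3.3901
           individual_gsd 1.6533 0.1621 1.0 1.5845 1.6428 1.7932 2.0497 2.3280
internal fraction of mean marrow dose: 0.46
```

The rows summarise the population distribution of per-person statistics
computed over the 300 dose realizations: mean cumulative marrow doses
around 26 mGy (median 8 mGy) for this synthetic cohort, with per-person
dose uncertainty around GSD 1.65 — i.e. a 90% uncertainty band spanning
roughly a factor of 5 on each individual dose.

The same pipeline is available from the shell:

```sh
mc2dose synth --seed 11 --cohort-size 100 --out bundle/
mc2dose run --bundle bundle/ --n-realizations 300 --seed 11 --out results/
mc2dose validate bundle/
```

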