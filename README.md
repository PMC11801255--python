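# mangrove-carbon

Tools for asking a simple restoration question with global chronosequence
data: **how quickly do planted mangrove stands rebuild the carbon stocks of
intact mature forests?**

Planted (restored or afforested) mangrove stands of known age are compared
against nearby intact reference stands, compartment by compartment —
aboveground biomass (AGB), belowground biomass (BGB), and soil organic
carbon to 1-m depth, all in MgC ha⁻¹. Each planted stand contributes a
dimensionless *buildup ratio*

    R = C_planted / mean(C_intact)

and the trajectory of R with stand age is modelled with a Bayesian
nonlinear logistic curve whose asymptote is free (planted stands may over-
or under-shoot intact stocks):

    R(age) = Rmax / (1 + exp(−β₀ − β₁ · ln age))
    ln R ~ Normal( ln Rmax − ln(1 + exp(−β₀ − β₁ · ln age)), σ )

with weakly informative priors ln Rmax ~ N(0, 2.5), β₀ ~ N(0, 5),
β₁ ~ N(0, 2.5) and a flat (Jeffreys) prior on ln σ. `Rmax` is the
asymptotic planted-to-intact ratio, `β₀` locates the curve (log odds at age
1 yr), `β₁` is its slope per unit ln(age), and `σ` is the residual SD of
the log ratio. Posterior draws then answer the applied questions: the
credible band of R at any age, the age at which a target ratio is reached
(`age = exp[(ln(R/(Rmax−R)) − β₀)/β₁]`, infinite when R ≥ Rmax), and
predicted absolute stocks obtained by multiplying R against literature
compilations of intact stocks.

The package is aimed at blue-carbon researchers and restoration planners
who have stand-level compilations of this shape, and at anyone who wants a
fully synthetic, seeded test bed for this class of ratio-chronosequence
meta-analysis.

## What is in the box

| Module | Purpose |
| --- | --- |
| `stand_data` | Typed stand records, CSV schemas, validation, exclusion filters (no location / composition / age, no replication) |
| `preprocess` | Soil C stock from profiles (BD × depth × %C), rescaling to the 1-m reference depth, scaling-method comparison by observed-vs-predicted regression |
| `pairing` | Haversine matching of planted stands to intact references (≤10 km local, same-geomorphic-class; climate-band remote fallback), ratio construction, stratum assembly |
| `model` | `BuildupModel` / `BuildupResults`: the logistic buildup model, ensemble-MCMC posterior, split-R̂/ESS gate, curve summaries, age inversion, slope probabilities, Bayesian R² |
| `prediction` | Predicted stocks per age (posterior draws × intact value sets) and net C gain over a horizon |
| `synthetic` | Seeded generator of realistic planted/intact datasets with hidden truth; parameter-recovery experiments |
| `cli` | `mangrove-carbon simulate/preprocess/pair/fit/summarize/predict` with run manifests |

## Worked example

Simulate a synthetic global compilation, harmonize it, pair planted with
intact stands, and fit the pooled BGB stratum:

```python
from mangrove_carbon import (BuildupModel, FitConfig, IntactStockSet,
                             SyntheticConfig, pair_dataset, simulate_dataset)
from mangrove_carbon.preprocess import harmonize_dataset
from mangrove_carbon.pairing import observations_to_frame

ds, truth = simulate_dataset(SyntheticConfig(seed=7))   # 325 stands
obs, report = pair_dataset(harmonize_dataset(ds))        # 750 ratio observations
df = observations_to_frame(obs)

model = BuildupModel.from_dataframe(df, "bgb", "all")
res = model.fit(FitConfig(seed=1))
print(res.summary().round(3))
```

```
            mean     sd   q2.5  q97.5   rhat       ess
parameter
rmax       0.672  0.057  0.573  0.797  1.010  5263.338
beta0     -2.407  0.120 -2.647 -2.177  1.008  5266.482
beta1      1.514  0.059  1.401  1.632  1.008  5306.332
sigma      0.492  0.023  0.451  0.539  1.007  5189.138
```

The generator's BGB truth is (Rmax 0.73, β₀ −2.5, β₁ 1.5, σ 0.5); every
95% interval above covers it. The recovery curve and derived quantities:

```python
print(res.curve([1, 5, 10, 20, 30, 40]).round(3))
print(res.age_at(0.5).round(2))                  # age reaching R = 0.5
print(res.net_gain(IntactStockSet("bgb", (40.0, 49.0, 60.0)), 40.0).round(2))
```

```
   age_yr   mean   q2.5  q97.5
0     1.0  0.055  0.051  0.061
1     5.0  0.339  0.309  0.370
2    10.0  0.498  0.455  0.544
3    20.0  0.598  0.529  0.675
4    30.0  0.630  0.549  0.722
5    40.0  0.644  0.558  0.745

median           10.12      # years to R = 0.5, with 95% CI [8.30, 14.09]
q2.5              8.30
q97.5            14.09
p_unreachable     0.00

mean     31.98               # net BGB gain over 40 yr, MgC/ha
q2.5     23.13
q97.5    42.89
```

So in this synthetic world a planted stand's belowground biomass reaches
half the intact stock in ~10 years and levels off near two-thirds of it,
adding ≈32 MgC ha⁻¹ against an intact pool of ~50 MgC ha⁻¹. The same
analysis runs from a shell:

```sh
mangrove-carbon simulate --seed 7 --out-dir sim/
mangrove-carbon preprocess --stands sim/stands.csv --out sim/harmonized.csv
mangrove-carbon pair --stands sim/harmonized.csv --out sim/ratios.csv
mangrove-carbon fit --ratios sim/ratios.csv --stratum bgb:all --seed 1 --out sim/posterior.csv
mangrove-carbon summarize --posterior sim/posterior.csv --out sim/curve.csv
```

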