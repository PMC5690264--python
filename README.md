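# icarmap

Bayesian small-area disease mapping with intrinsic conditional
autoregressive (ICAR) convolution priors, with first-class support for
**auditing spatial adjacencies** and **comparing spatial weight
specifications**.

The package is aimed at spatial epidemiologists analysing rare-event
counts (for example, fall-injury hospitalisations among seniors) over
small administrative areas such as census dissemination areas, where:

- adjacency lists extracted from a digital map can be *wrong* because
  shared polygon vertices are stored with slightly different coordinates
  in each ring, and
- the conventional choice of equal spatial weights (`w_ij = 1` for all
  neighbours) can oversmooth risks and distort covariate inference when
  the population at risk varies strongly between adjacent areas.

## The model

Counts are standardized indirectly: with `N_ik` persons and `Y_ik` cases
in area `i` and age–sex stratum `k`, study-wide reference rates
`z_k = Σ_i Y_ik / Σ_i N_ik` give expected counts `E_i = Σ_k N_ik z_k` and
standardized incidence ratios `SIR_i = Y_i / E_i`.

Area totals follow the Besag–York–Mollié convolution model

    Y_i ~ Poisson(λ_i),   log λ_i = log E_i + α + x_i'β + S_i + U_i

with unstructured heterogeneity `U_i ~ Normal(0, ν_u)` and spatially
structured effects with the ICAR conditional

    S_i | S_-i ~ Normal( Σ_j w_ij S_j / w_i+ ,  ν_s / w_i+ ),

the `ρ = 1` limit of the proper CAR model. The pair weights `w_ij` are
the object of study: either equal (`w_ij = 1`) or the product of a
per-area variable in the two adjacent areas — seniors' population,
population density, or expected count (`w_ij = E_i E_j`), the latter
adjusting for the age–sex composition of the population at risk.
Priors: flat on `α`, `Normal(0, 10^4)` on each `β`, `Gamma(0.5, 0.0005)`
on the precisions `1/ν_s`, `1/ν_u` (sensitivity alternative
`Gamma(0.001, 0.001)`). Fitting is by an adaptive Metropolis-within-Gibbs
sampler with conjugate precision updates; competing weight schemes are
compared by DIC with a decision margin, and per-area exceedance
probabilities `P(r_i > 1)` are tabulated at thresholds 0.5/0.75/0.90/0.95.

Because the motivating study's data and digital map are confidential, the
package ships a synthetic-data generator (`icarmap.synthetic`) producing
polygon lattices with controllable vertex-coordinate discrepancies,
age–sex stratified populations with an urban–rural gradient and
near-empty areas, spatially structured covariates, and counts drawn from
the model itself — with the full ground truth returned alongside.

## Worked example

```python
import numpy as np, warnings
import icarmap as im
from icarmap.pipeline import compare_weight_schemes

scen = im.SyntheticScenario(n_rows=10, n_cols=10, seed=42,
                            jitter_fraction=0.1, vertex_jitter_sd=1e-3)
ds = im.generate_dataset(scen)

# adjacency audit: exact vertex matching vs ground truth
exact = im.extract_queen_adjacency(ds.area_map, tolerance=0.0)
report = im.compare_adjacency(ds.adjacency, exact)
print(f"true neighbour entries: {report.total_true}, "
      f"extracted: {report.total_generated}, "
      f"undercount: {100*report.undercount_error:.1f}%")

# indirect standardization
E = im.expected_counts(ds.table, im.reference_rates(ds.table))
Y = ds.table.area_totals

# fit under equal and expected-count weights, compare by DIC
cfg = im.SamplerConfig(n_chains=2, burn_in=5000, keep=4000, seed=1)
comp = compare_weight_schemes(Y, E, ds.X, ds.adjacency,
                              ["equal", "expected"], cfg, table=ds.table)
print(comp.table[["scheme", "DIC", "pD", "spatial_fraction"]].round(2))
print("winner:", comp.winner)
```

prints

```
true neighbour entries: 684, extracted: 644, undercount: 5.8%
  scheme   DIC    pD  spatial_fraction
   equal 510.7 39.29              0.88
expected 518.5 47.72              0.45
winner: None
```

Ten percent of the map's shared vertices were stored with jittered
coordinates, so exact-coordinate matching loses 5.8% of the true
neighbour entries — rerunning `extract_queen_adjacency` with a tolerance
at the jitter magnitude recovers all of them. This particular dataset was
generated under equal weights and the DIC difference is below the
decision margin of 5, so no weight scheme is declared the winner; on data
generated under expected-count weights over a strong population gradient,
the expected-count fit wins the DIC comparison in the large majority of
replicates (see `scripts/acceptance.py`).

## Command line

```sh
icarmap simulate --rows 10 --cols 10 --seed 1 --out data/
icarmap adjacency data/map.geojson --tolerance 0 --reference data/adjacency_true.txt
icarmap standardize data/strata.csv --out standardized.csv
icarmap fit data/strata.csv data/adjacency_true.txt --covariates data/covariates.csv \
        --scheme expected --out fit/
icarmap compare data/strata.csv data/adjacency_true.txt --schemes equal,expected
icarmap run config.yaml       # full workflow from a YAML configuration
```

Exit codes distinguish configuration errors (2), data errors (3) and
convergence-gate failures (4).

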