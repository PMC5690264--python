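# Methods

## Model and standardization

Counts of a rare adverse event (the motivating application is fall-injury
hospitalisation among people aged 65+) are observed per area `i` and
age–sex stratum `k` (two sexes × ages 65–69, 70–74, 75–79, 80–84, 85+,
K = 10). Under the proportionality assumption `p_ik = r_i z_k` — the
area-level relative risk multiplies a study-wide stratum rate — the
stratified Poisson model collapses to area totals

    Y_i ~ Poisson(E_i r_i),   E_i = Σ_k N_ik z_k,

with internally standardized rates `z_k = Σ_i Y_ik / Σ_i N_ik`. Internal
standardization forces `Σ E = Σ Y` and a population-weighted mean SIR of
exactly 1; both identities are asserted in the test suite. An area with
no population at risk has `E_i = 0`: its SIR is flagged (0 if `Y_i = 0`,
undefined otherwise) rather than raised, and at model build `E_i = 0` is
replaced by a floor (`e_floor`, default 1e-4) with a logged warning so the
log-offset stays finite.

The log relative risk gets the convolution (BYM) prior: an intercept,
optional covariates, an unstructured Normal term `U`, and a spatially
structured term `S` with the intrinsic CAR conditional
`S_i | S_-i ~ Normal(Σ_j w_ij S_j / w_i+, ν_s / w_i+)`. The spatial
dependency parameter is fixed at its maximum `ρ = 1` (ICAR); proper CAR
with estimated `ρ` and the Leroux/BYM2 reparameterisations are
deliberately out of scope. The joint (improper) density behind the
conditional is `∝ exp(−(1/2ν_s) Σ_{i<j} w_ij (S_i − S_j)²)`; the test
suite checks the conditional against a complete-the-square oracle on this
joint to 1e-10 on small graphs.

## Spatial weights

Weights are stored unnormalised (the conditional above consumes `w` and
`w_i+` directly); row-normalised weights are derived for reporting only.
Four schemes share one code path: `equal` (`w_ij = 1`) and three product
schemes `w_ij = v_i v_j` with `v` = seniors' population, population
density, or expected count. Products are floored (default 1e-6 × the
median positive product) so that an area with `v_i = 0` keeps `w_i+ > 0`
and the ICAR conditional stays defined; the floor is logged prominently
in the weight spec. Product weights are invariant, after row
normalisation, to rescaling `v` by any positive constant, so the
units of the weighting variable are irrelevant.

## Priors

- `α`: improper flat. Valid because `S` is recentred each sweep with the
  shift absorbed into `α`.
- `β_q`: Normal(0, 10⁴) each, i.e. prior sd 100.
- precisions `1/ν_s`, `1/ν_u`: Gamma(shape 0.5, rate 0.0005) by default.
  `implied_sd_prior` computes, by Gamma quantiles alone, the implied
  random-effect sd: median ≈ 0.047 (≈ 0.05) with ≈ 1% probability of
  lying outside (0.01, 2.5). The sensitivity alternative is
  Gamma(0.001, 0.001); the pipeline reruns every final model under it.

## Sampler

Metropolis-within-Gibbs, one sweep =

1. `S`: scalar random-walk Metropolis targeting Poisson likelihood ×
   ICAR conditional, blocked by graph colour — the areas of one colour
   form an independent set, so their conditionals do not involve each
   other and the whole block updates in one vectorised step. Afterwards
   `S` is recentred to sum to zero and the shift moved into `α`
   (the standard identifiability fix for the improper ICAR; the rank
   correction `n − 1` in the `ν_s` update assumes one connected
   component, so island areas and disconnected maps are rejected at
   build time with the offending areas named).
2. `U`: vectorised scalar Metropolis (the `U_i` are conditionally
   independent given everything else).
3. `α`, then each `β_q`: scalar random-walk Metropolis.
4. Conjugate Gibbs draws: `1/ν_u ~ Gamma(a + n/2, b + ΣU²/2)` and
   `1/ν_s ~ Gamma(a + (n−1)/2, b + ½ Σ_{i<j} w_ij (S_i − S_j)²)`.

Step sizes adapt per component toward a 0.44 acceptance rate by a
decaying stochastic approximation during burn-in only, so detailed
balance holds for every retained draw. Defaults: 2 chains, 20,000
burn-in sweeps, 10,000 retained per chain (20,000 retained total),
thin 1. A fixed seed yields bit-identical chains; chains derive their
streams from a `SeedSequence` spawn of the configured seed.

A non-finite state (overflowing log-posterior) raises immediately with
the sweep index rather than propagating NaNs into summaries.

## Diagnostics and model comparison

- Gelman–Rubin: the standard finite-n potential-scale-reduction
  `√((W(m−1)/m + B/m)/W)`, clipped below at 1 (identical chains would
  otherwise report `√((m−1)/m) < 1`).
- Monte Carlo error: batch means with 30 batches; the convergence gate
  used before any scheme comparison is R-hat ≤ 1.1 and MC error < 5% of
  the posterior sd for every scalar parameter.
- DIC: `Dbar` is the posterior mean of the full Poisson deviance
  including the `log(y!)` terms, so values are comparable across weight
  schemes on identical data; `pD = Dbar − D(λ̄)` with the plug-in at the
  posterior means of the Poisson means λ_i (the stochastic-parents
  convention of the WinBUGS-style tools this reproduces). Schemes are
  fitted with identical data, adjacency, seeds and sampler settings; a
  winner is declared only when its DIC undercuts the runner-up by more
  than the margin (default 5).
- Exceedance: `P_i = ` fraction of retained draws with `r_i > 1`;
  threshold counts use a strict inequality, so an area with `P_i`
  exactly at a threshold is not counted.
- Spatial fraction: per retained iteration, `sd(S)/(sd(S)+sd(U))` with
  empirical area-level standard deviations; the posterior mean and 95%
  interval are reported. A variance-based alternative is available
  (`basis="var"`); the sd-based form is canonical here and the choice is
  recorded in output metadata, since the quantity has no unique standard
  definition.

## Workflow

The pipeline mirrors the study design: extract queen-contiguity
adjacency (and audit it against a reference list when one is supplied,
reporting directed-entry totals, missing/extra pairs, and the undercount
proportion `(true − generated)/true`) → standardize → screen covariates
one at a time under equal weights, keeping those whose 95% equal-tailed
credible interval excludes zero → optionally re-express a covariate as
percentile-category dummies → fit the final model under each weight
scheme → DIC table and Table-style outputs (coefficients/spatial
fraction/pD/DIC; risk summaries; exceedance counts) → sensitivity rerun
under the alternative hyperprior. Screening always uses equal weights,
whatever scheme later wins.

Percentile dummies: cutpoints (default 25/50/75) are nearest-rank
percentiles; the three columns are membership indicators for the upper
quartile categories (Q2, Q3, Q4) with Q1 the reference, and a value
exactly at a cutpoint falls into the lower category. "Quartile dummies
vs quintiled categories" is genuinely ambiguous in loose usage; three
cutpoints give exactly four categories and three indicator columns,
which is what the final-model structure requires, so quartile dummies
are implemented and the choice is noted in the pipeline's output
metadata.

## Adjacency extraction

Queen contiguity is implemented as a vertex test: areas are adjacent
when some vertex of one lies within `tolerance` of some vertex of the
other; `tolerance = 0` means exact coordinate equality after rounding to
1e-9. This is deliberate: the failure mode under study is precisely
shared vertices stored with close-but-different coordinates, which a
vertex test with a tolerance knob reproduces and repairs, while a full
geometric-intersection backend would conflate it with other map defects.
Candidate pairs are pruned by bounding boxes expanded by the tolerance;
pruning cannot change the result. Neighbour entries are counted directed
(i→j and j→i both count), matching how flattened num/adj files count
them. Adjacency lists round-trip through the WinBUGS-style
`num`/`adj`/`weights` text format with 1-based indices.

## Synthetic data

The generator replaces the confidential study data (an irregular map of
~308 census areas with stratified senior populations, fall counts, and
census covariates). Design choices, in the order the data are built:

- **Map**: an `n_rows × n_cols` lattice of quadrilaterals whose nodes
  are displaced uniformly (amplitude 0.2 of the cell size) — a
  controllable stand-in for irregular census geography with exact
  ground-truth queen adjacency (the 8-neighbour lattice). A chosen
  fraction of shared vertices is duplicated with independent
  Normal(0, `vertex_jitter_sd`) offsets per incident polygon, recreating
  the digital-map defect; the maximum realised discrepancy is recorded
  so tests can set an exactly sufficient tolerance. No value for
  real-world vertex discrepancies is available, so the jitter sd is a
  free scenario parameter (default example: 1e-3 of a cell).
- **Populations**: per-stratum counts uniform in `population_range`
  (default 2–30 seniors per stratum). `population_gradient` ∈ [0, 1]
  blends in a smooth urban-to-rural density surface (exponential decay
  from a random town centre), reflecting that senior populations
  concentrate geographically; 0 keeps draws spatially uniform. A
  `low_pop_fraction` of areas (default 5%) is made near-empty — 1–2
  seniors in each of two strata, total below 5 — producing the
  near-zero-E, occasionally extreme-SIR areas characteristic of census
  geographies (including possible zero-E areas when those strata have
  zero rates in a draw).
- **Stratum rates** (defaults): five-year fall-hospitalisation risks
  rising with age, 0.020→0.100 (women) and 0.016→0.080 (men), a 5-fold
  85+/65–69 ratio, consistent with fall rates rising steeply in the
  oldest groups.
- **Covariates**: a smooth random surface over centroids plus
  equal-variance white noise (≈ one-third of the variance spatial), the
  second column scaled ×10 to mimic an income-like unit. See
  *Limitations* for why covariates are not made as smooth as the latent
  field.
- **Spatial effects**: exact draws from the intrinsic Gaussian on the
  sum-to-zero subspace via the eigendecomposition of the weight
  Laplacian (covariance = ν_s × pseudo-inverse). `nu_s_true` is
  specified on the equal-weights scale; for product schemes the
  simulation variance is multiplied by the mean pair weight, using the
  ICAR's invariance to joint weight/variance rescaling — otherwise the
  field's magnitude would depend on the arbitrary scale of the weight
  products. Generation-side product weights use a larger floor (1e-2 ×
  median positive product) than the analysis default so that
  depopulated areas' conditional variances stay bounded and simulated
  log risks remain in a realistic range (|S| of a few units, matching
  the extreme SIRs of order 10–30 seen in sparse real areas).
- **Counts**: `Y_ik ~ Poisson(N_ik z_k r_i)` at stratum level, whose
  totals follow the aggregate model exactly.

One master seed drives six named per-stage streams (map, population,
covariates, icar, unstructured, counts), recorded in output metadata;
identical scenarios are bit-reproducible.

Two named scenarios freeze the study conditions used by the acceptance
checks: `recovery_scenario` (10×10 lattice, β = (0.3, 0.02), ν_s = 0.3,
ν_u = 0.05, equal-weights field) for coefficient recovery, and
`selection_scenario` (expected-count-weights field, ν_s = 0.5, full
population gradient with range 1–45 giving a ≥ 20-fold spread of
expected counts, 5% near-empty areas, no covariates) for DIC-based
scheme selection. The selection conditions matter: with spatially
uniform populations the expected-count weights vary edge-to-edge like
noise and DIC cannot tell the schemes apart; a strong, spatially smooth
population gradient is what makes the weight specification shape the
observable field, and is also the realistic regime (senior density in
real regions is strongly spatially structured).

## Problem sizes

Default sampler runs (2 × 30,000 sweeps) on a 100-area lattice take
~10–15 s each. The recovery check uses 20 replicates and the selection
check 10 replicates at the default sampler; unit tests use shorter
chains (hundreds to a few thousand sweeps) chosen to keep the whole
suite in the ten-minute range while leaving the acceptance checks at
full length.

## Limitations

- The generator's lattice geometry, uniform stratum draws and
  single-centre density surface are caricatures of real census
  geography; passing tests demonstrate correctness of the algorithms
  and calibration of the sampler under the model, not robustness to
  real-map pathologies (slivers, multipolygons with holes, projection
  artifacts) beyond the vertex-discrepancy mechanism explicitly
  modelled.
- Spatial confounding: when a covariate is nearly as spatially smooth
  as the latent ICAR field, its coefficient trades off against `S` and
  credible intervals under-cover — a property of the BYM model itself,
  not of this implementation (with weakly spatial covariates the
  sampler's 95% intervals cover at nominal rate, 29/30 per coefficient
  in an independent calibration run). The default synthetic covariates
  keep the spatial share near one-third for this reason; users fitting
  strongly spatial covariates should expect the same trade-off on real
  data.
- DIC's ability to identify the generating weight scheme is regime
  dependent (see above); in weak-signal regimes the schemes' DICs
  differ by less than Monte Carlo noise and no winner should be
  declared — hence the decision margin.
- The vertex-based queen test will not detect adjacency through a
  shared edge whose endpoints are both missing from one ring (a
  digitisation defect different from the one studied); a
  geometric-touch backend could be added for such maps.
- Exceedance counts and risk summaries are exported as CSV keyed by
  `area_id` for mapping in external GIS tools; no cartography is
  attempted.
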