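# Methods

`sproutess` models the evolution of sprouting probability in perennial
plants capable of vegetative dormancy (the focal systems are terrestrial
orchids: two *Cypripedium* species and *Ophrys sphegodes*). This note
documents the model, its assumptions, the numerical choices, what the
synthetic-data generator does and does not emulate, and known limitations.

## Vital-rate models

Each demographic rate is a generalized linear model on individual-by-year
transitions:

- **survival** from year *t* to *t*+1 (binomial, logit),
- **sprouting** in year *t*+1 conditional on survival (binomial, logit),
- **growth** — size (sprout or leaf count) in year *t*+1 conditional on
  sprouting (Poisson, log),
- **flowering** in year *t*+1 conditional on sprouting (binomial, logit),
- **flower count** conditional on flowering (Poisson, log), and optionally
  a fruiting/fruit-count chain in which flower count replaces size as the
  size-like covariate.

Covariates are used on their raw scales: current size `siz_t` and
flowering status `flwyn_t`; in the historical design also the previous
year's size and flowering and the growth increment
`grw_t = siz_t − siz_t1`; in the age × stage design the years since first
observation (`age`); plus two site climate variables (winter frost days
`dt32` and annual precipitation `tpcp`, or April–May sunshine `sun` and
February–May precipitation `sprppt`). Global models contain all main
effects plus two-way interactions; `enumerate_reduced_models` produces
every marginality-respecting submodel and `select_model` applies
small-sample AIC: the lowest-AICc fit wins unless an equally parsimonious
fit (ΔAICc ≤ 2) has strictly fewer parameters. `k` counts the fixed
coefficients plus one between-year variance term.

**Count responses are zero-truncated.** Size, flower count and fruit
count are each conditional on the event that produced them, so their
support is {1, 2, …}; they are fitted with a zero-truncated Poisson
likelihood (`statsmodels` `TruncatedLFPoisson`). A plain Poisson fit is
biased for these responses; the truncated fit is also what the matrix
builder's truncated-renormalized growth distribution assumes.

**Year effects.** Rather than a full mixed-model engine, year intercepts
are estimated in two stages: the fixed-effects model is fitted first, then
per-year one-step intercept updates are shrunk toward zero with a
method-of-moments estimate of the between-year variance (an empirical-Bayes
ridge). This preserves the year-deviation interface that stochastic
matrices need (a map year → link-scale deviation plus a between-year SD)
at a fraction of the complexity; a true GLMM backend can be substituted by
replacing `fit_vital_rate`. The reported log-likelihood is that of the
fixed-effects fit, which is adequate for comparing fixed structures but
understates support for models whose fit depends on the year term.

## State spaces and matrices

Two designs are supported.

- **Historical (paired-stage)**: states are ordered pairs of life-history
  stages in consecutive years, so transition probabilities can depend on
  the previous year's state (costs of growth, delayed costs of
  reproduction). With 19 mature stages (dormant, 1–9 sprouts vegetative,
  1–9 sprouts flowering) the adult block has 19² = 361 pair states. The
  juvenile pathway contributes 34 pair states: the fixed path
  seed→protocorm1→protocorm2→protocorm3→new-seedling (4), new-seedling →
  year-1 seedling with 0/1/2 sprouts (3), year-1 → year-2 seedling (9),
  and year-2 seedling → six adult entry stages (18). Total order 395.
  The six entry stages (dormant, 1–2 sprouts vegetative, 1–2 sprouts
  flowering, 3 sprouts vegetative) are an assumption — the published
  total pins the count but not the identities — and are overridable in
  `historical_space`.
- **Age × stage**: 10 adult age classes (the last absorbing, to model
  long lifespans) × 17 mature states (dormant, 1–8 leaves vegetative or
  flowering) plus two protocorm stages and one seedling stage; order 173.

Matrix entries follow the kernel decomposition: for source state with
survival *S*, sprouting *P*, growth distribution *g*, per-target-size
flowering *F_k*,

    a_D    = S (1 − P)
    a_k(V) = S P g_k (1 − F_k)
    a_k(F) = S P g_k F_k

so transition-block column sums equal *S* identically; this conservation
holds to 1e−12 by construction and is enforced by
`ProjectionMatrix.validate`. The growth distribution is the Poisson pmf
truncated to {1..max size} and renormalized (the published stage lists cap
size without stating how excess mass is handled; renormalization keeps
the column-sum identity exact). Flowering may carry a `siz_next` term
(target-size dependence); without one, *F* is constant across target
sizes. Matrices are dense (order ≤ 395), column-to-source oriented, and
exported as MatrixMarket with a sidecar state-index CSV.

**Fecundity** uses a pre-breeding census: seeds produced by a flowering
state in year *t* enter the seed/first-protocorm state in year *t*+1 at
rate flowers × fruit chain × seeds-per-fruit × germination. Juvenile
transition probabilities (protocorm survival, seedling emergence,
entry-stage mix) are literature-style configuration defaults, not fitted
quantities; the ±10% sensitivity harness (`perturb_fecundity`) exists
because of exactly this uncertainty, and on the built-in fixtures the
located optimum moves by well under 0.1 trait units under ±10%.

Stochastic matrices draw climate values from the configured marginal
distributions and one deviation per vital rate from its fitted
between-year SD; deterministic matrices use mean climate and zero
deviations.

## Density dependence

Adaptive dynamics needs the resident to set a density environment, so one
vital rate is made negatively density dependent. Candidate rates are
screened by refitting each rate with local density (individuals per
1 × 1 m cell, half-open bins) as an added fixed effect and classifying the
slope by a ±2 SE rule. The modifier is a multiplicative Ricker factor

    rate × exp(α − β N),    α ≤ 0, β ≥ 0,

with *N* the density of established plants (states whose current stage is
mature, including dormant adults) per m². Two deliberate choices:

- **Probability scale, not link scale.** With α ≤ 0 the factor cannot
  push a probability above 1, and a log-link scalar model reduces exactly
  to the classic Ricker map *N* exp(α − β*N*) with equilibrium α/β. More
  importantly, an *additive link-scale* modifier on sprouting is
  structurally collinear with the evolving trait (which is itself an
  additive link-scale intercept deviation): the density feedback then
  re-centres the trait axis at equilibrium and the invasion gradient is
  the same for every resident — no interior ESS can exist. This was
  verified numerically before the design was changed.
- **Where a sprouting modifier acts.** Even multiplicatively, a modifier
  applied uniformly to adult sprouting pins the effective adult sprouting
  probability to the rising branch of the fitness surface at every
  equilibrium, again removing interior optima. `RickerParams` therefore
  exposes `on_adults`/`on_juveniles` flags. The historical fixtures
  regulate juvenile emergence only (`on_adults=False`), matching the
  well-documented strength of recruitment-stage density dependence in
  herbaceous perennials; a crowding-suppressed seedling is treated as
  failing to establish (mortality), not as re-routed dormancy, since a
  dormant-entry path would otherwise bypass the regulation entirely. The
  age × stage fixture regulates adult survival, which is not collinear
  with the sprouting trait and needs no flag.

**Calibration.** α is profiled at 0 (no modification at zero density;
λ₀ > 1 is required, otherwise calibration fails as it must for rates that
cannot produce asymptotic growth). The stationary density is the unique
root of log λ(A(N)) = 0 — λ is strictly decreasing in *N* — so β is found
by bracketed Brent iteration on that root against the plateau target, to
well inside the 2% contract. The density-coupled iteration itself starts
from a single founder plant in the first adult entry state, declares
convergence when the relative density change stays below 1e−6 for 50
consecutive steps (cap 5000), and is finished by the root polish, which
also replaces the stationary structure with the dominant eigenvector.
That polish is what makes invasion neutrality exact to ~1e−15 rather than
the iteration tolerance.

## Adaptive dynamics

The evolving trait is the sprouting-model intercept deviation `d_spr`
(default search bounds [−3, 3]), an intrinsic tendency to sprout
independent of state and weather. Invasion fitness is the mean annual log
growth of a rare mutant's share of the population:

- **Deterministic mode** takes the strict rare-mutant limit: the
  environment is the resident's stationary density, held fixed; the
  mutant founder is distributed over states in proportion to the resident
  stationary structure; per-step log growth is averaged after an
  automatic burn-in (iterate until successive log growth changes by
  < 1e−13, cap 2000, then average 100 steps). This equals the log
  dominant eigenvalue of the mutant matrix in the resident environment to
  ≤ 1e−6 and makes neutrality (fitness of a neutral clone) zero to
  ~1e−15. A full finite-share simulation cannot meet those contracts: the
  mutant's own density contribution and the power-iteration transient
  both perturb the mean at the 1e−3 level.
- **Stochastic mode** keeps the finite-share coupled simulation over 100
  drawn years (climate from the configured marginals, one deviation per
  rate per year, both genotypes sharing each drawn year and the total
  density), seeded and reproducible.

`find_ess` locates singular strategies by bracketing a sign change of the
selection gradient (central difference, step 1e−3) on a coarse scan and
refining with Brent's method; residents that cannot persist (λ₀ ≤ 1)
return NaN gradients and are skipped during bracketing. Classification
checks convergence stability (gradient decreasing through zero) and
strategy stability (negative second difference of fitness in the mutant
direction). Bootstrap SEs resample individuals with replacement (all of
an individual's records move together), refit the vital rates, and re-run
the search; the desk-scale default is 100 replicates.

## Forecasting

Simulated climate is bias-corrected additively by the difference in
overlap-period means (a ratio correction is available for precipitation);
corrected overlap means equal observed means to machine precision.
Optimization inputs for year *Y* are the mean climate over years
*Y*−25..*Y* (26 values; incomplete windows are omitted, never padded).
Each forecast year gets its own optimum `d*(Y)` from `find_ess` at that
window mean, with the previous year's optimum used as a warm start.
Per-year population growth is deterministic λ of the annual matrix built
at that year's *annual* climate values, with `d_spr = d*(Y)` or 0, and
without the density modifier (asymptotic rates); the ESS search, by
contrast, always runs density-coupled. Derived predictors missing from
simulated datasets (frost days, sunshine hours) are filled by least-squares
maps from shared variables, clipped to physical bounds; sunshine is
estimated from monthly shortwave radiation via a clearness-index relation
(relative sunshine duration = (K/K_clear)², times day length) whose site
constants are configuration, not code.

The with/without-evolution comparison is decomposed by a fixed-design
LTRE: contributions are (A_evolved − A_static) ∘ sensitivity evaluated at
the element-wise mean matrix, with sensitivities from the dominant
eigen-triple. Category sums (stasis in dormancy, growth to flowering,
shrinkage, fecundity, …) are derived from state metadata and partition
the contribution matrix exactly; the total matches Δλ to first order
(within 10% on the built-in fixtures).

## Synthetic data and the species-analogue fixtures

The generator draws each individual's fate in the conditional order
survival → sprouting → size (zero-truncated Poisson) → flowering →
flower count, with a shared per-year intercept deviation per rate, climate
covariates from the supplied series, and uniform positions on the plot.
Climate variables are independent normals (truncated for precipitation,
rounded for frost-day counts) — marginals only, no cross-correlation or
autocorrelation, which real climate has. Observation censoring emulates
the field reality that dormant plants are invisible: interior gaps between
emergences are reconstructed as dormancy; a terminal gap of 1..k years
(default k = 3) leaves the plant flagged dead-or-dormant and excluded
from survival responses; a longer terminal gap is classified as death in
the year after last emergence. The exact field criteria live in site
literature, so k is a configurable stand-in. One consequence worth
knowing: density-induced dormancy is partly misclassified as death by
this rule, which can shunt a true sprouting-density signal into the
survival screen; coefficient-recovery suites therefore fit the truth
tables, and screening fixtures are documented accordingly.

The three analogue bundles mirror the fitted sign structures of the study
populations at desk scale (historical toy space of order 86 with maximum
size 4; age × stage toy of order 31), with trade-offs constructed so the
optimum is interior and its climate response has a known sign:

- *parviflorum*-like: emergent-size survival cost amplified by frost
  days; dormancy is a refuge that preserves stored size (growth depends
  on previous size); large plants are dormancy-prone. Warming → upward
  optimum.
- *candidum*-like: the same structure with the size cost amplified by
  precipitation; a rise-and-return precipitation excursion → excursion
  and return of the optimum.
- *ophrys*-like: survival falls steeply with size (flowering partially
  rescues it), growth ratchets size upward while emergent, dormancy is
  the only reset, reproduction concentrates in small plants; wetting
  deepens the size cost → downward optimum.

Passing tests on these fixtures show that the pipeline recovers known
optima and known qualitative responses under its own generating
assumptions; they do not show that any real population has these
parameter values, and the deliberately simplified fixtures omit
observation error in size, spatially structured recruitment and climate
autocorrelation.

## Problem sizes

Desk-scale defaults keep the full suite and the acceptance script
comfortably reproducible: toy spaces for dynamics (orders 86 and 31) with
the full 395/173 spaces used for structural checks and matrix builds;
trajectories at a 5-year stride; 20 replicates of 500 × 20 cohorts for
coefficient recovery; grid oracles at 0.01 resolution; bootstrap demos at
B ≤ 4 with the production default at 100 (1000 matches the published
analysis scale).

## Known limitations

- Year effects are shrunken offsets, not a joint mixed-model likelihood;
  AICc comparisons involving the year term are approximate.
- The fruiting chain enters fecundity through its expectation at the
  expected flower count (no demographic stochasticity in the chain).
- Density feedback is mean-field (plot-level density); the 1-m grid is
  used for screening only.
- No stochastic (log) growth-rate forecasting; forecasts use the
  deterministic model throughout.
- The pairwise-invasibility classification reports raw sign patterns and
  local stability at located singular points; branching-point
  continuation is out of scope.
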