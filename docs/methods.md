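# Methods

## The experimental design and estimands

The package targets a fully crossed reciprocal-transplant design: two
sites, soil collected at both sites, and the two locally adapted
ecotypes, grown in all eight site × soil × ecotype combinations. Each
planted seedling is scored for survival to reproduction and, if
reproductive, fruit number; viable seeds per fruit are counted on one
intact mature fruit for the subsample of reproductive plants that still
carry one at harvest.

Overall fitness of a planted seedling is the expected seed number,
estimated as the plant's fruit count multiplied by the *cell mean* seeds
per fruit (fruit count is 0 for plants that died before reproduction).
Because the multiplier is a cell constant, the cell mean of this proxy
factorizes exactly:

    overall = survival × fecundity × seeds_per_fruit

which the code verifies as an invariant (`check_product_identity`,
relative tolerance 1e−12). Two deliberate conventions:

* an all-dead cell has overall fitness exactly 0 even though fecundity
  and seeds per fruit are undefined — every planted seedling set no seed;
* a cell with survivors but no seed-measured plant has *missing* overall
  fitness. The multiplier is never imputed from another cell, because
  the proxy is defined through the cell's own mean.

Selection against the non-local ecotype in a site–soil combination is
`s = 1 − w_nonlocal/w_local` for each of the four components; `s` is
undefined when the local mean is 0 (there is no meaningful reference).
Soil-specific adaptation at a site is the contrast
`Δs = s(local soil) − s(non-local soil)`, computed on the overall-fitness
scale and per component.

## Resampling inference

**Bootstrap CIs.** Confidence intervals are percentile intervals (linear
interpolation between order statistics) over replicates that resample
records with replacement independently within every site–soil–ecotype
stratum at its original size, preserving the design. The seeds-per-fruit
cell means — and hence the overall proxy — are recomputed inside every
replicate; the proxy is part of the estimator, so resampling must
propagate through it. Replicates in which `s` is undefined (for example
a resample of a sparse stratum with no survivor) are dropped and counted;
if more than 5% of replicates drop, the interval is flagged unreliable
and a warning is raised. Percentile intervals are the minimal choice
given only the resampling design; BCa or studentized intervals are out
of scope.

**Permutation test.** The null hypothesis of equal selection on the two
soils is tested by reshuffling soil labels uniformly among all records
within a site — the individual plant record is the permutation unit, its
ecotype and observations ride along, and per-soil totals are preserved —
and recomputing `Δs` for each reshuffle. Internally the engine always
shuffles the indicator of a fixed reference soil (the lexicographically
first label) and applies a sign afterwards, so the realized permutation
stream is identical whichever soil is called local; this makes the test
exactly antisymmetric under relabelling (Δs negates, p unchanged).

Two tail conventions are provided:

* **signed** (default): p = 2 · min(upper tail, lower tail) of the signed
  Δs null distribution, with ties counted in both tails. A single-tail
  "proportion greater, doubled" rule looks equivalent but is not: it
  gives different answers depending on which soil is labelled local,
  breaking the antisymmetry that any label-symmetric test must have, so
  the min-tail form is used.
* **absolute**: p = proportion of |Δs_perm| ≥ |Δs_obs|.

By default the add-one correction is applied, p = (1 + #exceedances)/
(n_perm + 1) per tail: it never returns 0 and is finite-sample valid. A
plain-proportion flag exists for strict replication of proportion-based
reports. In exhaustive mode every distinguishable soil-label assignment
is enumerated (the observed one included), the plain proportion is used,
and the test is exact; the engine refuses enumerations beyond 2 × 10⁶
assignments per site.

All randomness flows from a single seed in `ResamplingPlan`, split into
independent bootstrap and permutation streams, so a fixed seed and record
order reproduce every replicate.

## The synthetic-cohort generator

Per design cell the generator draws:

* survival ~ Bernoulli(p_cell);
* fruits among survivors ~ zero-truncated negative binomial with
  untruncated mean `fruit_mean` and dispersion `fruit_dispersion`
  (a reproductive plant has ≥ 1 fruit). Sampling uses inverse-CDF on
  (P(0), 1], so it is exact and reproducible;
* seeds per fruit ~ negative binomial with mean `seed_mean` and
  dispersion `seed_dispersion`, observed with probability `measure_prob`
  per survivor, independent of plant size (missing completely at
  random).

The negative-binomial family was chosen because field fecundity data are
overdispersed; dispersion → ∞ recovers Poisson for tests. Because every
ingredient has a closed-form mean — the zero-truncated fruit mean is
`μ / (1 − (k/(k+μ))^k)` — `derive_true_effects` returns the exact
per-cell component means, selection coefficients and between-soil
contrasts implied by a configuration, which is what the estimator
checks, coverage simulations and power analysis use as ground truth.

**Defaults.** The default configuration uses the design's cell sizes:
256 local and 264 non-local seedlings per soil per site, 2080 in total
(the extra non-local plants compensate for their lower winter survival).
Survival, fruit and seed parameters are field-realistic values chosen to
mirror the magnitudes of adaptive differentiation such experiments
report — roughly a 4.4-fold local overall-fitness advantage at the
Italian site and 6.2-fold at the Swedish site, with survival selection
stronger in Sweden and fecundity selection stronger in Italy, and about
85% of survivors seed-measured:

| site   | cell        | n   | survival | fruit mean | seed mean |
|--------|-------------|-----|----------|------------|-----------|
| Italy  | local       | 256 | 0.85     | 12         | 30        |
| Italy  | non-local   | 264 | 0.65     | 7          | 15        |
| Sweden | local       | 256 | 0.80     | 10         | 25        |
| Sweden | non-local   | 264 | 0.40     | 6          | 13        |

with `fruit_dispersion = 2`, `seed_dispersion = 4`, `measure_prob =
0.85`. Both soils share all parameters within a site, so every true Δs
is exactly 0 — the default is a soil-null configuration.

**What the generator does not emulate.** No spatial structure or block
effects (the design it models was fully randomized), no germination or
dormancy stage, no climate covariates, and no dependence of the
seed-measurement subsample on plant size. That last point matters for
interpretation: if in real data large plants were more likely to retain
an intact fruit, the seeds-per-fruit mean would be biased in a way the
MCAR generator cannot reveal, so passing tests certify the estimator
under MCAR subsampling only.

## Power analysis

A known soil effect is injected into a configuration by rescaling the
non-local ecotype's seed mean on the non-local soil of the target site.
Overall fitness is linear in the seed mean, so the factor that makes the
true Δs equal any requested value is closed-form,
`(1 − s_local_soil + Δs) / (1 − s_nonlocal_soil)`, and the injected truth
is exact to machine precision; a factor ≤ 0 (an effect that would wipe
out the cell's fitness) is rejected. Injection through a single
component keeps every other true quantity untouched. Other injection
channels (survival, fruit number) are out of scope.

`run_power` sweeps a (Δs, n) grid; per grid point it generates `n_sims`
cohorts (uniform per-cell n), runs the full pipeline, and reports the
rejection rate of the overall-fitness contrast at level α with its
binomial Monte-Carlo standard error, plus the mean and SD of the
estimated Δs. Power runs default to reduced resampling — no bootstrap,
200 permutations — as a fidelity/runtime trade-off appropriate for grid
sweeps; pass an explicit plan for full-fidelity points.

## Numerical and testing choices

* Means are plain arithmetic means; no trimming, shrinkage or weights.
* Undefined quantities propagate as NaN and are never imputed; every
  drop is counted and reported.
* Cell labels are free strings; the two-label universe is checked at
  analysis time, keeping the pipeline generic over any two-site design.
* Equality cases: `s` is exactly 0 when the two cell means are equal,
  and bootstrap intervals collapse to the point estimate for
  zero-variance strata (both hold exactly, not to tolerance, and are
  tested).
* The statistical acceptance suite uses 500 simulated cohorts at the
  full design size for the type-I-error band (α = 0.05, 500 permutations
  each, pooled over the two sites) and for bootstrap coverage (500
  resamples, pooled per component over the four site–soil pairs);
  parameter recovery uses 5000 plants per cell; the power grid uses
  Δs ∈ {0, 0.1, 0.25} × n ∈ {128, 264} with 80 simulations per point.
  These sizes give binomial bands tight enough to be informative while
  keeping the full suite at desk scale.

## Known limitations

* Only 2 × 2 × 2 designs: no more than two ecotypes or soils, no
  continuous soil gradients.
* The overall-fitness proxy ignores within-cell covariance between fruit
  number and seeds per fruit; that is a property of the proxy itself,
  faithfully reproduced, not corrected.
* No parametric selection models, no multiple-testing correction across
  the per-component contrasts (none is applied by design), and no
  analytic power approximations — power is purely Monte-Carlo.
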