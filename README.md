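# localadapt

Selection analysis for fully crossed **site × soil × ecotype**
reciprocal-transplant experiments, of the kind used to ask whether local
adaptation of a plant ecotype is driven by climate, by soil type, or both.
The package provides the complete analysis pipeline — fitness-component
estimation, selection coefficients with stratified bootstrap confidence
intervals, and a within-site soil-permutation test for soil-specific
adaptation — together with a matched synthetic-cohort generator with
closed-form true effects and a Monte-Carlo power layer, so the whole
pipeline can be exercised and calibrated without any external data.

It is aimed at evolutionary ecologists running (or reviewing) transplant
experiments with two sites, two soil origins and two ecotypes, where each
planted seedling is scored for survival to reproduction, fruit number, and
— on a subsample — viable seeds per fruit.

## The statistics

For every treatment cell (site × soil × ecotype) four fitness components
are computed:

* **survival** — mean survival to reproduction over planted seedlings;
* **fecundity** — mean fruit count over reproductive plants;
* **seeds per fruit** — mean viable-seed count over the measured subsample;
* **overall fitness** — expected seed number per planted seedling, taken as
  each plant's fruit count times the *cell-mean* seeds per fruit, averaged
  over all planted seedlings. This proxy satisfies
  `overall = survival × fecundity × seeds_per_fruit` exactly.

Selection against the non-local ecotype in each site–soil combination is

```
s = 1 − w_nonlocal / w_local
```

where `w` is the cell-mean fitness component. 95% CIs come from the
percentile interval over bootstrap resamples drawn independently within
every site–soil–ecotype stratum at its original size. Soil-specific
adaptation at a site is measured by `Δs = s(local soil) − s(non-local
soil)`; its null distribution is built by permuting soil labels among all
records within the site (each record keeps its ecotype and observations)
and the two-sided p-value doubles the smaller tail. On small sites the
permutation test can be run exhaustively, making it exact.

## Worked example

```python
import localadapt as la

cfg = la.GeneratorConfig.default(seed=42)   # the 2080-seedling design, no soil effect
cohort = la.generate_cohort(cfg)
res = la.SelectionModel(cohort).fit(la.ResamplingPlan(n_boot=1000, n_perm=1000, seed=1))
print(res.summary())
```

The default configuration places 256 local and 264 non-local seedlings per
soil per site (2080 in total), with both soils identical within a site, so
every true Δs is zero. Selected lines of the printed summary:

```
Selection against the non-local ecotype (s = 1 - w_nl/w_l)
  site   soil       component  s_hat  ci_low  ci_high
 Italy  Italy         overall 0.7956  0.7496   0.8384
Sweden Sweden         overall 0.8345  0.7767   0.8761

Between-soil contrasts (delta_s = s_local_soil - s_nonlocal_soil)
  site       component   delta_s  p_value  n_perm
 Italy         overall  0.005002   0.8631    1000
Sweden         overall  -0.01922   0.5435    1000
```

Read: the local ecotype enjoys strong selection in its favour at both
sites (s ≈ 0.80 and 0.83 on overall fitness — a four- to six-fold fitness
advantage), while the between-soil differences in selection are tiny
(|Δs| ≤ 0.02) and compatible with the true value of zero, exactly the
structure the generator encodes.

The same pipeline is available from the shell:

```sh
localadapt simulate --out cohort.csv --seed 42
localadapt analyze --input cohort.csv --n-boot 1000 --n-perm 1000 --seed 1 --out-dir results/
localadapt power --scenario scenario.yaml --out-dir power/
```

`analyze` accepts any cohort CSV with columns
`plant_id,site,soil,ecotype,survived,fruits,seeds_per_fruit,edge`, so field
data can be run through the identical code path.

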