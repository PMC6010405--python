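# phenonet

Within-season temporal dynamics of plant–flower-visitor interaction
networks: temporal beta diversity, quantitative bipartite modularity,
and phenology-driven module membership.

Seasonal pollination communities are usually summarized as one
cumulative network built from all visits recorded over a flowering
season. That summary hides whether interacting species actually
co-occur in time: pollinator assemblages turn over within a season, and
the modules of the cumulative network may simply be groups of species
that are active together. `phenonet` is a pipeline for asking exactly
that question on visitation census data from a single flowering season,
built for community ecologists working with short, intensively sampled
seasons (e.g. alpine systems). It provides:

- **Temporal sub-networks** — dated visitation records are aggregated
  into one weighted bipartite network per census day (or per pair of
  census days, or per ISO week), plus the season-wide cumulative
  network with weights A_ij = visits of visitor *j* to plant *i*.
- **Beta diversity in time** — pairwise Whittaker dissimilarity
  β = (a+b+c)/((2a+b+c)/2) − 1 of species (β_S) and interactions
  (β_WN), the rewiring component β_OS among shared species, and the
  multiple-site Jaccard dissimilarity β_CC with its exact additive
  partition into species replacement (β_3M) and richness difference
  (β_RICH), pooled over all pairs of census days.
- **Phenology** — per-species activity windows, start day of activity
  (days since 1 January), and the pairwise flowering-overlap index
  S_ij = a_ij/b_ij (shared flowering days over union flowering days).
- **Quantitative bipartite modularity** — the weighted Barber
  modularity Q = Σ_ij (A_ij/F − k_i d_j/F²)·1[g(i)=g(j)] maximized by
  restarted simulated annealing, with significance from a Z-test
  against marginal-preserving (Patefield) random networks.
- **Module phenology** — per-module activity profiles, one-way χ²
  tests with Monte-Carlo p-values and Holm correction, and a
  multinomial logistic regression of module membership on activity
  start day, with a likelihood-ratio χ² test and predicted membership
  probability curves.
- **A season simulator** — synthetic seasons with known ground truth
  (activity windows, latent temporal guilds) under two contrasting
  phenological scenarios, *concentrated* and *staggered*, so the whole
  pipeline can be validated end to end.

## Worked example

Simulate a staggered season (three temporal guilds of plants and
visitors) and run the full analysis:

```python
from phenonet import (SeasonConfig, simulate_season, aggregate, cumulative,
                      multisite_jaccard_partition, all_pairwise_network_beta,
                      ols_fit, BipartiteModularity, build_phenology,
                      fit_multinomial, turnover_lag)

cfg = SeasonConfig(scenario="staggered", seed=7)
records, flowering, truth = simulate_season(cfg)
subnets = aggregate(records, window="day")
cum = cumulative(records)
print(f"{len(subnets)} daily sub-networks; cumulative: "
      f"{len(cum.plants)} plants x {len(cum.visitors)} visitors, F = {cum.F}")

part = multisite_jaccard_partition([set(n.plants) for n in subnets])
print(f"plants: beta_CC = {part.beta_cc:.2f} = beta_3M {part.beta_3m:.2f} "
      f"+ beta_RICH {part.beta_rich:.2f}  (replacement share {part.replacement_share:.0%})")

betas = [b for b in all_pairwise_network_beta(subnets) if b.time_lag > 0]
fit = ols_fit([b.time_lag for b in betas], [b.beta_wn for b in betas], transform="log-lag")
print(fit.summary())
lag = turnover_lag(betas)
print(f"complete interaction turnover beyond {lag.lag} days "
      f"({lag.n_pairs_at_or_beyond} network pairs)")

res = BipartiteModularity(cum).fit_significance(n_runs=50, n_null=50, null_runs=10, seed=7)
print(res.summary())

phen = build_phenology(records, flowering)
starts = {s: phen[s].start_day for s in cum.species if s in phen}
mfit = fit_multinomial(starts, {s: res.assignment[s] for s in starts})
print(mfit.summary())
```

which prints:

```
10 daily sub-networks; cumulative: 16 plants x 110 visitors, F = 2316
plants: beta_CC = 0.74 = beta_3M 0.56 + beta_RICH 0.17  (replacement share 76%)
OLS (transform=log-lag): slope=0.2368 intercept=0.1866 R2=0.640 p=4.37e-11 n=45
complete interaction turnover beyond 29 days (10 network pairs)
Quantitative bipartite modularity
  network: 16 plants x 110 visitors, F=2316
  Q = 0.5067  modules = 3  restarts = 50
  null (n=50): mean Q = 0.1225 sd = 0.0043  Z = 89.96  p = 0  p_rank = 0.0196
Multinomial logistic regression: module ~ start day of activity
  n = 126  modules = 3 (reference: 0)
  LR chi2 = 166.53  df = 2  p = 6.89e-37
  converged = True  quasi-separation flag = False
  module        intercept     slope/day
  1               -90.5244      0.5287
  2              -148.8730      0.8426
```

Reading the output: most of the dissimilarity among daily plant
assemblages is species replacement (β_3M is 76% of β_CC), interaction
dissimilarity β_WN rises log-linearly with the time lag between census
days and saturates at complete turnover for lags ≥ 29 days, the
cumulative network is strongly modular relative to its
marginal-preserving nulls (Z ≈ 90), the three detected modules recover
the three latent guilds, and a species' activity start day almost
perfectly predicts its module (LR χ² = 166.5 on 2 df).

The same pipeline runs on field data from the shell:

```bash
phenonet simulate --scenario staggered --seed 7 --out season/
phenonet analyze season/interactions.csv --flowering season/flowering.csv \
    --runs 100 --nulls 100 --seed 1 --out results/
```

`analyze` accepts any interaction file with columns
`date,site,plant,visitor,functional_group,visits` (ISO dates; comma or
tab separated) and writes per-site tables: multiple-site and pairwise
beta diversity, β-vs-lag regressions, the module partition with its
null-model test, module activity profiles with Monte-Carlo χ² tests,
and the multinomial membership report with predicted probability
curves. Deposited datasets with other column headers can be converted
with `phenonet.read_mapped` and a user-edited column-mapping file.

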