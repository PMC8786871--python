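# paleorates

Bayesian estimation of speciation and extinction dynamics directly from
dated fossil occurrences — no phylogeny required.  Built for
palaeobiologists analysing the macroevolution of extinct clades (the kind
of question: *why did a once-dominant group of carnivores decline and
disappear?*), it covers the full workflow from raw occurrence tables to
rate curves and correlation tests:

1. **Curation** (`paleorates.fossil_records`) — read delimited occurrence
   tables, drop taxonomically uncertain records (cf. / aff. / ?), drop
   records dated with ≥ 15 Ma uncertainty, restructure into four dataset
   variants (species occurrences, fossil specimens, stage-dated
   occurrences, genus occurrences), and draw 20 age-randomised replicates.
2. **Preservation model choice** (`paleorates.preservation`) — homogeneous
   vs hump-shaped (NHPP) Poisson fossil recovery, with optional
   Gamma-distributed rate heterogeneity across species, compared by AIC.
3. **Rate inference** (`paleorates.birth_death`) — reversible-jump MCMC
   over each species' speciation time `Ts` and extinction time `Te`, the
   preservation parameters, and piecewise-constant speciation `λ(t)` and
   extinction `μ(t)` profiles with an unknown number of shifts.  Replicate
   chains are pooled; outputs are rate-through-time curves with 95% HPD
   bands, net diversification `r = λ − μ`, and diversity trajectories.
4. **Trait correlation** (`paleorates.trait_covar`) — per-lineage rates
   linked to centred log body mass, `λ_i = λ0 e^{α_λ x_i}`,
   `μ_i = μ0 e^{α_μ x_i}`; `α` significant when 0 is outside the 95% HPD.
5. **Environmental/biotic correlation** (`paleorates.env_mbd`) — a
   multivariate birth–death model with rates driven (linearly or
   exponentially) by rescaled covariate series (CO₂, temperature proxy,
   sea level, palaeoelevation, clade diversities), a horseshoe prior
   separating signal from noise via shrinkage weights (`w > 0.5` = signal),
   and linear-vs-exponential comparison by thermodynamic-integration log
   Bayes factors.
6. **Synthetic records** (`paleorates.synthetic_fossils`) — a generator of
   fossil records, traits, and covariates with known truth, used by the
   whole validation suite.

A thin CLI (`paleorates simulate|build|modeltest|bd|covar|mbd|report`)
orchestrates the stages with run manifests; see `docs/methods.md` for the
models, priors, and numerical choices.

## Worked example

Simulate a fossil record at study-like conditions (hump-shaped
preservation, q = 4 occurrences/lineage/Ma, dating windows up to 6 Ma),
curate it, and estimate rates from four age-randomised replicates:

```python
import numpy as np
from paleorates.preservation import PreservationModel, PreservationKind
from paleorates.synthetic_fossils import (SimScenario, conditioned_on_size,
    simulate_bd_lineages, simulate_preservation, make_occurrence_table)
from paleorates.fossil_records import (filter_taxonomy, filter_age_uncertainty,
    build_dataset, resample_replicates, summarize_counts)
from paleorates.birth_death import (MCMCConfig, rjmcmc_run,
    combine_replicates, rates_through_time)

scen = SimScenario(seed=11, lam=0.3, mu=0.2, origin=30,
                   preservation=PreservationModel(kind=PreservationKind.NHPP, q=4.0),
                   n_cap=1500)
lineages = conditioned_on_size(simulate_bd_lineages, scen, 80, 200)
fossils, n_unobserved = simulate_preservation(lineages, scen.preservation, seed=12)
table = make_occurrence_table(fossils, window_max=6.0, seed=13)
table = filter_age_uncertainty(filter_taxonomy(table))
dataset = build_dataset(table, "species_occurrence")
print("taxa, occurrence rows:", summarize_counts(dataset))
print("unobserved species:", n_unobserved)

reps = resample_replicates(dataset, n=20, seed=14)
chains = [rjmcmc_run(rep, MCMCConfig(generations=20_000, sampling_freq=100, seed=100+i))
          for i, rep in enumerate(reps.replicates[:4])]
pooled = combine_replicates(chains)
rtt = rates_through_time(pooled, np.arange(25.0, -0.01, -5.0))
print(rtt.table[["age", "lam_mean", "mu_mean", "r_mean", "div_mean"]].round(3))
```

Output:

```
taxa, occurrence rows: (142, 464)
unobserved species: 7
 age  lam_mean  mu_mean  r_mean  div_mean
25.0     0.154    0.025   0.129     5.173
20.0     0.154    0.026   0.128     8.748
15.0     0.154    0.027   0.127    22.945
10.0     0.154    0.029   0.125    38.270
 5.0     0.154    0.059   0.095    70.995
```

142 of 149 simulated species were preserved at least once (464 occurrence
rows after curation).  The posterior rate curves are flat — the data were
generated under constant rates, and the reversible-jump sampler finds no
support for shifts — with `λ` ≈ 0.154 and `μ` ≈ 0.03 per lineage per Ma
over the well-sampled interval and a rising mean diversity toward the
recent.  (The apparent extinction burst at age 0, not shown, is the
present-day edge: the example treats every species as extinct, so
terminal `Te` values pile up near 0; pass `extant=` to `rjmcmc_run` for
clades with living members.)

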