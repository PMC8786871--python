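# Methods

`paleorates` estimates speciation and extinction dynamics of extinct clades
directly from dated fossil occurrences, without a phylogeny.  This note
records the models, the numerical choices, and what the synthetic-data
validation does and does not demonstrate.

## The observation model

The unit of data is a fossil occurrence: a taxon observed at one
stratigraphic level of one locality, dated to a window `[min_age, max_age]`
in Ma before present.  Four dataset variants can be built from a curated
occurrence table:

* **species occurrences** — deduplicated by (species, locality, stratum);
* **fossil specimens** — every specimen kept;
* **stage-dated occurrences** — species occurrences with windows replaced by
  the bounds of a user-supplied stage table (e.g. South American
  Age/Stage units);
* **genus occurrences** — deduplicated by (genus, locality, stratum).

Curation removes records with open-nomenclature qualifiers (cf., aff., ?)
and records whose dating window is 15 Ma or wider (strictly narrower than
15 Ma is kept).  Dating uncertainty is then propagated by drawing 20
replicate datasets with each occurrence age resampled uniformly within its
window; all downstream posteriors pool the 20 replicate chains with equal
weight.  Uniform resampling is the minimal assumption given only window
endpoints.  A missing stratum field is treated as a single unnamed stratum
per locality.  The 15 Ma filter is applied before stage substitution in
`age_stage` mode.

## Preservation

Fossil recovery along a lineage's life span `[te, ts]` is a Poisson process
with rate `q` (expected occurrences per lineage per Ma).  Three variants:

* **HPP** — constant intensity; per-species log likelihood
  `k log q − q (ts − te)` (unconditioned; a `condition_on_detection`-style
  correction is deliberately not applied by default so likelihoods remain
  comparable across models, and species enter the data only when observed
  at least once).
* **NHPP** — hump-shaped intensity `q · f(u)` with
  `u = (ts − age)/(ts − te)` and `f` the symmetric Beta(`a`, `a`) density;
  `a = 1` recovers HPP exactly, `a > 1` concentrates preservation
  mid-life-span.  The Beta family is this package's concrete definition of
  the one-parameter bell; the intensity integrates to `q (ts − te)` for
  every `a`, so `q` retains its interpretation.
* **Gamma heterogeneity** — per-species `q` multiplied by a mean-one
  Gamma(`α`, `α`) factor, discretised into 4 equal-probability categories.
  Category values are the conditional bin means (computed from the
  Gamma(`α`+1, `α`) CDF), not quantile midpoints: the means always average
  exactly 1, and one category reproduces the base model identically.

Model choice uses maximum likelihood and AIC, with each species' life span
proxied by its observed stratigraphic range.  Because the Beta bell
vanishes at the endpoints for `a > 1`, the proxy span is padded outward by
5% of the range plus 0.1 Ma so observed fossils are interior points; this
also regularises singleton species whose observed range is a point.  Ties
in AIC go to the model with fewer parameters.

## Birth–death inference

Given per-species speciation/extinction times (`ts`, `te`), the clade
follows a birth–death process with piecewise-constant rate profiles
`λ(t)`, `μ(t)`.  The log likelihood is
`Σ_k [B_k ln λ_k + D_k ln μ_k − (λ_k + μ_k) T_k]` over rate intervals,
where `B_k` counts speciation events (every `ts` except the single oldest
lineage's origin, which has no scored parent event), `D_k` extinction
events, and `T_k` the summed lineage time.  `ts`, `te` are latent,
constrained by each species' oldest/youngest fossil, and sampled jointly
with the preservation parameters and both rate profiles.

The sampler is a reversible-jump MCMC.  Moves: single-species sliding
windows on `ts`/`te`; multiplier updates on `q`, the NHPP shape, and
individual interval rates; birth/death of rate shifts; and shift-time
slides.  Shift birth proposes the new time uniformly over the data span
and the new (younger-interval) rate from its Gamma(1.1, 1) prior, so prior
and proposal densities cancel and the acceptance ratio reduces to
`(L'/L) · Λ/(k+1)` (times the boundary-move correction), with
`k ~ Poisson(Λ = 1)` shifts a priori.  Priors: rates Gamma(1.1, 1), shift
times uniform order statistics, `ts`/`te` flat subject to the fossil
constraints, `q` Gamma(1.1, 1), shape parameters log-normal.  Proposal
windows adapt toward ~30% acceptance during the first 20% of generations
(the burn-in, which is discarded) and are frozen afterwards, preserving
detailed balance for every retained sample.

Summaries: rates evaluated per posterior sample on a 0.1 Ma age grid;
means with 95% highest-posterior-density bands (quantile intervals are not
used); net diversification `r = λ − μ` computed per sample before
summarising; diversity as the mean number of lineages with
`ts ≥ age > te` (closed at the speciation end).  Effective sample sizes
use the rank-normalised bulk estimator.

## Body-mass-correlated rates (Covar)

Per-lineage rates follow an exponential link on centred natural-log body
mass `x_i`: `λ_i = λ0 e^{α_λ x_i}`, `μ_i = μ0 e^{α_μ x_i}`.  Centring
makes the baselines the rates of a mean-mass lineage and renders the
likelihood invariant to rescaling all masses by a constant.  Because the
early record is sparse, only species with `ts` strictly younger than 30 Ma
enter.  The sampler is a random-walk Metropolis over
(log λ0, log μ0, α_λ, α_μ) that cycles across supplied posterior life-span
samples (one per 1,000 generations) to propagate `ts`/`te` uncertainty,
rather than re-estimating everything jointly — a two-stage design matching
how the rate and correlation analyses are layered.  A correlation is
called significant when 0 lies outside the 95% HPD interval.

## Multivariate covariate model (MBD)

Time-varying rates are linked to J rescaled covariate series
(`x_j(t) ∈ [0, 1]`):

* linear: `rate(t) = rate0 · max(0, 1 + Σ G_j x_j(t))`
* exponential: `rate(t) = rate0 · exp(Σ G_j x_j(t))`

with separate coefficients for speciation (`G_i`) and extinction (`G_m`).
Covariates are linearly interpolated onto the shared 0.1 Ma grid
(nearest-value extrapolation outside their span); exposure per bin uses
exact interval overlap, so setting all `G = 0` reproduces the
constant-rate likelihood to machine precision.  If the linear form floors
a rate at 0 in a bin containing an event the likelihood is −∞; parameters
are never silently repaired.

A horseshoe prior separates signal from noise:
`G_j ~ N(0, local_j² τ²)` with half-Cauchy local and global scales,
sampled through inverse-gamma auxiliary variables whose conditionals
depend only on the `G`s and therefore stay conjugate under any likelihood.
The shrinkage weight `w_j = 1 − 1/(1 + local_j² τ²)` flags covariate `j`
as signal when its posterior mean exceeds 0.5.  The `G` updates use a
two-component Metropolis proposal: a wide (sd 0.5) component to cross
between the shrunk and unshrunk regimes and a narrow component matched to
the current prior scale.  With a fixed-width proposal the chain freezes at
`G = 0` while the Gibbs steps collapse the scales to the numerical floor —
the familiar funnel of the centred horseshoe, which the mixture proposal
resolves; scale draws are additionally clipped to `[1e−12, 1e12]`.

Linear and exponential links are compared with log Bayes factors from
thermodynamic integration: power-posterior chains at 16 temperatures
`β = (i/15)^{1/0.3}` (dense near 0), trapezoidal integration of the mean
tempered log likelihood.  Both `log BF` and `2 log BF` are reported with
the conventional verbal categories, since "BF" is printed on different
scales in different sources.

## The synthetic-fossil generator

The generator emulates the statistical structure the inference assumes, at
study-realistic conditions: clade histories of tens of Ma; preservation in
the empirically reported range of roughly 1–22 expected occurrences per
lineage per Ma (default q = 3, hump-shaped with a = 2); dating windows up
to (but strictly below) 15 Ma wide so synthetic records survive the
curation filter by construction; body masses log-normal around 5 kg with
log-sd 1.5, spanning roughly 0.3–200 kg in a founder-rich stand; covariate
curves (trend, random walk, sinusoid) emitted unrescaled.

Simulation is an exact event-driven (Gillespie) scheme; time-varying rates
are piecewise-constant on the same 0.1 Ma lattice the inference uses, so
generative and inferential discretisations match.  Species with zero
preserved fossils are dropped from the emitted record and counted, making
taxon-sampling incompleteness explicit.

Two design choices matter for validation and are deliberate:

* **Trait heritability.**  In the trait-linked regime a daughter species
  perturbs its parent's log mass by a Normal(0, 0.25) innovation (founders
  draw from the stand distribution).  Drawing each species' trait
  independently would decouple a species' trait from its origination event
  while the Covar likelihood scores each birth at the born species' own
  rate; heritable traits make the generative process consistent with that
  attribution, as body mass is across speciations in real clades.
* **Single-root conditioning.**  Recovery experiments simulate from one
  founder and re-draw (with derived sub-seeds) until the clade size falls
  in a target range — conditioning on a usable realisation, analogous to
  conditioning on clade survival.  Starting many founders at once places a
  spike of co-origin "birth events" at the origin that the likelihood has
  no way to attribute, and measurably biases coefficient recovery.

What passing these simulations does **not** show: robustness to
taphonomic structure the generator lacks (spatially clustered localities,
correlated dating errors, taxonomic lumping/splitting), to model
misspecification of the preservation bell, or to covariates measured with
error.  Real-data conclusions inherit those caveats.

## Problem sizes and runtimes

The full-scale presets mirror the study settings (20,000,000 generations
sampled every 5,000 for the birth–death and Covar samplers; 200,000,000 /
50,000 for MBD; 20 replicates).  The `desk` preset divides generation
counts by 100 with identical architecture, and is what the test suite and
the acceptance script use, with validation problem sizes chosen as the
package's own balance of power against runtime: ~200-species clades for
rate recovery, 10 seeds for the recovery protocols, 20 datasets for
interval calibration.  At these sizes the whole validation battery runs in
minutes on one core.

## Known limitations

* Preservation is time-homogeneous per lineage (no epoch-specific rates).
* The birth–death likelihood treats lineages exchangeably; no topology.
* The Covar and MBD stages condition on life spans sampled upstream; they
  cycle over posterior draws rather than integrating jointly.
* The linear MBD link is not differentiable at the rate floor; inference
  near the floor relies on the −∞ guard rather than gradient information.
* Bayes-factor scale conventions differ across the literature; both
  scales are emitted and the verbal category uses `2 log BF`.
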