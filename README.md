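# batjsdm

Hurdle joint species distribution modelling of bat assemblage change in a
fragmented landscape with a regenerating secondary-forest matrix.

## The problem

Long-term fragmentation studies ask whether the recovery of the matrix —
the secondary forest growing back between old-growth fragments — helps or
hurts the species living in a landscape.  Capture data from mist-netting
surveys are hard to analyse species by species: most species are rare,
the count matrix is ~70% zeros, and effort differs wildly between sites
and survey periods.  `batjsdm` implements the full analysis chain for
this setting:

1. **CLAM classification** — each species is labelled an old-growth
   specialist or habitat generalist from its capture totals in primary
   versus disturbed habitat, using the supermajority multinomial test
   (threshold K = 2/3, level P = 0.01) with coverage-adjusted relative
   abundances.
2. **Hierarchical hurdle JSDM** — a joint model over all species with a
   probit submodel for presence–absence and an overdispersed-Poisson
   (lognormal-mixed) submodel for abundance conditional on presence:

   ```
   model 1:  y_ji = 1[z_ji > 0],     z_ji = x_j'β_i⁽¹⁾ + η_s(j)'λ_i⁽¹⁾ + ε_ji,   ε ~ N(0,1)
   model 2:  y_ji - 1 | y_ji ≥ 1  ~  Poisson(exp(L_ji)),
             L_ji ~ N(x_j'β_i⁽²⁾ + η_s(j)'λ_i⁽²⁾, σ_i²)
   community:  vec(B) ~ N(vec(ΓT'), V ⊗ W(ρ)),   W(ρ) = ρC + (1-ρ)I
   ```

   Traits (specialist/generalist) drive coefficient means through Γ, a
   phylogenetic correlation C (Brownian diffusion on the species tree)
   structures coefficient covariance with weight ρ, and latent factors
   (site scores η, species loadings λ under multiplicative-gamma
   shrinkage) give each site a community-level random effect.  Fitting is
   by a blocked Gibbs sampler (truncated-normal data augmentation, slice
   sampling for the log rates), bit-reproducible under a fixed seed.
3. **Posterior summaries** — per-visit expected species richness
   (Σ occurrence probabilities) and individuals (Σ occurrence ×
   (conditional abundance + 1)) under habitat-standardized effort;
   species-level between-period changes with posterior support; and
   assemblage similarity, defined as the per-draw Pearson correlation of
   log-transformed predictions between two assemblages.

A synthetic-data module generates full datasets from the model itself
(19 sites, 2 periods, 301 sessions, 50 species, ~70% zeros) with known
ground truth, so the whole pipeline is testable without any download.
See `docs/methods.md` for model details, priors and design choices.

## Worked example

```sh
batjsdm simulate --species 50 --seed 1 --out demo/
batjsdm run-all --captures demo/captures.csv --covariates demo/covariates.csv \
        --tree demo/phylogeny.nwk --seed 7 --mcmc-iter 2000 --out demo/run
```

The first command writes a synthetic landscape (`zero fraction 0.682`) in
which specialists were planted to benefit from matrix regeneration in
period 2.  The second runs CLAM → fit → predict → change → similarity;
`demo/run/` then contains `clam.csv`, the posterior archive
(`posterior.npz` + JSON sidecar), `predictions.csv`, `change.csv`,
`similarity.csv` and a manifest.  Expected per-visit species richness
(posterior means from `predictions.csv`):

```
period                     1      2
habitat    group
continuous generalist  12.75  11.83
           specialist   4.24   3.32
fragment   generalist  13.23  14.60
           specialist   4.57   7.07
secondary  generalist  10.91  10.26
           specialist   2.52   2.61
```

Specialist richness in fragments rises from 4.6 to 7.1 expected species
per visit between periods — the planted regeneration benefit — while
generalists barely move.  `similarity.csv` gives the matching turnover
view, e.g. for generalists between continuous forest and fragments the
occupancy-scale similarity moves from 0.98 to 0.95 with posterior
probability 0.12 of an increase (no supported change), and
`prob_increase` 0.80+ for the continuous:secondary comparisons where the
planted signal pushes assemblages together.  Effort is standardized
within habitat, so numbers are comparable between periods but not across
habitats.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline from scratch at desk scale: it generates the
default 50-species synthetic world from the given seed, runs every stage
(classification, both Gibbs-sampled submodels, predictions, change and
similarity tables) and writes the JSON report to `--out`.  The
statistical correctness checks themselves live in
`tests/test_acceptance.py`: quadrature equivalence for the probit
posterior, a joint-distribution (Geweke-style) sampler test, credible-
interval coverage on synthetic ground truth, an exact brute-force oracle
for the CLAM rules, exact prediction/similarity identities, and the
calibrated zero fraction.
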