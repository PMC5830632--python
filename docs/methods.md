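# Methods

`batjsdm` implements a complete analysis chain for asking how a bat
assemblage in a fragmented, regenerating tropical landscape changed
between two survey periods: classify species by habitat affinity, fit a
hierarchical joint species distribution model (JSDM) to session-level
capture data, and summarise the posterior as standardized per-visit
richness/abundance, species-level change probabilities, and model-based
assemblage similarity.

## Sampling design and data model

The sampling unit is one mist-netting session at one site.  The emulated
design has 19 sites in three habitat classes (6 continuous forest, 6
fragments, 7 secondary forest), two survey periods, and ~301 sessions with
heterogeneous effort measured in mist-net hours (mnh).  Counts form a
session x species matrix dominated by zeros (~70%).

The hurdle split separates presence/absence from abundance conditional on
presence: `Y_occ = 1[count > 0]`, and where present `Y_cond = count - 1`
(conditional on presence the smallest count is one, so subtracting one
matches the support of the count distribution).  Absent cells are treated
as *missing data* in the abundance submodel — represented by an explicit
mask, never by sentinel values — so zeros carry no information about
conditional abundance.

The session design matrix has nine fixed columns: intercept, fragment and
secondary-forest dummies (continuous forest is the reference), a period-2
dummy, secondary-forest cover within 500 m (as a proportion, for
conditioning of the coefficient scale), natural-log effort, and the
period x habitat and period x cover interactions.  Continuous covariates
are not z-scored by default (a flag enables it): keeping the raw scales
makes the standardized prediction grid transparent.

## CLAM habitat-affinity classification

Species are classified from capture totals in two habitat pools
(continuous primary forest vs fragments + secondary forest) with the
supermajority multinomial scheme: with threshold K (default 2/3), a
species is a habitat-1 specialist when the one-sided test rejects
`p1 <= (K/(1-K)) p2` at level alpha (default 0.01), and symmetrically for
habitat 2; a generalist when both one-sided tests reject
`p1 <= ((1-K)/K) p2` and `p2 <= ((1-K)/K) p1`; otherwise too rare to
classify.  Relative abundances are coverage-adjusted: species with fewer
than `coverage_limit` (default 10) individuals in a habitat have `y/N`
multiplied by the estimated sample coverage `1 - f1/N` (f1 = singleton
count), discounting rare species under unequal effort.  Tests use the
normal approximation with independent Poisson variances `y/N^2`; ties at
the critical boundary resolve to the less specialized category.

A widely used R implementation of this classifier differs in two details:
binomial rather than Poisson variances, and a geometric minimum-abundance
rule for the too-rare region.  The variants agree except for boundary
species; the Z-test/Poisson construction implemented here is the
documented contract of this package and is pinned by an exact brute-force
oracle test.

For downstream analysis the four categories collapse to two functional
groups: primary-forest specialists and too-rare species ("specialists" —
conservative pooling, since too-rare species are predominantly old-growth
taxa), and generalists plus the few disturbed-forest specialists
("generalists").  Raw (not effort-weighted) totals are used; an
effort-weighted variant would be a sensitivity analysis, not the default.

## The hurdle JSDM

Both submodels share one architecture.  For session j and species i:

* **Model 1 (occurrence, probit):** `Y_occ[j,i] = 1[Z_ji > 0]`,
  `Z_ji = x_j' b1_i + eta1_{s(j)}' l1_i + e_ji`, `e ~ N(0,1)`.
* **Model 2 (abundance | presence, overdispersed Poisson):** on present
  cells only, `Y_cond[j,i] ~ Poisson(exp(L_ji))` with
  `L_ji ~ N(x_j' b2_i + eta2_{s(j)}' l2_i, sigma_i^2)` — lognormal mixing
  of the Poisson rate, which keeps the latent-Gaussian architecture (a
  negative-binomial variant is out of scope).

Community level, each submodel: the p x S coefficient matrix B is matrix
normal around the trait regression `Gamma T'` (T columns: intercept,
specialist indicator), with row covariance V (among covariates) and column
covariance `W(rho) = rho C + (1 - rho) I_S`.  C is the Brownian-diffusion
correlation implied by the phylogeny: shared root-to-MRCA path length
scaled by the maximum root-to-tip depth (non-ultrametric trees are
accepted and normalised by maximum depth; the diagonal is forced to 1).
`rho in [0,1]` measures phylogenetic signal in the environmental
responses.  Site effects use the latent-factor construction: sites carry
H-dimensional scores (standard normal prior) and species carry loadings
under the multiplicative-gamma process (MGP) shrinkage prior, inducing a
low-rank between-species residual covariance.

The two submodels have separate Gamma, V, rho and factor sets: nothing in
the data forces occurrence and conditional abundance to share community
structure, and coupling them is a stronger assumption than keeping them
apart.

### Priors (defaults, all exposed in configuration)

| block | prior | default |
|---|---|---|
| Gamma entries | Normal(0, v) | v = 10 |
| V | Inverse-Wishart(nu0, Psi0) | nu0 = p + 2, Psi0 = I |
| rho | uniform on a grid | 51 points {0, 0.02, ..., 1} |
| loadings | MGP (a1, a2, nu) | a1 = 2, a2 = 3, nu = 3 |
| sigma_i^2 | Inverse-Gamma(a, b) | a = 1, b = 0.3 |

These are standard weakly-informative choices for this model family; the
exact constants are package defaults, not estimates of any published
configuration.

### Gibbs sampler

One sweep updates, in order, for model 1 then model 2: the latent block
(truncated-normal Z, or slice-sampled log rates L), then B, Gamma, V, the
gridded rho, the factor block (eta, lambda, MGP locals), and finally the
overdispersion variances.  All full conditionals are conjugate except:

* **Z:** truncated normals sampled by the inverse *survival* function in
  log space (`ndtri_exp` + `log_ndtr`), accurate arbitrarily far into the
  tail where the naive inverse-CDF loses all precision.
* **L:** per-cell slice sampling (stepping-out, width 1.0, unlimited
  steps, shrinkage) targeting `Poisson(y|e^L) N(L | g, sigma_i^2)`; the
  target is log-concave, so both loops terminate.  Parameterising the
  state as the log rate L (rather than the residual e = L - g) keeps the
  coefficient and factor updates conjugate with pseudo-data L.
* **rho:** discrete full conditional over the grid, computed in the
  eigenbasis of C with log-sum-exp stabilisation.

The default run length follows the analysis this package reproduces:
50,000 sweeps with 15,000 discarded as transient; draws are thinned by 10
for memory.  The factor count is fixed (H = 3 by default) rather than
adaptively truncated: adaptive factor birth/death breaks bit-level seed
reproducibility, which the package guarantees (same data + spec + seed =>
identical draws).  Absent cells are simply skipped by all model-2
updates; nothing is imputed.

Correctness is pinned by three kinds of evidence in the test suite:
closed-form conditional checks (GLS/ridge posterior for a single species,
prior recovery for data-free blocks, uniform rho under C = I), an exact
2-D quadrature oracle for the single-species Bayesian probit posterior,
and a joint-distribution (Geweke-style) test comparing prior forward
simulation with the successive-conditional sampler on a tiny model.  For
the latter, each successive-conditional chain is started from an exact
joint draw (prior parameters + simulated data), so it is stationary from
the first sweep; Monte-Carlo error is estimated from independent
replicate chains because some components (notably model-2 intercepts)
carry autocorrelation times of order 10^2 sweeps that single-chain
estimators miss.

## Predictions under standardized effort

Predictions are made on a 6-row habitat x period grid: effort is set to
the habitat's mean mnh pooled over both periods (so within-habitat
comparisons between periods are effort-corrected; comparisons *across*
habitats are not meaningful), and cover to the habitat's site mean in that
period.  Per draw and species:

* occurrence probability `Phi(x'b1 / sqrt(1 + ||l1||^2))` — the site
  effect is marginalised analytically (probit variance inflation), which
  reads as prediction for a generic new site;
* expected captures `P(occ) * (exp(x'b2 + (sigma^2 + ||l2||^2)/2) + 1)` —
  lognormal marginalisation over overdispersion and site effect, the +1
  restoring the count scale.

Conditioning on a typical site (eta = 0) instead is available via a flag;
it drops the `||l||^2` terms.  Expected richness is the per-draw sum of
occurrence probabilities over a species group; expected individuals the
sum of expected captures.  Headline uncertainty is the posterior standard
deviation.  Species-level change is the posterior mean of the period-2
minus period-1 difference, with directional support the fraction of draws
strictly positive (or negative); "high support" flags fractions above
0.95.  Ties count toward neither direction, so identical draws yield zero
support in both.

## Assemblage similarity

The similarity between two assemblages (habitat x period conditions) is
the Pearson correlation across species of log-transformed predicted
occurrence probabilities (occupancy scale) or expected abundances
(abundance scale), computed per posterior draw; the posterior probability
of a between-period similarity increase is the fraction of draws in which
the period-1 value is strictly below the period-2 value.  Per-draw
computation is the default because it is what supports that posterior
probability; correlating posterior-mean predictions first is available as
a flag.  Predictions that underflow to zero are floored at a configurable
1e-12 before logging (with a warning): probit probabilities are never
analytically zero but can underflow in double precision.  Pearson (not
rank) correlation is used: the explicit log transform indicates
product-moment correlation on log scale, which is invariant to a global
multiplicative rescaling of either assemblage.

## Synthetic world

The generator emulates the study design, not any particular dataset:

* 19 sites (6/6/7 by habitat), two periods, session counts per site
  chosen so the total is exactly 301;
* effort lognormal with log-sd 0.5 and per-habitat medians 180/180/60 mnh
  (continuous/fragment/secondary) — secondary-forest sites were sampled
  with far fewer net-hours, and the uneven medians exercise the effort
  covariate and the standardization logic;
* cover uniform within habitat bands (continuous 0–10%, fragments
  30–70%, secondary 60–95%) shifted +10 points (capped at 100) in period
  2, a plausible regeneration signal with no claim of fidelity to real
  maps;
* 50 species, 27 specialists / 23 generalists; a unit-depth pure-birth
  phylogeny (general-sampling-approach simulator, so terminal branches
  are strictly positive and C is non-singular);
* coefficients drawn around fixed trait-level means whose signs encode
  the emulated ecology (specialists rarer, avoiding modified habitats in
  period 1, benefiting from regeneration), with rho = 0.5, V = 0.1 I,
  N(0, 0.3^2) loadings, standard-normal site scores and uniform [0.2,
  0.5] overdispersion variances.

The occurrence intercept (-2.40 for generalists, -0.80 specialist offset)
was calibrated once so the default world yields ~70% zero cells (seed 1:
0.68; mean over ten seeds: 0.70), and then frozen.  The generator does
*not* emulate: the real species-abundance distribution, fragment
re-isolation events, spatial coordinates or distance-dependent
correlation between sites, or dates/seasonality.  A green recovery test
therefore establishes that the sampler recovers parameters of a
well-specified model at this design's information content — not
robustness to the mis-specifications real data would add.

Two identifiability notes documented by the tests: (i) factor loadings
are identified only through the product eta * lambda' (and up to sign);
under a null site effect the realized site-effect magnitude collapses
while individual loadings remain prior-scale, so shrinkage is asserted on
the product.  (ii) Because cover bands barely overlap between habitats,
cover and the habitat dummies are strongly collinear — intervals remain
calibrated (coverage ~0.93 in the recovery experiment), but posterior-mean
*signs* of borderline coefficients (|beta| just above 0.5) are unstable,
plateauing near 90% agreement regardless of chain length.

## Numerical choices

* Species order is lexicographic everywhere; matrix assembly is
  deterministic and permutation of input rows cannot change results.
* `W(rho)` is handled in the eigenbasis of C; grid points where the
  smallest eigenvalue of W drops below 1e-12 get zero posterior mass
  (relevant only for singular C at rho = 1).
* The positive-definiteness tolerance for accepting a correlation matrix
  is an eigenvalue floor of -1e-10.
* Expected-count prediction raises (with the draw index) if the log rate
  exceeds 700, the double-precision overflow edge — a guard against
  divergent chains, not a model feature.
* Non-finite parameters abort the sampler with the iteration index.

## Known limitations

* Single-chain MCMC per fit; convergence diagnostics beyond the logged
  trace summaries (rho, loading norms per 100 sweeps) are the user's
  responsibility at real-data scale.
* No model comparison (WAIC/cross-validation) and no spatially explicit
  random effects; site non-independence is handled only through the
  latent factors.
* The coefficient block update is a dense pS x pS solve; fine for
  p = 9, S = 50, but quadratic-memory in S beyond a few hundred species.
* GIS processing of cover, seasonal covariates and map/figure rendering
  are out of scope; covariates are taken as given inputs.
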