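# Methods

`clonegxe` analyses clonally replicated common-garden trials planted at
several sites: the same genotypes (clones), copied as ramets, grown in
replicate/incomplete-block layouts across environments.  Its goal is the
quantitative-genetic decomposition of a productivity trait — how much
phenotypic variance is genetic, whether genetic merit is stable across
environments (GxE), and how productivity responds to climate at the
seed origin and at the planting site.

## The multi-environment mixed model

The observation of one ramet is modelled as

    y = beta_i + p_(q,i) + g_(c,i) + r_(r,i) + b_(b,i) + e

for population (cluster) q, genotype c, replicate r, block b at site i.
Environment is treated as a dimension of a multivariate response:

* population effects `p_q = (p_q1, ..., p_qn)` across the n sites are
  multivariate normal with unstructured covariance **G1**;
* genotype-within-population effects likewise with unstructured **G2**;
* replicate, block-within-replicate and residual terms have independent
  per-site variances.

The diagonal (per-site) structure of the design and residual terms is a
modelling decision forced by the design: no ramet is grown at two sites,
so cross-site covariances of these terms are unidentifiable and are
fixed at zero.  Only G1 and G2 — whose levels (populations, genotypes)
do span sites — are unstructured.

Phenotypes are z-scored **within site** before fitting.  Per-site
intercepts would absorb site means either way; within-site scaling makes
variance components comparable across sites (components per site sum to
roughly one) and puts binary traits (e.g. sprout occurrence, analysed on
the observed 0/1 scale after standardization rather than through a
threshold link) on the same footing as continuous ones.

### Gibbs sampler

All full conditionals are conjugate:

1. every location effect (site intercepts and all random-effect vectors)
   is drawn **jointly** from its conditional multivariate normal given
   the current covariances (mixed-model equations with per-site residual
   weights, dense Cholesky);
2. two translation-group sweep moves resample the likelihood-invariant
   directions — the offset between intercepts and population effects,
   and the offset between each population's effect and its genotypes'
   effects.  These are exact generalized-Gibbs moves (translation group,
   unit Jacobian); without them the confounded population/genotype
   partition mixes by a slow random walk;
3. G1 and G2 are drawn from inverse-Wishart conditionals with scale
   `S0 + E'E` (E the current effect matrix) and degrees of freedom
   `df0 + n_levels`;
4. each scalar variance is drawn from its inverse-gamma conditional.

Numerical safeguards: a failed Cholesky of the conditional precision is
retried with escalating diagonal jitter (logged) before erroring; every
retained G1/G2 draw is positive definite by construction of the
inverse-Wishart sampler and can be audited with
`PosteriorChains.check_psd()`.

The implementation was validated against an independent MCMC engine
(JAGS via rjags) on matched small problems: with identical priors the
posterior means and quantiles of all variance components, correlations
and residual variances agree to within Monte-Carlo error.

### Priors

The paper trail for this class of analysis rarely states priors, so they
are an explicit design choice here, all configurable via `ModelSpec`:

* **G1, G2** — inverse-Wishart with scale `I * s` and df `n_env + 1`.
  This df makes the implied prior on every cross-site *correlation*
  uniform on (-1, 1).  The scale parameter `s` acts like `df0`
  pseudo-observations of variance `s`: large `s` measurably shrinks
  weakly identified cross-site correlations toward zero (with ~25
  population levels, `s = 1` caps a generating correlation of 0.99 near
  0.89), while very small `s` concentrates prior mass at zero variance
  and can trap weakly identified components there.  The default
  `s = 0.1` is small relative to unit phenotypic variance but away from
  the zero spike; sensitivity to `s` should be checked whenever a term
  has few levels.
* **scalar variances** — inverse-gamma(0.001, 0.001).
* **intercepts** — flat.

Chain defaults are 500 000 iterations, 50 000 burn-in, thinning 10; the
test-suite and acceptance runs use scaled-down chains (20 000/2 000)
with correspondingly wider Monte-Carlo wobble, which is why recovery
tests compare against realized sample moments (below).

### Reported quantities

Per site, broad-sense heritabilities

    H2_pop = s2_pop / (s2_pop + s2_gen + s2_e)
    H2_gen = s2_gen / (s2_pop + s2_gen + s2_e)

whose denominator deliberately **excludes** replicate and block
variances (design variance is treated as removable noise; definitions
that include it give smaller values — mind this when comparing across
studies).  Per site pair and level, the genetic correlation
`r = cov_ij / sqrt(s2_i s2_j)`.  Every ratio is evaluated per MCMC
sample and summarised by the posterior mode of the *ratio chain* —
never the ratio of modes, which differs for skewed posteriors — using a
Gaussian KDE (Silverman bandwidth, 512-point grid).  Intervals are
shortest-window HPD by default with equal-tail quantile intervals
offered alongside; the two differ for skewed variance components.
A correlation whose interval stays above 0.7 is treated as "no
practically important GxE" (a common rule of thumb); `important_gxe` is
flagged when the upper limit is below 0.7.  When a site has essentially
no genetic variance the correlation is reported as undefined (NaN) with
a diagnostic, not as a number.

## Synthetic data

The generator is first-class, tested code: it emulates exactly the
structure the model assumes (hierarchical effects with per-site
variances, cross-site population/genotype correlations, incomplete
blocks, each ramet at exactly one site) and exposes the drawn effects so
tests can compare estimates against **realized** sample moments.  With
~25 effect levels the realized variance of a draw differs from its
generating value by ~30% (1 SD), so single-realization recovery is
judged against the realized moments; the generating values are the
long-run target.

Default study conditions mirror a range-wide conifer collection trialled
in a temperate maritime country: 4–6 sites, ~85 origin locations with
1–6 genotypes each on a latitudinal climate gradient whose defaults
induce corr(lat, tmax) ≈ −0.93, corr(lat, precip) ≈ +0.59 and hence the
moderate corr(tmax, precip) ≈ −0.55 that makes (tmax, precipitation)
the only admissible response-surface pair; variance components near
population 0.41, genotype 0.35, residual 0.65 with cross-site
correlations 0.99 (population) and 0.75 (genotype).  Site intercepts
default to distinct values per site so within-site standardization is
actually exercised.  Binary traits are latent-Gaussian thresholded at a
configurable incidence (default 0.3).

All randomness flows from one integer seed through per-component hashed
streams, and cross-site mixing uses the (nested) Cholesky factor, so
adding a site or a trait leaves existing draws bit-identical.

What the generator does **not** emulate — spatial autocorrelation within
sites, competition between neighbours, age/propagation-history
confounding, non-Gaussian residuals — bounds what passing tests show:
they demonstrate correctness of the estimation machinery under the
model's own assumptions, not robustness to field realities outside them.

## Clustering of origins

Locations (not genotypes — 1–6 genotypes share a location) are grouped
by partitioning around medoids on z-scored geography + climate features;
Euclidean distance on z-scores is the only defensible way to mix
degrees, kilometres, metres, °C and millimetres.  PAM is the classic
BUILD + greedy best-improvement SWAP with deterministic tie-breaks; for
small instances (≤ 50 000 candidate medoid sets) the result is refined
by exhaustive enumeration, since BUILD+SWAP alone can end in a
single-swap local optimum (the reference R implementation exhibits the
identical behaviour on the same instance).  The number of clusters is
chosen by average silhouette width (singletons score 0), ranked over a
candidate range with ties broken toward smaller k.

## Rank-change diagnostics

Genotypes are ranked within each environment on posterior-mean genotype
effects (shrinkage-consistent with the model; a raw clone-mean mode is
available), ties broken by identifier so each environment's ranks are a
permutation.  The average clonal rank is the arithmetic mean over
environments where the genotype occurs; the boxplot statistic per
genotype is the multiset of pairwise absolute rank changes between
environments, which is invariant under any strictly monotone transform
of the effects.

## Universal response function

Performance `Y_ij` of cluster i at site j is regressed on

    X1, X1^2, X2, X2^2, X1*X2     (per climate variable)

with X1 the origin climate (transfer part) and X2 the site climate
(response part); no cross-variable products.  The default response is
the back-transformed posterior mean of site intercept + cluster effect
(mm for a diameter trait); a raw cluster-by-site mean is selectable.
Cluster-level origin climate is the mean over member locations.

Predictors are z-scored before the polynomial expansion (raw-unit
squares and products are numerically wild and their coefficients
unreadable); the scaling record travels with the fit so grid prediction
applies the identical transform.  The design rank is checked up front:
with only four distinct site climates the four site-level polynomial
terms plus intercept are not identifiable, and the error names the
dependent columns — this is the characteristic failure mode of response
surfaces over few sites, and the reason synthetic response-surface runs
here use six or more sites.  Fitting is plain OLS via the normal
equations with an explicit singularity error (never a silent
pseudo-inverse); per-term R² is the marginal squared correlation of the
term with Y (the per-term values of such tables sum to more than one,
ruling out an additive partition).  Grid predictions are never clipped;
cells whose climate leaves the training min–max box per variable are
flagged extrapolated.

## Pipeline

`run_pipeline` sequences the stages (simulate/load → cluster → fit →
summarize → ranks → response surface) under one seed, writes plain
CSV/JSON artifacts, and records a manifest with input checksums and
per-stage signatures so unchanged stages are reused on rerun.  The
clustering scenario used downstream is configurable (best k, second-best
k, or a fixed k); the fine-grained scenario is the informative one for
transfer-function work because it provides many origin-climate levels.

## Known limitations

* The population/genotype variance partition is weakly identified when
  populations contain very few genotypes; with ~2 genotypes per
  population the (correct) marginal posterior modes can sit far from
  the generating values even though posterior means remain calibrated.
  This is a property of the posterior, verified against an independent
  sampler, not of the implementation.
* KDE posterior modes from short thinned chains are noisy; production
  inference should use the full-length defaults.
* Silhouette-based k-selection on smooth gradients (no true clusters)
  ranks all k low and nearly equal; the ranking is then not meaningful.
* The URF is an empirical regression: predictions outside the training
  climate box are reported but untrustworthy, and with few sites the
  site-level polynomial is at the edge of identifiability.
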