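# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and what the validation studies do and do not show.

## 1. Phenology measure

The flight period of one species at one site in one year is summarised by
the count-weighted mean day of adult counts,
`sum(count_d * d) / sum(count_d)`, over visits inside the species'
generation window.  Days are integers from the start of the recording
season (day 1 = 1 April; the standard season is days 1–182, 26 weekly
visits).  Zero-count visits carry zero weight but are counted as visits.
A site-year with no positive count yields no record (a NaN sentinel at the
scalar level), so batch processing never aborts.

For multivoltine species only a single generation should enter the
analysis; per-species generation windows (e.g. days 1–95 for a spring
brood) restrict the measure accordingly.  Records are then filtered by a
sufficiency rule — at least `min_positive_visits` (default 3) positive
visits spanning at least `min_span_days` (default 7) days — an explicit,
logged stand-in for scheme-specific annual-index sufficiency criteria.
The defaults are deliberately mild; both are knobs in the pipeline config.

## 2. Climate windows

Monthly grid-cell temperatures are smoothed into three-month running means
labelled by centre month; January windows borrow the previous December and
December windows the following January, so analysing years Y₀…Y₁ requires
temperatures for Y₀−1…Y₁+1.  Sites link to cells by floor division of
their projected coordinates (half-open cells, 5-km default).

Window selection regresses the national annual mean flight date
(unweighted over sites with a record that year) on the national annual
mean window temperature (unweighted over those sites' cells) for each of
the twelve windows and keeps the window with the largest |t| (or largest
absolute coefficient under the alternative criterion).  Ties break toward
the earlier centre month; windows with fewer than three usable years or
zero temperature variance are reported with NaN diagnostics rather than a
pseudo-value.  Unweighted national averaging is an assumption — the
alternative (abundance weighting) is not implemented.

## 3. Bivariate slope decomposition

For each species, the unit of analysis is the site-year pair
z = (window temperature, mean flight date).  The model is

    z_i = mu + u_pop(i) + v_year(i) + e_i,
    u ~ N(0, Sigma_pop),  v ~ N(0, Sigma_year),  e ~ N(0, Sigma_res),

with crossed population and year intercepts (the year effect is shared
across the whole landscape, not nested in population) and intercept-only
fixed effects.  Populations are sites aggregated on a 50-km grid by
default; 0 m (site-level) and 100-km are the standard sensitivity scales.
Temperatures enter per site-year; the population structure acts only
through the random-effect grouping.

Slopes are covariance ratios per retained draw:
b_time = Sigma_year[t,p]/Sigma_year[t,t],
b_space = Sigma_pop[t,p]/Sigma_pop[t,t], delta_b = b_space − b_time
(draw-wise, so the identity is exact).  The sign convention is fixed by
the among-minus-within ordering: with negative slopes, delta_b > 0 means
the spatial slope is shallower than the temporal one (countergradient
local adaptation).

**Sampling.** A Gibbs sampler with conjugate updates: flat prior on mu;
multivariate-normal full conditionals for the random-effect vectors
(grouped by level size, so balanced designs update in one vectorised
draw); inverse-Wishart full conditionals for each covariance matrix.  The
prior on every component is IW(nu·V, nu) with V = I₂ and nu = 0.002 — the
weakly-informative convention in which "V = 1, nu = 0.002" is understood.
Defaults are 13 000 iterations, 3 000 burn-in, thinning 10 (1 000 retained
draws), single chain.  Thinning is a package choice (the convention the
run lengths imply); multi-chain running is just repeated calls with
different seeds.  The 2×2 inverse-Wishart draws use a hand-rolled Bartlett
decomposition (cross-checked against scipy's distribution in the tests)
because the sampler draws ~40 000 of them per fit and per-call overhead
dominates otherwise.

Degenerate inputs (constant temperature column, a term with fewer than two
levels) are rejected before sampling; numerically non-positive-definite
scale matrices are jittered with a logged warning (not observed in
practice).

## 4. Posterior summaries and the decision rule

Point estimates are posterior modes: the argmax of a Gaussian KDE over the
draws, evaluated on a 512-point grid, with bandwidth equal to Silverman's
rule times 2.  The doubling is a deliberate variance/bias trade: the plain
Silverman argmax has Monte-Carlo SD ≈ 0.08 on a unit-variance posterior
with 10⁴ draws, the doubled bandwidth ≈ 0.03, at the cost of a small
smoothing bias that is negligible for the near-symmetric slope posteriors
(it matters only for strongly skewed shapes, where the mode is a poor
summary anyway).  Intervals are 95% HPDs computed exactly on the sorted
draws (shortest window of ⌈0.95 n⌉ order statistics; verified against an
exhaustive search).  The local-adaptation null is rejected iff the delta_b
HPD excludes zero, boundaries counting as spanning; direction labels
(countergradient / co-gradient) come from the sign of the delta_b mode.

## 5. Phylogenetic meta-analysis

Species-level estimates y_i (of b_time or delta_b) with fixed
measurement-error variances m_i (the posterior variance of that species'
estimate) follow

    y_i = mu + beta' x_i + a_i + e_i + m_i,
    a ~ N(0, sigma_a2 * A),  e ~ N(0, sigma_e2 * I),  m ~ N(0, diag(m_i)),

where A is the Brownian correlation matrix of a rooted tree: shared
root-to-tip path length of each tip pair divided by tree depth (per-tip
geometric-mean normalisation when the tree is not ultrametric, with a
warning).  The measurement-error matrix is diagonal — the standard
formulation.  Phylogenetic heritability H² = sigma_a2/(sigma_a2+sigma_e2)
is computed per draw, so H² ∈ [0, 1] draw-wise by construction.

**Sampling.** A partially collapsed Gibbs sampler: (mu, beta) and the
a-vector are updated with e + m integrated out (per-species residual
variance sigma_e2 + m_i, well defined when some m_i = 0); e is then
re-imputed from its exact conditional, and the variances drawn from scaled
inverse-chi-square full conditionals (same IW(nu·V, nu) prior family,
nu = 0.002, V = 1).  Because sigma_a2 and the scale of a mix slowly under
plain Gibbs (the hierarchical funnel), the sigma_a2 update is followed by
an ancillarity–sufficiency interweaving move: the effect vector is
whitened, the signed scale s (a = s·ã) is proposed from its Gaussian
likelihood conditional, and accepted against the prior ratio.  The move
leaves the posterior invariant and raises the effective sample size of H²
about six-fold; correctness is verified against an exact 2-D quadrature
posterior (fixed effects integrated analytically; feasible because
constant m_i makes the marginal covariance diagonal in A's eigenbasis),
with Gibbs and quadrature posterior means agreeing to three decimals.
Near-singular A (tips that diverged very recently) is inverted through an
eigenvalue floor at 10⁻⁸ of the largest eigenvalue, with a warning.
Defaults for this stage: 6 000 iterations, 1 000 burn-in, thinning 5.

**Tree pooling.** Phylogeny uncertainty enters by splitting a total
iteration budget evenly over a sample of trees and concatenating the
retained draws; a single tree reproduces the direct fit exactly, and trees
missing any estimate species are skipped with a warning.  Trait
predictors enter as fixed effects, one trait per run by default
(treatment contrasts against the first category in sorted vocabulary
order for categorical traits), with listwise deletion of species with
missing trait values.

## 6. Synthetic-data generator

The generator defines the package's study conditions; everything
downstream is validated against its known truth.

*Landscape and temperatures.* Sites are uniform over a 1 000-km square
(emulating a national monitoring network); monthly cell temperatures are

    base (9 °C) + seasonal cycle (amplitude 6 °C, June/July peak)
    + gradient · northing (−6 °C per 1000 km, so ~6 °C spatial range)
    + year anomaly (SD 0.7 °C) + month noise (SD 1.2 °C),

with both stochastic terms shared across cells.  Spatially coherent
anomalies are the realistic regime at this scale, and they are what makes
the twelve candidate windows distinguishable nationally: with independent
per-cell noise the national window series would be collinear up to
vanishing noise.  The combined interannual SD of a three-month window is
~1 °C.  The spatial dimension of the field is therefore the static
gradient; there is no site-level temperature noise.

*Counts.* The latent mean flight date of site s in year y is

    mu_sy = mu0 + b_time (T_sy − T̄_s) + (b_time + delta_b)(T̄_s − T̄)
            + u_pop + v_year + e_sy,

with T the cue-window temperature, and u, v, e zero-mean Gaussian (year
effects shared landscape-wide, mirroring the fitted model).  Counts at
each scheduled visit are Poisson with mean proportional to a Gaussian
flight curve (SD `flight_sd`) around mu_sy, normalised so the expected
seasonal total over the schedule equals `site_abundance_mean`; a
negative-binomial option with a dispersion knob is available, since real
transect counts are overdispersed.  The default visit schedule is the 26
weekly visits (days 1, 8, …, 176); oracle tests use daily schedules.  The
site-to-population truth, per-site mean temperatures and latent dates are
returned alongside the counts.

*Phylogenetic estimates.* Species values follow the meta-model exactly:
a ~ N(0, sigma_a2·A), traits by Brownian motion on the same tree,
residuals and measurement errors independent.  The standard study tree is
a 31-tip pure-birth tree with a fixed seed; the tree is a study condition,
not a replicate.

*What the generator does not emulate:* weather-dependent recording rules
and observer effort, site-level temperature deviations from the gradient,
overdispersion (by default), multi-generation flight curves (except via
explicit two-brood constructions in tests), and non-Gaussian flight
curves.  Passing recovery tests therefore demonstrates correctness of the
estimators under the model's assumptions, not robustness to every
violation real data can present.

## 7. Validation studies and problem sizes

The standard studies (in `phenodecomp.studies`, shared by the test suite
and `scripts/acceptance.py`):

- **Headline decomposition** — 40 site-level populations × 30 years,
  b_time = −6.4, delta_b = +2.4, date SDs (population 3, year 2, residual
  5 days), full 13 000-iteration fits; 20 replicates for HPD coverage and
  mode bias.
- **Window selection** — 25 sites × 30 years, March cue, low date noise;
  20 replicates.  A noise-free construction checks strict |t| dominance of
  the true window.
- **Heritability** — 31-tip study tree, sigma_a2 = 3, sigma_e2 = 1
  (H² = 0.75), m_i = 0.05; 20 replicates.  Note: with n = 31 and the
  spike-at-zero nu = 0.002 priors, even the *exact* posterior's 95% HPD
  covers a fixed true H² of 0.75 in only ~85–90% of replicates (checked by
  quadrature), and coverage varies with the tree's eigenstructure — an
  identifiability property of the model at this sample size, not a sampler
  artefact.
- **Cross-scale stability** — 60 sites × 15 years, ten species with
  delta_b from −3 to +8, decomposed at site-level, 50-km and 100-km
  aggregation with 4 000-iteration fits; rank correlations of delta_b
  across scales.  The reduced fit length is adequate because only the
  delta_b mode ordering is compared.

The balanced univariate sampler check (50 groups × 20 observations)
compares Gibbs posterior means against an exact 2-D quadrature posterior
within Monte-Carlo error, and documents that both sit within the known
O(1/m) skew gap of the REML point estimates: the posterior *mean* of a
between-group variance under a weak prior exceeds REML by a factor of
roughly (m−1)/(m−3), so point identity with REML at MCMC precision is not
the correct expectation for any exact sampler.

## 8. Known limitations

- Single-chain defaults; split-R̂ diagnostics are a matter of running
  multiple seeds, not built in.
- No site level below population in the bivariate model; spatial
  autocorrelation enters only through the population grouping.
- The sufficiency filter is a pragmatic stand-in, not a reimplementation
  of any scheme's annual-index criterion.
- Modal point estimates inherit a small smoothing bias from the widened
  KDE bandwidth (Section 4); means and HPDs are unaffected.
- H² is weakly identified at n ≈ 31 species; its posteriors (and pooled
  versions over discordant trees) are honest about this by being wide.
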