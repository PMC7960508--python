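# Methods

This note documents the statistical machinery in `citymort`: the models,
the conventions they rely on, the choices made where the design was
genuinely open, and what the synthetic test bed does and does not show
about real data.

## Age grid and data model

All mortality quantities live on the standard 17-group abridged grid
(0, 1–4, 5–9, …, 70–74, 75+). The death-distribution methods operate on
the coarser 16-group grid with 0–4 collapsed. Deaths tables are long
count tables keyed by (country, city, year, sex, age group, cause
group); populations are enumerated at the two endpoints of a five-year
window. Person-years of exposure per cell default to T·√(N1·N2) (the
exact mid-period population under exponential growth); an arithmetic
T·(N1+N2)/2 variant is available because sources differ on this
convention and the Bayesian module can be exercised under either.

## Preprocessing

Missing sex is imputed per record batch by one binomial draw with p =
observed proportion male in the same (5-year age, cause group, country,
year) stratum; missing age by one multinomial draw over the 17 groups
from the (sex, cause, country, year) stratum. Rows missing both are
sex-imputed first from age-marginal strata. Ill-defined disease deaths
are redistributed over {CMNN, cancer, CVD/NCD} and ill-defined injury
deaths over {unintentional, violent} with the stratum's observed cause
distribution; the disease/injury boundary is never crossed.

Strata with no observed deaths fall back along a fixed ladder — drop
the year, then the age dimension, then country totals — and
redistribution ends with an equal within-family split (with a warning)
if a family has no observed deaths anywhere. The ladder is a
terminating convention, not a statistical claim. Every operation
conserves the integer death total exactly; a deterministic
`mode="expect"` allocates expected fractional counts for testing.
ICD-10 codes are mapped to the five cause groups by longest-prefix
match against an editable table; the bundled default is chapter-level.

## Registration completeness

Three death-distribution methods per city and sex, each over three age
bands (automatic best-fitting, 30–65, 50–70):

* **GGB** fits b(a+) − r(a+) = δ + (1/c)·d(a+) by orthogonal (total
  least squares) regression over open age intervals; completeness is
  the reciprocal slope and δ estimates the relative coverage drift of
  the two censuses (ln(k1/k2)/T).
* **SEG** reconstructs the annual flow of persons attaining each exact
  age from registered deaths above that age carried backward at
  group-specific growth rates; completeness is the median ratio of
  reconstructed to enumerated flows over the band.
* **hybrid** reconciles the censuses with the GGB δ (second census
  scaled by exp(δT)) and then applies SEG.

Numerical conventions that matter:

* Exact-age entry flows are estimated from grouped counts with the
  cubic four-group boundary formula (−g₋₂ + 7g₋₁ + 7g₀ − g₊₁)/60
  (two-group fallback (g₋₁+g₀)/10 at grid edges). The two-group average
  systematically overestimates a convex decaying density at the
  boundary; on assumption-satisfying fixtures the cubic form cuts the
  GGB bias from ~1% to ~0.3–0.6%.
* The 75+ interval is not a 5-year group; for the flow at exact age 75
  its effective 75–79 population is taken as N(75+)·(1 − e^(−5/ê75)).
* The SEG open-interval seed is N̂(75) = D(75+)·(1 + r·ê75). This is
  the exact growth-discount factor E[e^(−rT)]⁻¹ when remaining lifetime
  above 75 is exponential with mean ê75 — the same constant-hazard tail
  convention the life-table module uses (L = l/m, e = 1/m). The common
  series form e^(r·ê75)(1 − (r·ê75)²/6) assumes death ages concentrated
  near ê75 (variance ê75²/3) and overshoots a dispersed tail by
  (r·ê75)²/3, a 3–4% completeness bias at r = 0.02. The two agree to
  first order in r·ê75.
* ê75 comes from the bundled standard schedule (the package's default
  Siler schedules), sex-specific, and can be overridden. Under zero
  growth the seed does not depend on it at all; sensitivity grows as
  exp(r·Δê75).
* The automatic band minimizes the orthogonal-fit RMSE over contiguous
  bands with lower end 5–35, upper end 50–75 and width ≥ 30 years, with
  deterministic tie-breaks (widest, then lowest start). It is a
  reconstruction of "best-fitting band" behaviour, not a claim of exact
  equivalence with any particular implementation.

The nine estimates are clamped to (0.3, 1.0] (values above 1 are
over-registration artifacts and set to 1), harmonically averaged into
φ, and their sample variance about φ (denominator 8) gives s². The
prior is Beta(Kφ, K(1−φ)) with K = φ(1−φ)/s² − 1, which has mean φ and
variance s² exactly. Degenerate cases: s² is floored at 10⁻⁶ when the
estimates coincide; K ≤ 0 (possible when s² ≥ φ(1−φ)) is clamped to
K = 1 with a warning, keeping a proper but weak prior; fewer than two
valid estimates is an error.

## Bayesian mortality model

y ~ Poisson(c·n·λ) with log λ = β0_ks + α_is + z_ijks, AR(1) city
deviations across age, and c ~ Beta(Kφ, K(1−φ)) per city and sex.
Sexes are modelled independently. Hyperpriors are weakly informative:
β0 ~ N(0, 10²), τ ~ half-N(0,1), σ_k ~ half-N(0,1) independently per
age group, ρ ~ U(0,1) (mortality schedules are smooth, so only
positive age-correlation is entertained). The country effect α is one
value per (country, sex); a country containing a single city is shrunk
toward zero like any other.

The sampler is adaptive Metropolis-within-Gibbs: vectorized random-walk
updates for β0 (per age), α (per country), z (odd/even age interleave,
vectorized over cities), logit-scale updates for c, log-scale updates
for τ and σ_k, and a conjugate truncated-normal Gibbs draw for ρ.
Because the likelihood only identifies sums like β0 + α + z and the
product c·λ, four likelihood-invariant "swap" moves travel along the
flat directions (β0↔z, α↔z, overall level β0↔α, and log c↔z with c·λ
preserved); without them the intercept block mixes an order of
magnitude more slowly. Proposal scales adapt toward 44% acceptance
during burn-in only, so the retained chain has a fixed kernel.

The default schedule is 50,000 burn-in, 100,000 iterations, thin 100
(1,000 retained draws). Tests and the acceptance checks run scaled-down
schedules (2,000/4,000/thin 4 for calibration; 4,000/12,000/thin 12 for
the end-to-end check, whose 2.5% tail quantiles need the extra
effective draws). Convergence is monitored with split-R̂ and effective
sample size on the β0 block and a systematic sample of λ cells; more
than 5% of monitored parameters above R̂ = 1.1 raises a warning, never a
silent success. Cities are sorted canonically by (country, city) before
sampling, so results are invariant to input row order; draws are
reproducible given the seed.

Posterior draws are stored in a self-describing netCDF container with
named dimensions (draw, city, age, sex, country).

## Life tables

q = n·m/(1 + (n − a)·m) with a₀ from the sex-specific Andreev–Kingkade
piecewise-linear formulas in m₀, a(1–4) = 1.5 years, a = n/2 for 5-year
groups; the open interval takes q = 1, L = l/m, e = 1/m. Radix 100,000.
The q↔m conversion is exactly self-consistent: the implied central rate
d/L reproduces the input m in closed groups to machine precision, which
is the main internal check. Life expectancies are reported at ages 0,
20, 40, 60. Per city and sex, the 1,000 posterior rate draws give 1,000
life expectancies; the r.s.e. is their standard deviation divided by
the median (the only dispersion available per city), and an estimate is
flagged reliable when r.s.e. < 25%. The open interval starts at 75
(17 groups); with rates near zero elsewhere this convention forces
e0 = 75 + 1/m(75+), the fixture used in the tests.

## Profiles and predictors

PM is deaths in a cause group over total deaths, sexes combined by
default (a stratified option exists); AAPM replaces counts with
age-adjusted cause-specific rates, standardized to the WHO 2000–2025
world standard population collapsed to the 17-group grid (the published
0–4 share is split 1/5 : 4/5 between ages 0 and 1–4; groups above 75
are pooled). Both vectors sum to 1 per city; zero-death cities are
emitted as missing. Coverage corrections are two distinct modes, never
mixed: descriptive analyses divide deaths by c, count models multiply
population by c (identical crude rates, different precision
implications). The social environment index is the sum of z-scores of
education, water and sewage access minus the z-score of overcrowding.
Predictors are centered and scaled by their overall s.d. except
population, which is log-transformed (a helper converts the
log-coefficient into the effect of a 50% larger city, β·ln 1.5). City
growth is (P2/P1 − 1)·100 over the five-year window, with an alternate
earlier window for the growth-timing sensitivity analysis.

## Multilevel inference

The three-level decomposition of life-expectancy draws (draws within
cities within countries) is estimated by method-of-moments nested
ANOVA: pooled within-city draw variance, within-country variance of
city means minus its sampling part, between-country variance of country
means minus both. Components are clamped at zero and shares of the
total are reported. City-population weights enter at the draw level
(weighted pooling of within-city variances and weighted means), the
package's reading of population-weighting for this model. A
restricted-likelihood fit of the same model is the independent
cross-check in the tests. With a single country the country component
is zero and flagged. Note that a *share* is a ratio: with few countries
its numerator has k−1 degrees of freedom and the per-replicate share is
noticeably Jensen-biased even when the components are unbiased, so
recovery is judged on components averaged over replicates.

Two-level ICCs for profiles use the one-way ANOVA estimator with the
unbalanced-design n₀ correction, clamped to [0, 1].

Draw-wise associations fit a random-intercept (country) linear model of
life expectancy on scaled predictors once per posterior draw and pool
with Rubin's rules: Q̄ = mean estimate, W̄ = mean within-fit variance,
B = between-draw variance, T = W̄ + (1 + 1/m)B, normal 95% CI. No
p-values are reported. The default per-draw fit is a closed-form
moments + GLS estimator (residual one-way ANOVA for the variance
components, Woodbury-inverted GLS for coefficients): it is always
defined, has no optimizer, and agrees with REML on well-behaved panels
(cross-checked in tests); a REML backend is available, where
non-converged draws are skipped and more than 5% skipped is an error.
The cause-specific association model is supported through its
data-reshaping contract only (cause indicators against a CVD/NCD
reference, exposure interactions, log of coverage-weighted population
as offset); the negative-binomial mixed fit itself is delegated to
standard software.

## Synthetic data: what it emulates and what it does not

The generator draws multi-country city panels: Siler hazards
m(x) = a·e^(−bx) + c + d·e^(ex) evaluated at group midpoints (defaults
give e0 ≈ 83 for females and ≈ 74 for males at level 1, inside the
60–85 design range; country and city lognormal level multipliers and a
smooth age tilt create realistic heterogeneity), stable populations
obtained by fine-grid integration of the piecewise-constant hazard so
that group deaths equal rate × person-years *exactly* — this is what
makes the death-distribution balance identities hold by construction —
Poisson deaths over a five-year window, binomial under-registration
with coverage ~ U(0.6, 1.0) per sex, an age-specific five-group cause
mix, 3% ill-defined miscoding, 0.5% missing age and 0.2% missing sex.
Defaults mirror the scale of Latin-American city panels (populations of
order 10⁵–10⁶, growth 0.5–2.5%/year). One RNG stream per city (keyed by
position, derived from the master seed) means adding cities never
perturbs existing ones.

Passing tests on this bed show the chain is *internally correct*:
estimators recover known parameters when their assumptions hold, and
degrade in the documented direction (an age-selective migration option
exists precisely to violate the DDM assumptions on demand). They do not
show robustness to what real registries add: migration flows, census
coverage errors correlated with age, cause-coding practices that vary
by hospital, digit preference, or non-stable age structures. The
cohort-projection and migration options in the generator are the hooks
for studying those failure modes; results on defaults should be read as
upper bounds on real-data performance.

## Problem sizes and schedules

The standard small panel used in examples and acceptance checks is 2
countries × 5 cities × 2 sexes × 17 age groups (~340 rate cells), with
the scaled-down MCMC schedules above; a full run at the default
schedule on such a panel takes a few minutes on one CPU. The
completeness recovery check uses 30 independent cities; the
variance-decomposition check uses 9 countries × 40 cities × 100 draws,
averaged over 20–30 replicates for the degrees-of-freedom reason given
above.
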