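# Methods

`iodintake` estimates the habitual (long-run average) total iodine intake
distribution of a population from a survey with two non-consecutive 24-h
dietary recalls per subject, and evaluates adequacy and safety against
dietary reference intakes. Total iodine intake is decomposed into four
sources handled by separate sub-models before being recombined:

(a) iodine naturally present in foods (excluding iodised salt and
supplements), (b) iodised salt added by food manufacturers, (c) iodised
salt added discretionarily during meal preparation or at the table, and
(d) dietary supplements.

## Daily intake tabulation

Daily intakes are computed per subject per recall day with fixed unit
conventions: food amounts in g, composition per 100 g food, salt iodine
concentrations in mg I per kg salt, intakes in µg/d. The bridging identity
`g salt × (mg/kg) = µg iodine` is exact and tested.

* Natural: Σ amount × C_food/100 over foods, excluding foods assigned to a
  manufacturer iodised-salt category (bread etc.), whose iodine is counted
  in source (b).
* Manufacturer salt: Σ amount × Z_food/100 × salt_fraction × C_z over the
  foods whose (subject, food group) pair is assigned the iodised variant.
  `salt_fraction` handles composite foods — for pizza only half of the
  salt is attributed to added iodised salt.
* Discretionary salt: Σ amount × added_amount/100 × C_z over eligible food
  groups the subject is assigned to salt. Foods produced with salt are
  never eligible. The amount of salt added per 100 g food is configuration
  (cookbook-recipe scale, ~0.5–1 g/100 g by default).
* Supplements: the reported supplemental iodine per recall day.

## Probabilistic salt-use assignment

Who actually uses iodised salt is not observed, so it is assigned by
Monte Carlo and the assignment repeated (default 100 iterations):

* Discretionary user status: subjects with a salt-questionnaire answer
  keep it deterministically. Within each (age band, sex) stratum of the
  remaining subjects, a fraction equal to the configured never-user
  proportion is drawn without replacement and set to never-user.
* Food-group use: per manufacturer group, a fraction of its consumers
  equal to the market share is assigned the iodised variant; per
  discretionary-eligible group, a configured fraction of the salt-adding
  consumers is assigned to salt that group. Assignment is at the subject
  level: all of a subject's products in a group are iodised or none are.

Sampling is exact-fraction — permute the candidates and take
`round-half-even(p·n)` — rather than independent Bernoulli draws, so the
assigned count matches the configured proportion exactly per iteration and
ensemble spread reflects *who* is assigned, not binomial noise in *how
many*. Deterministic products (always/never iodised) are simply market
shares of 1 or 0. Each iteration's generator is seeded from
`SeedSequence((root_seed, iteration, stream))`, making iterations
independent and individually reproducible.

Both discretionary status and food-group use are re-drawn in every
iteration, so the ensemble spread covers both assignment layers jointly.

## Habitual intake model

Each source's habitual distribution is estimated with a measurement-error
model on a Box-Cox transformed scale:

y_ij = f(age_i) + b_i + e_ij,  b_i ~ N(0, σ²_b),  e_ij ~ N(0, σ²_w)

* Transformation: the power λ is profiled over the Tukey ladder
  {0, 1/4, 1/3, 1/2, 2/3, 1} by the pooled Box-Cox log-likelihood, or
  fixed by the user. Restricting to the ladder keeps the transformed scale
  interpretable and the variance components commensurable across refits;
  λ=0 is the plain natural log and λ=1 the plain identity (the
  conventional affine shift is dropped — it only moves the intercept).
  Incidental zero days are shifted by half the minimum positive value
  (with a warning) before transformation; structural zeros belong in the
  two-part model instead.
* Age trend: f is a cubic B-spline with 3 interior knots at age quantiles
  (configurable), fitted separately by sex by survey-weighted least
  squares on the subject means. Degenerate designs (few distinct ages)
  fall back to lower-degree bases down to an intercept.
* Variance components: with the balanced 2-day design,
  σ̂²_w = Σ wᵢ(y_i1 − y_i2)² / (2 Σ wᵢ) from paired day differences and
  σ̂²_b = Var_w(ȳᵢ − f̂(ageᵢ)) − σ̂²_w/2, clipped at zero with a warning.
  These are the ANOVA estimators, which coincide with REML in this
  balanced design (cross-checked against a linear mixed model in the test
  suite) while supporting survey weights. Season/day-of-week effects are
  handled through the survey weights rather than modelled.
* Person effects and shrinkage: the BLUP
  b̂ᵢ = k (ȳᵢ − f̂(ageᵢ)), k = σ̂²_b/(σ̂²_b + σ̂²_w/nᵢ), is rescaled so the
  weighted variance of the person effects equals σ̂²_b. The raw BLUP
  distribution is too narrow by the factor k, which would bias the tails
  of the population habitual distribution; variance-matched shrinkage
  preserves the person ranking and the population mean while restoring
  the between-person spread (the classic shrink-then-inflate construction
  of usual-intake methodology). When σ̂²_w = 0 the rescaling factor is
  exactly 1 and habitual values equal back-transformed 2-day means.
* Back-transformation: habitual intake is
  Hᵢ = ∫ g⁻¹(f̂(ageᵢ) + b̂ᵢ + e) φ(e; σ̂²_w) de by Gauss–Hermite quadrature
  (order 15 by default; exact for λ=1, accurate to ≪1e-6 of the
  log-normal closed form for λ=0 at realistic σ_w). Negative Box-Cox
  powers can push quadrature nodes outside the transform's image; this is
  reported as an error advising a λ floor of 0.

### Two-part model (episodic sources with true non-consumers)

Sources (b) and (c) are episodic and have structural zeros: subjects never
assigned an iodised product, and never-salting subjects, are true
non-consumers with habitual intake exactly 0. For potential consumers the
habitual intake is p̂ᵢ × amountᵢ, where

* p̂ᵢ is the age-dependent probability of a consumption day, fitted per
  sex by logistic regression on the spline age basis over the day-level
  consumption indicators (survey-weighted; degenerate all-0/all-1 cases
  collapse to a constant). The probability and amount parts are fitted
  independently.
* amountᵢ is the one-part model fitted on positive consumption days only
  (subjects may contribute one day). A potential consumer with no observed
  positive day gets the population-mean amount at their age and sex,
  integrating over both variance components.

With never-consumer fraction 0 and consumption probability 1 the two-part
model reproduces the one-part model exactly.

### Supplement model

Potential users are subjects with reported supplemental iodine in at least
one recall and/or questionnaire-reported use of iodine-containing
supplement categories. Users with recall amounts keep the mean of their
reported daily amounts as habitual (supplement doses are label-quantised
and stable day to day, so the reported amount is the habitual amount).
Questionnaire-only users receive a prediction from a recursive
partitioning (regression-tree) model trained on the users with known
amounts; default covariates are age and sex with a minimum leaf size of
10. Non-users contribute a structural zero.

## Combination and evaluation

The four habitual distributions are combined "first shrink then add": each
source is shrunken separately (retaining source-specific transformations
and variance components, and source-specific non-users), then a Monte
Carlo sample of simulated individuals (default 100 000) sums one habitual
draw per source. A simulated individual first draws an (age band × sex)
stratum by survey weight, then draws each source independently within the
stratum. Conditional-on-stratum independence is the key structural
assumption — person-level correlation between sources beyond what age and
sex induce is not modelled; `match_persons=True` keeps a subject's four
sources attached as a sensitivity alternative.

Adequacy is the weighted fraction of the habitual total below the age/sex
band's EAR (EAR cut-point method); safety the fraction above the UL. The
EAR/UL values are user configuration — the shipped `default_dri()` is an
illustrative table in the style of the IOM EARs and SCF ULs.

Sources (a) and (d) do not depend on salt assignment and are fitted once;
(b) and (c) are re-fitted per assignment iteration. Every statistic
(percentiles 5/25/50/75/95, %<EAR, %>UL per band, source shares) is
reported as the ensemble median with SD and 2.5–97.5 range across the
iterations, quantifying the iodised-salt assumption uncertainty.

## Synthetic data generator

Because the survey microdata are not public, the package ships a
generator that emulates the structure the estimation assumes, with known
ground truth: per-source person-day intakes back-transformed from
f(age) + b + e on the chosen Box-Cox scale, episodic groups with true
never-consumers, a salt questionnaire observed for one third of subjects,
and a ~10 % supplement-user fraction with label doses {50, 100, 150} µg
reported on a recall day with probability 0.6. The default ("survey")
parameter set produces log-normal-ish intakes with a natural-source median
near 110–150 µg/d, daily bread around 110–130 g/d and mild age trends; the
recovery preset uses the identity transform with constant mean 150 µg/d,
σ_b = 20 and σ_w = 30 so that the habitual truth is exactly
Normal(150, 20²) and closed-form oracles exist
(`true_prevalence_below`).

Deliberate simplifications, and hence what passing tests do *not* show
about real data: one representative food per group (no brand/NEVO-level
heterogeneity); foods in the salt branches carry zero natural iodine so
each branch's truth is exact (real potatoes contribute natural iodine
too); no seasonality, no correlated food choices beyond age/sex, no
misreporting; supplement doses exactly label-quantised. The default fixture
sizes are 2000 subjects for recovery tests and ~50–300 for unit tests.

## Problem sizes and numerical choices

The shipped acceptance run uses 2000 subjects for the recovery study and
1000 subjects × 100 assignment iterations × 50 000 Monte Carlo individuals
for the full pipeline — sizes chosen so the whole run completes in well
under a minute while leaving Monte Carlo error far below the reported
spreads. Weighted percentiles use the inverse weighted-ECDF definition
(smallest value whose cumulative weight share reaches p), which is
monotone in p and exact on point masses. Rounding in exact-fraction
sampling is round-half-to-even. All JSON reports are written with sorted
keys and no timestamps, so identical configurations and seeds produce
byte-identical outputs.

## Known limitations

* Variance-component estimation assumes the balanced 2-day design; designs
  with 3+ recalls would need the general REML path.
* The probability part of the two-part model has no person-level random
  effect: individual consumption frequency beyond the age/sex trend is not
  captured.
* Cross-source correlation is limited to what the stratum induces (see
  above).
* The uncertainty ensemble covers assignment uncertainty only; sampling
  uncertainty of the survey itself (bootstrap over subjects) is out of
  scope.
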