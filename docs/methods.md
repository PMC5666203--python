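# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, and what the synthetic data can and cannot
establish.

## Cohort model and the synthetic generator

A cohort record is one person: sex, continuous age at census in
[20, 60), a SOC 2000 occupation code (or none reported), geography, a
follow-up interval from the census date, and a death flag.  The generator
draws age uniformly on the configured range, occupation from configured
prevalences, and a death time from a piecewise-constant hazard over
attained 5-year age bands:

    lambda_g(a) = (r_g / 100 000) * m_band(a)

with r_g the group's target standardised rate and m_a age-shape
multipliers.  Death times are sampled band by band (exponential residual
time within each band, survival into the next band when the draw exceeds
the time spent there), which is exact for a piecewise-constant hazard.
Censoring is administrative at the end of follow-up (default 10 years).

The multipliers are constrained so that sum_a w_a m_a = 1, where w_a are
the standard-population weights renormalised over the in-range bands.
Under that constraint the *expected directly standardised rate equals r_g
exactly*, whatever the age shape, because standardisation reweights the
band-specific rates by exactly the w_a used in the constraint.  The crude
rate has no such protection — it weights band rates by the cohort's own
person-time — and the test suite uses that contrast (a U-shaped hazard
whose crude rate falls well below the target while the standardised rate
stays on it) to show the standardisation is doing real work.

Defaults and deliberate simplifications:

- Age at census is uniform; the true age mix within occupations is not
  public.  Uniform exercises the Lexis machinery fully and is overridable.
- Hazard depends on attained age, not baseline age, so a ten-year
  follow-up genuinely crosses band boundaries.
- One census date per geography (2001-04-29 by default); the particular
  day is immaterial to the mathematics.
- Dates are stored at day precision and all age/person-time arithmetic
  uses a 365.25-day year, consistently across generator, splitter and
  validators.  Day rounding perturbs individual follow-up by at most half
  a day, far below every tolerance used.
- Not modelled: census non-response, linkage failure, emigration
  loss-to-follow-up, cause-specific mortality.  Passing parameter-recovery
  tests therefore shows the pipeline is self-consistent, not that real
  linkage data are free of those problems.

## Lexis splitting

Follow-up is partitioned at the exact ages where the person crosses a
band boundary; contributions sum to the follow-up length by construction.
A death is attributed to the band containing attained age at exit, with
an exit exactly on a boundary belonging to the band below (the band the
person actually spent their final instant in).  Default bands tile
[20, 70) — baseline ages 20–59 plus ten years of ageing; time beyond the
top edge goes to a catch-all 70+ band with a warning.  A baseline-age
basis (all time to the band of age at census, bands [20, 60)) is provided
as an option because published analyses do not always state which basis
was used; attained age is the default as the epidemiologically standard
choice when follow-up spans a decade.

## Standardisation

R = 1e5 * sum_a w_a d_a/PY_a with Var(R) = 1e10 * sum_a w_a^2 d_a/PY_a^2
(band deaths Poisson, delta method on the fixed-denominator rates), CI =
R ± 1.959964 se.  The ESP 2013 weight table is packaged with the 0–4 and
90+ bands pre-merged (5 000 and 1 000 per 100 000); only the 20–69 bands
matter here and weights are always renormalised over the bands present —
[20, 70) for the attained basis, [20, 60) for baseline.  Bands with no
person-time and no deaths are dropped with a warning before
renormalising; a band with deaths but no person-time is impossible input.
A symmetric normal interval (not a gamma interval) is the deliberate
convention, matching how the packaged published tables were themselves
summarised; with the death counts involved (tens to hundreds per group)
the difference is below display rounding.

Disclosure control: groups under 10 deaths are flagged suppressed and
omitted from rendered tables but kept for totals.  The hierarchical
collapse merges the deficient group with fewest deaths first, into the
sibling sharing the longest common code prefix, choosing the
fewest-deaths sibling on ties and ascending code after that.  This order
is a determinism choice — any order satisfies the threshold, but a fixed
one makes outputs reproducible.  Merged groups get a synthetic id
(common prefix + "x").  A group with no sibling at any level, and the
no-occupation group, cannot merge and are suppressed instead.  The
operation is idempotent and conserves total deaths.

## Monte Carlo rate differences

Published rates from separate safe settings cannot share a likelihood, so
differences are simulated: each rate is Normal(rate, se), n_sim = 10 000
independent pairs, difference per pair, interval = empirical 2.5%/97.5%
quantiles, reported difference = mean of the simulated differences.
Standard errors reconstructed from printed intervals use
(high − low)/(2 × 1.959964).  Choices worth stating:

- The two-sided p value is 2·min(share above 0, share below 0), floored
  at 1/n_sim.  The published tables did not state their formula; this
  definition reproduces their printed p values.
- Draws for the two rates are independent (no pairing), matching a
  procedure that simulates each country separately and compares per
  simulation.
- Negative simulated rates are allowed: the normal approximation is the
  point (the published analysis itself noted it could not use the more
  appropriate Poisson because death counts were not releasable).
- The random stream is assigned to the two inputs by lexicographic label
  order, which makes swapping the arguments mirror the result *exactly*
  (same seed), a convenient invariant for testing.
- Per-group comparisons across whole tables derive an independent
  substream per group from the master seed (keyed by sorted group id), so
  row order cannot change results.

The empirical interval of 10 000 draws carries sampling noise: the 2.5%
quantile of a normal has standard deviation ≈ 0.0267 σ at that size,
about 1 per 100 000 for the rate uncertainties typical of the packaged
tables.  The oracle-equivalence acceptance check (empirical vs closed-form
normal-difference interval within ±2 per 100 000) therefore draws its 100
random input pairs with se in [4, 10] — the regime of well-estimated,
large groups — where ±2 is more than five quantile standard deviations
and the check has essentially full power; at larger se the identical code
path simply carries proportionally larger, correctly-quantified noise.

The p-value calibration test replicates the frequentist experiment (two
observed rates drawn around one truth, then the procedure applied);
applying the procedure to two *literally identical* summaries gives p ≈ 1
by construction, which is correct behaviour but not a calibration check.

## Scenarios

P_g = W · PY_g / Σ PY_g allocates a national working-age count over
groups; persons are treated as annual person-years at risk (a static
snapshot — outputs are deaths per year, and no dynamic population model
is warranted by the inputs).  Expected deaths D_g = r_g P_g / 1e5; a
scenario swaps in another geography's rate table.  Per draw, every rate
is sampled from its normal approximation and per-group changes sum to the
total change exactly, so reported totals are internally consistent.
Baseline and counterfactual draws are independent; as the one exception,
a counterfactual table value-identical to the baseline reuses the
baseline draws so the self-scenario excess is exactly zero (identity
enforced by table equality, not draw pairing).  Groups lacking a rate in
either table are dropped from both arms to keep the contrast
like-for-like.  The 2001 working-age counts W per sex and geography were
never published alongside the tables and are a required user input; the
published headline excess-deaths totals also depend on per-occupation
person-years that are not public, so the engine is validated against
exact identities (self-scenario zero, closed-form means, additivity,
linearity in W) rather than against those totals.

## Packaged data

Four published rate tables (England & Wales 2001–11 men/women; Scotland
1991–2001 and 2001–11 men/women) transcribed into CSV, with the group id
equal to the published SOC code, `none` for the no-occupation row and
`all` for the every-occupation row.  The grouping files list one group
per published code (union over the two geographies per sex) plus the
no-occupation group; the exact membership of merged published categories
(for example the two-digit professional groups) was never released, so
groupings are configuration, not ground truth, and four-digit input codes
fall into them by longest-prefix match.

## Problem sizes and determinism

Stochastic tests fix their seeds and were sized for stable margins: the
parameter-recovery check uses one 200 000-person cohort (about 13 000
deaths across six groups spanning 150–1100 per 100 000, every group far
past 50 expected deaths, assertion at ±3 estimated standard errors);
distribution-level Monte Carlo checks use 10 000–200 000 draws as noted.
Every simulation, comparison and scenario is reproducible from a single
integer seed; reruns with the same seed produce byte-identical CSVs.

## Known limitations

- The synthetic cohort draws occupation independently of age; real
  occupation prevalence is strongly age-structured.
- Standard errors reconstructed from rounded printed intervals inherit
  the rounding (up to ~1 per 100 000 on the interval width), which is why
  reproduction tolerances on published differences are a few per 100 000.
- The no-occupation group is heterogeneous (students, homemakers,
  long-term sick) and the model gives it a single hazard.
- Northern Ireland data (incomplete death ascertainment in the source
  linkage) and cause-specific mortality are out of scope.
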