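# Methods

## Model structure

The engine is a discrete-time Markov cohort model with six states
{NW1, NW2, OW, OB1, OB2, dead}, annual cycles, ages 2–100 (98 cycles),
simulated separately for women and men.  NW1 and NW2 share every
parameter; the split exists so that "never heavier" and "previously
heavier" normal-weight people can be given different parameters later.
Structural zeros follow the transition graph: moves are one class at a
time, OW regresses to NW2 (never NW1), NW1 is left only via OW, and the
dead state is absorbing.

Within a cycle, mortality is applied first to the state held at cycle
start; survivors then move between weight classes.  The surviving mass of
a state splits between its scheduled moves, with the stay-probability
defined as the complement — rows of every transition matrix therefore sum
to one exactly, and cohort mass is conserved to machine precision.

Defaults (`ModelSpec`): 55,120 persons (26,458 women, 28,662 men),
initial distribution 89.83 / 8.98 / 0.86 / 0.33 % over NW/OW/OB1/OB2
assigned to NW1, OW, OB1, OB2; discount rate 4%/y with age 2 as the
discounting base; no half-cycle correction (available as a flag).  The
female cohort size is the complement of the male size in the total rather
than exact 48% rounding, so the per-sex totals add up.

## Transition probabilities from survival curves

Sparse longitudinal records are interpolated linearly in weight between
measurements and in height until age 18, after which height is constant;
a measurement pair straddling 18 reaches the later measured height at
exactly 18.  Persons with fewer than two measurements are excluded (and
counted).  Annual BMI values are classified with WHO adult cutoffs from
age 18 and age/sex-specific child cutoffs at 2–17; all class intervals
are lower-inclusive (a BMI of exactly 35 is grade-2 obesity).

For each of six transitions, spells open at the first age a person is
observed in the origin class (delayed entry on the age clock), close with
an event at the first age in the destination class, and are censored at
loss to follow-up or on exit to a non-destination class (cause-specific
censoring — the standard treatment; whether the source analyses censored
or dropped such spells is not determinable, and censoring preserves risk
time).  Re-entry into the origin class opens a new spell.  A two-class
jump between consecutive annual states (possible in raw data after
interpolation, impossible in the model graph) is decomposed into two
one-class events at the same boundary; the pass-through spell is given a
nominal duration of 0.5 y to preserve entry < exit, and occurrences are
counted.  Spells are assigned to the child/adolescent/adult estimation
band by entry age and split at the band boundaries (13, 20), the later
part entering the next band with delayed entry.

Six parametric families are implemented on their natural scales:
exponential (rate λ), Weibull (log-rate β₀, shape p; S = exp(−e^{β₀}t^p)),
log-normal (μ, σ of log-time), log-logistic (location, scale of
log-time), Gompertz (shape γ, rate λ; h = λe^{γt}) and the
three-parameter generalized gamma (μ, σ, κ), which nests the log-normal
(κ→0) and Weibull (κ=1).  The likelihood is the left-truncated
right-censored form Σ event·ln f + censored·ln S − ln S(entry).
Because annual state series only locate an event to within a year, the
fitting entry point also offers an interval-censored event term
ln[S(max(entry, t−1)) − S(t)], which is the exact likelihood of the
annual observation process; fitting the continuous density at integer
exit times instead is measurably inconsistent for such data (bias ≈ −0.13
on the log-normal μ at ≈ 4,000 spells).  Use `interval_width=1.0` for
spells built from annual series, and the default (continuous) form for
genuinely continuous times.

Optimisation is deterministic: moment-based starting values with a fixed
set of perturbed multi-starts, Nelder–Mead polish followed by BFGS, and
positivity-constrained parameters fitted on the log scale.  The parameter
covariance is the inverse observed information from a central-difference
Hessian at the optimum.  Family selection minimises AIC or BIC over the
converged fits; ties (within 1e−9) break to fewer parameters, then a
fixed family order.  Model selection is intended to be run on pooled
data, with parameters refitted per sex under the selected family.

The annual transition probability at integer age a is
p(a) = [S(t) − S(t+1)]/S(t) with the analysis clock t = a − band entry
age (entry ages 2, 13, 20).  The band-entry clock origin is used for all
three bands because it exactly reproduces the documented annual
child-band sequence (0.49%, 1.70%, 2.46%, … averaging 2.72% for the
women's NW→OW log-normal(3.16, 1.22) fit); whether adult analyses used
absolute age instead cannot be determined from the available decade
means, so the convention is uniform and configurable in principle via the
band entry ages.  Schedules cover ages 2–99 (child fits serve 2–12,
adolescent 13–19, adult 20+, the adult clock extending to the horizon
without an extrapolation cap); probabilities are clipped to [0, 1].

The shipped default models (`data/default_transition_models.csv`) carry
published Norwegian child-band log-normal, adolescent Weibull/Gompertz
and adult Gompertz estimates.  For the two adult progression cells
originally reported from log-logistic fits, the printed tuples' link
scale could not be pinned down (under the (location, scale)-of-log-time
reading they imply near-total transition within two years, contradicting
the reported ≈ 3% annual averages), so the defaults use constant hazards
matched to the reported adult average annual probabilities
(3.25/3.86/2.38/1.63%).  The log-logistic family itself is fully
implemented and tested.

## Mortality

Annual death probability: q = 1 − exp(−m·HR), with m the life-table rate
and HR the BMI-class hazard ratio for the age band (NW ≡ 1, NW1/NW2
share it).  Scaling the rate rather than the probability keeps q < 1 for
any finite inputs and matches the definition of a hazard ratio.  With all
HRs equal to 1, engine survivorship telescopes exactly to the life
table's — a structural identity used as an acceptance check.  The shipped
hazard-ratio table and the Gompertz–Makeham life table
(m = c + λe^{γ·age}, λ bisected so that engine life expectancy from age 2
is ≈ 80 y) are synthetic fixtures, clearly non-authoritative; real
analyses must supply national life tables and meta-analytic hazard
ratios as the delimited-text inputs.

## Costs

Individual annual costs are semicontinuous (many zeros, skewed
positives), modelled in two parts: logistic regression for P(cost > 0)
and a gamma GLM with log link for the positive mean, both with weight
class, age (continuous), smoking status and marital status as covariates,
stratified by sex (fits via statsmodels).  Incremental costs are average
marginal effects vs NW, averaged over the estimation sample's observed
covariate distribution with age set to each year from 20 to 80.  The
cost schedule is flat above 80 at the age-80 value; below 20 it defaults
to zero (configurable to constant-at-20) — the data behind the default
increments cover adults only, and the under-20 share of lifetime costs is
small either way.  Negative increments (men's OW) are used as-is.
Cost accumulation multiplies state occupancy by the per-state increment
at each age (survival-adjusted by construction), discounts by
(1+r)^(age−2), and reports whole-cohort and per-start-person totals.

## Probabilistic sensitivity analysis

Survival coefficient blocks are drawn as mean + L·z with L the lower
Cholesky factor of the block covariance; hazard ratios log-normally with
σ from the 95% CI; costs from gammas matched to mean and variance, with
negative-mean blocks drawn as negated gammas around |mean| (gamma is
positive-only; the sign-preserving draw is this package's convention).
Published coefficient covariances were not available, so the shipped
uncertainty builder substitutes synthetic diagonal covariances (5%
relative SE) and cost SEs back-derived from reported p-values (z = 3.5
assumed where only "p < 0.001" is known); these are replaceable inputs,
not estimates.  Randomness uses one stream per (iteration, block), the
block stream keyed by a stable digest of the block name, so adding a
block never perturbs other blocks' draws.  Confidence bounds are the
⌈0.025n⌉-th and ⌈0.975n⌉-th order statistics (no interpolation); drawn
scale parameters are clipped to their positive domain; failed iterations
are excluded and counted, with more than 5% failures aborting the run.

## Scenarios

Scenario 1 zeroes OB1→OB2 and moves the initial OB2 mass to OB1;
scenario 2 zeroes OW→OB1 and moves the initial OB1+OB2 mass to OW; the
stay-probability absorbs the removed mass, so matrices remain
row-stochastic.  Scenarios 3–6 start the whole cohort at age 30 in one
class with standard (adult-band) dynamics after.  Years of life lost are
reported as positive years (LE of the counterfactual minus base, or NW
start minus class-X start), with cohort totals scaled by the per-sex
sizes 26,458/28,662.  Life expectancy is start age plus the sum of
subsequent alive fractions, horizon-truncated at 100 (survivors at 100
are retained, not force-killed).  Note one non-theorem: with regression
flows active, scenario 1's OB1 occupancy can dip slightly below base at
some ages (the base OB2 pool regresses back into OB1); the accumulation
property holds exactly under progression-only dynamics and is tested
there.

## Synthetic data

The generator produces everything the pipeline consumes with known
ground truth: latent annual weight-class paths driven by a true
transition schedule (one-class moves; competing up/down hazards within a
year), visits at configured ages with survey-like structure (annual-ish
child checks, 4–11 y adult gaps, geometric dropout), BMI drawn uniformly
inside the latent class band and converted to weight via a deterministic
sex-specific height curve plateauing at 18.  It emulates the *structure*
of linked health-survey anthropometry, not its content: no realistic
growth curves (LMS), no secular trends, no informative dropout by
default, and within-band BMI is uniform rather than skewed.  Passing
recovery tests therefore demonstrate correctness of the
restructure-and-fit machinery under the model's own assumptions, not
robustness to real-data violations of them.

## Numerical and testing choices

Problem sizes: recovery tests use ≈ 5,000 spells per replicate, averaging
estimates over five seeded replicates because the single-replicate
sampling SD of the log-normal parameters (~0.05 at ≈ 1,000 events) is the
same order as the ±0.05 accuracy band being asserted; family-selection
recovery uses 50 seeded replicates of n = 5,000 over the five non-nesting
candidate families — with the generalized gamma (a strict superset of the
Weibull) in the set, AIC prefers the superset with asymptotic probability
P(χ²₁ > 2) ≈ 16%, so "selects the generating family" is only a
well-posed criterion among non-nesting alternatives.  The microsimulation
oracle (200,000 agents through the identical matrices) is compared
cell-wise within 3 Monte-Carlo standard errors plus a 20-agent absolute
floor: 594 simultaneous 3σ checks expect ~1.6 chance exceedances, and the
floor absorbs that multiplicity while remaining orders of magnitude below
the systematic deviation any engine defect would produce.  S(t) = 0
cells return a transition probability of 1 with a logged warning;
degenerate spells from two-class jumps carry the 0.5-y pass-through
convention; the exponential MLE closed form (events / exposure) anchors
the optimiser in tests, and lifelines serves as an independent
cross-check of the left-truncated log-normal fit.

## Known limitations

Secular trends are whatever the fitted hazards imply — there is no
explicit trend term.  Covariates beyond sex are not supported in the
survival models.  The shipped cutoff, hazard-ratio, life-table and cost
tables are reference/synthetic fixtures; all headline absolute outputs
(life expectancy, costs, YLL) depend on the user supplying authoritative
versions of these inputs.  Treatment effects that change BMI within a
class (relevant for severe obesity) are invisible to a class-based state
space.
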