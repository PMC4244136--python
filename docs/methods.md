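# Methods

This note documents the statistical model behind `rdscontacts`, the choices
made where the design was genuinely open, and the limits of what the
synthetic-data tests demonstrate.

## Data model

A webRDS dataset is a participant table and an edge table forming a
recruitment forest: each participant has at most one recruiter, recruits at
most four others, and sits at a *wave* equal to its recruiter's wave plus
one (seeds are wave 0).  Waves and tree membership are derived by
breadth-first traversal at load time, never trusted from the file.  A
participant's **degree** is the reported number of contact persons at
different locations plus while travelling during one recording day; contact
persons while eating and household members are recorded separately and are
*not* part of the degree.  A contact person is someone within arm's length
for at least 30 seconds.

Symptom classes: influenza-like illness = {fever, headache, muscle pain}
all present; common-cold-like = {runny nose, sore throat, cough} all
present; a respondent can be both or neither.

Filtering: degrees above 2,200 (physically implausible given the contact
definition) are removed with their incident edges.  Children of a removed
node are promoted to seeds, which preserves all pair distances *within*
surviving subtrees without inventing links; a `drop_subtrees` flag discards
the whole subtree instead.  Incomplete responses are retained for forest
structure but excluded pairwise from attribute correlations and from the
degree fits (the surveys tabulate "total participants" and "complete
responses" separately; how incomplete rows entered the original fits is not
stated, so complete-only is our default and is controlled by a flag).

Reported percentages round half-up to one decimal.  One consequence: the
Thai household effective contact rate computed from the printed moments is
exactly 6.15, which our convention rounds to 6.2 where half-even rounding
would print 6.1.

## Degree distributions

Degrees are modelled as negative binomial N(μ, k) with variance μ + μ²/k;
small k means strong overdispersion.  The MLE of μ is the sample mean
(exact property of the NB likelihood), so fitting reduces to a 1-D profile
likelihood search in k, done on the log scale over k ∈ [10⁻³, 10³] with
tolerance 10⁻⁸.  Confidence intervals are percentile intervals over B
parametric resamples (default B = 1000; simulate NB(μ̂, k̂) of the original
size, refit).  The likelihood is evaluated on value–frequency pairs, which
makes a single fit cheap enough for nested bootstrap-within-simulation
tests.

Sample comparison uses the Scholz–Stephens k-sample Anderson–Darling
statistic in its **midrank (tie-corrected)** form, mandatory for count data.
The statistic and its exact null mean/variance are implemented in-package
(the test suite cross-checks the standardized statistic against an
independent library implementation and the raw statistic against a direct
transcription of the defining formula).  Two p-value routes are exposed and
labelled: the standard-normal approximation of the standardized statistic,
and a permutation distribution of the pooled sample (the default below a
pooled size of 200, where the normal approximation is least trustworthy).
A two-sample KS test and matched empirical quantiles (Q-Q) complete the
comparison toolkit.

## Mixing by link distance

Within-tree pair sets at link distance 1, 2, 3 and ≥4 (lumped) are built
from depths and lowest common ancestors along root paths.  Two modes:
`all-pairs` (any two members of a tree at that shortest-path distance,
including siblings and cousins — the default) and `lineal-only`
(ancestor–descendant chains).  Which of the two the original analysis used
for distances ≥2 is not stated; both are available and reported.

Correlations on unordered pairs are computed on the symmetrized pair list
(each pair in both orientations) so estimates are orientation-free; CI and
p use the number of distinct pairs.  Methods: Pearson r (integer
attributes), phi (binary; identical to Pearson on 0/1 coding), Spearman
rank (ordinal).  Transforms: natural log of count + 1 (zero degrees exist),
and pooled-quintile categorization for degree classes.  CIs are Fisher-z
asymptotic; the phi p-value is χ² = nφ² with 1 df.  These asymptotics
ignore the dependence structure within trees (pairs share members), so the
intervals are approximate — a deliberate match to standard practice for
this design.

## First-order Markov check

If recruitment is first-order Markov, correlations factorize along chains.
For a numeric attribute the check compares r₀₋₃ over (seed, wave-3
descendant) lineal pairs with the product r₀₋₁·r₁₋₂·r₂₋₃ of stepwise
(ordered, non-symmetrized) estimates.  For a binary attribute the one-step
transition matrix P is estimated from recruiter→recruitee counts, the joint
table diag(marginal)·P³ is formed with the marginal taken from wave-0
participants (the natural choice for a seed-anchored comparison), and its
phi is compared with the directly observed one.  For the symmetric 2-state
chain with stay probability q and uniform marginal the implied phi is
exactly (2q − 1)³, which the tests verify.  The module reports both numbers
and deliberately issues no verdict: with few deep trees the order of the
process cannot be pinned down, only a systematic excess of the direct
correlation can be flagged.

## Effective contact rate

Under proportionate mixing in a population stratified by contact rate,
R₀ ∝ C = m + v/m with m the mean and v the variance of individual contact
rates.  The sample variance uses the n − 1 denominator (the alternative
changes nothing at one decimal for samples of a few hundred).  Summaries are
produced per category — degree, locations only, travel only, eating,
household members (household size as the rate) — and scenario comparisons
report (C_full, C_restricted, ratio), e.g. full contacts versus household
only as a stay-at-home scenario.  For NB(μ, k) rates, C → μ + 1 + μ/k;
the suite checks convergence at n = 10⁵ within 2%.

## Recruitment drivers

The intention to recruit (did the respondent request invitations on the
last survey page?) is modelled by logistic regression on degree, age, sex
(female indicator), education (ordered codes 1–3) and household size —
the smallest model consistent with the survey's adjustment set.  Degree
enters untransformed by default (log-degree by flag).  Fitting is IRLS via
a GLM with binomial family; non-finite or exploding standard errors are
reported as separation with the offending covariate named.  Prediction
curves transform the linear predictor's ±1.96 SE band through the inverse
logit, so bands stay in [0, 1] and contain the point estimate.  The model
is fitted with and without seeds, since seeds volunteered rather than being
recruited.

## Synthetic-data generator

The generator emulates the features the analyses rely on, with defaults set
from the published tabulations where printed:

- degrees i.i.d. NB(μ, k): NL-like (25.65, 1.00), TH-like (58.51, 0.83);
- the degree split multinomially over location/transport settings with
  shares reproducing the published locations-vs-travel category means;
  eating contacts an independent NB draw with moments matched to the
  printed mean/variance (NL 7.3/106.5, TH 11.8/225.0);
- household-size distributions with means ≈3 (NL) and ≈4 (TH), symptom-class
  probabilities matching the printed ILI / common-cold / two-or-more shares,
  seed age/sex/education from the printed seed tabulations, completion
  probabilities 0.899 / 0.856, recruitment-method shares as printed;
- homophilous recruitment: recruitee age = recruiter age + N(0, age_sd)
  truncated to [14, 80] (integer years); recruitee sex equals the
  recruiter's with probability q; education drawn from the recruiter's row
  of a 3×3 transition matrix built as (1 − w)·marginal + w·identity.
  Defaults (age_sd 8 y NL / 6 y TH, q 0.645 / 0.60, w 0.15 / 0.55) were
  chosen once to place the distance-1 sex and education correlations in the
  range the surveys report (phi at distance 1 ≈ 2q − 1 for a balanced
  population);
- branching: intention to recruit follows logit p = −0.25 + 0.008·degree +
  0.45·female (coefficients config-visible so the recruitment model has a
  known truth to recover); conditional on intending, successes are
  Binomial(4, success_prob) with success_prob 0.30 / 0.24, calibrated to the
  published recruiter–recruitee pair counts per inviter;
- `markov_order=2` anchors each recruitee attribute on the recruiter or,
  with probability 1/2, the grand-recruiter — the minimal long-memory
  deviation the Markov check should detect.

Everything is driven by one `numpy` Generator seeded from the config, so a
given seed yields a bit-identical dataset.

**What the generator does not emulate** (hence what green tests do not show
about real data): no joint distribution of degree with demographics (the
surveys do not print one; attributes and degree are independent here), no
age dependence in the younger/same/older contact tallies, no day-of-week
effects, no clustering of contacts, and no epidemic process on the network.
The distance-1 *age* correlation of the default random-walk kernel comes
out higher (~0.7) than the surveys report (~0.5), because the kernel
accumulates variance down the chain; the monotone dependence of the
correlation on `age_sd`, which is what the mixing tests exercise, holds
regardless.

## Problem sizes and numerical choices

Simulation-based checks in the test suite use sizes chosen to keep Monte
Carlo error well inside the asserted bands: coverage checks run 100
replicates (NB at n = 5000 with B = 199 bootstrap resamples — percentile
intervals are insensitive to B at this order; logistic at n ≈ 1600–2000);
the Markov agreement check uses one forest with ≥3000 seed-to-wave-3 chains
and the order-2 discrimination a sign test over 50 replicate forests; the
Anderson–Darling type-I check runs 1000 null simulations with 199
permutations each.  Ties in rank-based statistics use midranks throughout.
Degenerate inputs fail loudly: constant samples (k unidentifiable),
zero-variance correlation margins, all-zero contact rates (C undefined),
single-class or separated logistic outcomes.
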