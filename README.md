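# rdscontacts

Analysis toolkit for **online respondent-driven (webRDS) contact surveys**,
built for the comparison of social contact patterns relevant to the
transmission of respiratory pathogens across populations (the built-in
profiles mirror surveys run in the Netherlands and Thailand).

In a webRDS survey, seed participants fill in a short contact questionnaire
and invite up to four peers; invitees do the same, producing a *recruitment
forest* whose links can be read as real-world contacts.  This package
implements the full analysis chain for such data:

- **Data model & I/O** — participant/edge CSV tables, validation (forest
  structure, wave assignment by BFS, outlier filtering at degree > 2200),
  GraphML export, participation summary tables.
- **Degree distributions** — a participant's *degree* is the number of
  contact persons at different locations plus while travelling.  Fitted by
  negative-binomial maximum likelihood, N(μ, k) with variance μ + μ²/k, with
  parametric-bootstrap CIs; samples compared by the tie-corrected
  Scholz–Stephens Anderson–Darling k-sample test, two-sample KS, and Q-Q
  quantile pairs.
- **Mixing by link distance** — pairs of participants 1, 2, 3, ≥4 link steps
  apart in the same tree; Pearson r / phi / Spearman rank correlations with
  CIs, recruiter–recruitee contact-intensity matrices, younger/same/older
  contact-age proportions.
- **First-order Markov check** — is recruitment memoryless?  Compares the
  seed-to-wave-3 correlation r₀₋₃ with the stepwise product
  r₀₋₁·r₁₋₂·r₂₋₃ (numeric attributes) or the phi implied by the cubed
  one-step transition matrix (binary attributes).
- **Effective contact rates** — under proportionate mixing, R₀ ∝
  C = m + v/m, where m and v are the mean and variance of individual
  contact rates; computed per contact category (degree, locations, travel,
  eating, household members) and for intervention scenarios.
- **Recruitment drivers** — logistic regression of the intention to recruit
  on degree, age, sex, education and household size, with
  probability-vs-degree prediction curves, with and without seeds.
- **Synthetic data** — a generator producing datasets with the same
  statistical structure (NB degrees, ≤4 recruitees, homophilous recruitment
  with tunable strength and Markov order), so the whole pipeline is testable
  without access to survey microdata.

## Worked example

```python
import numpy as np
import rdscontacts as rc

# synthetic Dutch-like survey: 90 seeds, up to 6 waves
profile = rc.make_profile("NL-like")           # mu = 25.65, k = 1.00
forest = rc.generate_forest(profile, rc.GeneratorConfig(n_seeds=90, rng_seed=1))
forest = rc.filter_records(forest, max_degree=2200)

degrees = [rc.compute_degree(r) for r in forest.records(complete_only=True)]
fit = rc.fit_negbin(degrees, B=200, rng=1)
print(f"mu = {fit.mu:.2f} [{fit.ci_mu[0]:.2f}-{fit.ci_mu[1]:.2f}], "
      f"k = {fit.k:.2f}")

pairs = rc.pairs_at_distance(forest, 1)
age_r = rc.correlate_pairs(forest, pairs, "age")
print(f"age correlation at distance 1: {age_r.estimate:.3f} "
      f"[{age_r.ci_95[0]:.3f}-{age_r.ci_95[1]:.3f}]  n={age_r.n_pairs}")

ecr = {s.category: s for s in rc.category_summaries(forest)}
print(f"effective contact rate (degree): {ecr['degree'].C:.1f}")
```

prints (seed 1):

```
mu = 26.95 [23.60-30.19], k = 1.03
age correlation at distance 1: 0.783 [0.713-0.838]  n=154
effective contact rate (degree): 52.6
```

The fitted μ and k recover the profile's generating values (25.65, 1.00)
within sampling error; the distance-1 age correlation is strongly
assortative because recruitees' ages are drawn around their recruiter's;
and C ≈ 52.6 sits near the negative-binomial limit μ + 1 + μ/k ≈ 52.3 —
double the mean degree, because overdispersed contact rates inflate
transmission potential.

A command-line interface wraps the same pipeline:

```sh
rdscontacts generate --profile NL-like --seed 1 --out data/
rdscontacts analyze --participants data/participants.csv --edges data/edges.csv --out analysis/
rdscontacts table2                     # effective contact rates from published moments
```

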