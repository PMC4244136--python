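"""Summary values reported by the two webRDS surveys (Netherlands, Thailand).

These are *inputs*: printed sample moments and participation counts from the
original surveys, used to seed the synthetic profiles, to drive the
printed-inputs mode of the effective-contact-rate table, and to check that
the arithmetic of the pipeline reproduces the reported figures.  Nothing
here is a computed result of this package.
"""

from __future__ import annotations

#: Reported mean and variance of individual contact rates per category.
#: Degree means carry the two-decimal precision quoted with the
#: negative-binomial fits; other categories are printed to one decimal.
CONTACT_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    "NL": {
        "degree": (25.65, 2212.2),
        "locations": (21.4, 2057.6),
        "travel": (4.2, 80.8),
        "eating": (7.3, 106.5),
        "household": (3.0, 10.1),
    },
    "TH": {
        "degree": (58.51, 8601.9),
        "locations": (40.9, 4671.4),
        "travel": (17.6, 1346.9),
        "eating": (11.8, 225.0),
        "household": (4.0, 8.6),
    },
}

#: Reported negative-binomial degree fits (point estimates and 95% CIs).
DEGREE_FITS = {
    "NL": {"mu": 25.65, "mu_ci": (23.15, 28.51), "k": 1.00, "k_ci": (0.87, 1.16)},
    "TH": {"mu": 58.51, "mu_ci": (50.30, 67.24), "k": 0.83, "k_ci": (0.72, 1.02)},
}

#: Reported participation counts (numerator, denominator).
PARTICIPATION_COUNTS = {
    "NL": {
        "total_participants": 358,
        "complete_responses": (322, 358),
        "invited_seeds": 189,
        "seeds_completed": (92, 189),
        "recruiter_recruitee_pairs": 233,
        "household_reported_by": 326,
    },
    "TH": {
        "total_participants": 257,
        "complete_responses": (220, 257),
        "invited_seeds": 191,
        "seeds_completed": (89, 191),
        "recruiter_recruitee_pairs": 140,
        "household_reported_by": 221,
        "degree_outliers_removed": 2,
    },
}
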