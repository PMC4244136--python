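"""Effective contact rates.

Under proportionate mixing in a population stratified by contact rate, the
basic reproduction number is proportional to the effective contact rate

    C = m + v / m,

where m is the mean and v the variance of the individual contact rates
(Anderson & May).  Heterogeneity therefore raises the transmission
potential above what the mean alone suggests: C = m exactly when v = 0.
For negative-binomial contact rates with mean mu and dispersion k,
C converges to mu + 1 + mu / k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import RDSForest, compute_degree


class UndefinedRateError(ValueError):
    """Mean contact rate is zero; C = m + v/m is undefined."""


@dataclass
class ContactRateSummary:
    category: str
    m: float  # sample mean
    v: float  # sample variance (n - 1 denominator)
    C: float  # effective contact rate
    n: int


def rate_from_moments(mean: float, variance: float) -> float:
    """C = m + v/m from summary moments."""
    if mean <= 0:
        raise UndefinedRateError("mean contact rate must be positive")
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    return mean + variance / mean


def effective_contact_rate(counts, category: str = "degree") -> ContactRateSummary:
    """Mean, variance and effective contact rate of a sample of rates."""
    values = np.asarray(counts, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need at least 2 contact rates")
    if (values < 0).any():
        raise ValueError("contact rates must be nonnegative")
    m = float(values.mean())
    v = float(values.var(ddof=1))
    return ContactRateSummary(category=category, m=m, v=v,
                              C=rate_from_moments(m, v), n=values.size)


def scenario_comparison(
    full: ContactRateSummary, restricted: ContactRateSummary
) -> tuple[float, float, float]:
    """Both C values and their ratio, e.g. all contacts vs household only."""
    return full.C, restricted.C, full.C / restricted.C


def category_summaries(
    forest: RDSForest, complete_only: bool = True
) -> list[ContactRateSummary]:
    """One effective-contact-rate summary per contact category.

    Categories: total degree, contacts at locations only, contacts while
    travelling only, contacts while eating, and household members
    (household size as the contact rate).
    """
    recs = forest.records(complete_only=complete_only)
    extractors = {
        "degree": lambda r: compute_degree(r),
        "locations": lambda r: sum(r.location_counts.values()),
        "travel": lambda r: sum(r.transport_counts.values()),
        "eating": lambda r: r.eating_count,
        "household": lambda r: r.household_size,
    }
    return [
        effective_contact_rate([fn(r) for r in recs], category=name)
        for name, fn in extractors.items()
    ]


def ecr_table(forest: RDSForest, complete_only: bool = True) -> pd.DataFrame:
    """Long-format table of (country, category, mean, variance, C, n)."""
    extract = {
        "degree": compute_degree,
        "locations": lambda r: sum(r.location_counts.values()),
        "travel": lambda r: sum(r.transport_counts.values()),
        "eating": lambda r: r.eating_count,
        "household": lambda r: r.household_size,
    }
    by_country: dict[str, list] = {}
    for rec in forest.records(complete_only=complete_only):
        by_country.setdefault(rec.country, []).append(rec)
    rows = []
    for country in sorted(by_country):
        for name, fn in extract.items():
            s = effective_contact_rate(
                [fn(r) for r in by_country[country]], category=name
            )
            rows.append(
                {
                    "country": country,
                    "category": name,
                    "mean": s.m,
                    "variance": s.v,
                    "C": s.C,
                    "n": s.n,
                }
            )
    return pd.DataFrame(rows)
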