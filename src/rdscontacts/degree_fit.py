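"""Degree-distribution fitting and comparison.

Negative-binomial maximum likelihood with parametric-bootstrap confidence
intervals, the Scholz-Stephens Anderson-Darling k-sample test (midrank
version, since count data are full of ties), the classical two-sample
Kolmogorov-Smirnov test, and matched empirical quantiles for Q-Q plots.

Parameterisation: mean ``mu`` and dispersion ``k`` with variance
``mu + mu**2 / k`` (the ecology convention); small ``k`` means strong
overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

K_BOUNDS = (1e-3, 1e3)
_K_TOL = 1e-8


class DegenerateDataError(ValueError):
    """All observations equal: the dispersion parameter is unidentifiable."""


@dataclass
class NegBinFit:
    mu: float
    k: float
    ci_mu: tuple[float, float]
    ci_k: tuple[float, float]
    loglik: float
    n: int
    B: int

    def variance(self) -> float:
        return self.mu + self.mu**2 / self.k


@dataclass
class TwoSampleTestResult:
    statistic: float
    p_value: float
    method: str  # "AD-k-sample" or "KS-two-sample"
    p_method: str  # "asymptotic" or "permutation"


def _nb_loglik(counts: np.ndarray, weights: np.ndarray, mu: float, k: float) -> float:
    p = k / (k + mu)
    return float(np.sum(weights * stats.nbinom.logpmf(counts, k, p)))


def _fit_mu_k(values: np.ndarray) -> tuple[float, float, float]:
    """Profile-likelihood NB fit: mu at the sample mean, 1-d search in k."""
    mu = float(values.mean())
    uniq, weights = np.unique(values, return_counts=True)
    res = optimize.minimize_scalar(
        lambda log_k: -_nb_loglik(uniq, weights, mu, np.exp(log_k)),
        bounds=(np.log(K_BOUNDS[0]), np.log(K_BOUNDS[1])),
        method="bounded",
        options={"xatol": _K_TOL},
    )
    k = float(np.exp(res.x))
    return mu, k, _nb_loglik(uniq, weights, mu, k)


def fit_negbin(
    counts, B: int = 1000, rng: np.random.Generator | int | None = None
) -> NegBinFit:
    """Maximum-likelihood NB fit with percentile-bootstrap 95% intervals.

    ``mu`` is profiled out at the sample mean (the NB MLE of the mean);
    ``k`` maximises the profile likelihood on a bounded log-scale search.
    Confidence intervals are percentile intervals over ``B`` parametric
    resamples: simulate NB(mu_hat, k_hat) samples of the same size and refit.
    """
    values = np.asarray(counts, dtype=np.int64)
    if values.ndim != 1 or values.size < 10:
        raise ValueError("need a flat sample of at least 10 counts")
    if (values < 0).any():
        raise ValueError("counts must be nonnegative")
    if np.unique(values).size < 2:
        raise DegenerateDataError(
            "all counts are equal; the dispersion parameter k is unidentifiable"
        )
    rng = np.random.default_rng(rng)
    mu, k, loglik = _fit_mu_k(values)
    n = values.size
    boot = np.empty((B, 2))
    p = k / (k + mu)
    for b in range(B):
        resample = rng.negative_binomial(k, p, size=n)
        if np.unique(resample).size < 2:  # pathological resample; redraw-free guard
            boot[b] = (resample.mean(), k)
            continue
        bm, bk, _ = _fit_mu_k(resample)
        boot[b] = (bm, bk)
    ci_mu = tuple(np.percentile(boot[:, 0], [2.5, 97.5]))
    ci_k = tuple(np.percentile(boot[:, 1], [2.5, 97.5]))
    return NegBinFit(
        mu=mu,
        k=k,
        ci_mu=(min(ci_mu[0], mu), max(ci_mu[1], mu)),
        ci_k=(min(ci_k[0], k), max(ci_k[1], k)),
        loglik=loglik,
        n=n,
        B=B,
    )


# ---------------------------------------------------------------------------
# Anderson-Darling k-sample test (Scholz & Stephens), midrank tie correction.


def ad_statistic(samples: list[np.ndarray]) -> float:
    """The tie-corrected k-sample Anderson-Darling statistic A2akN."""
    samples = [np.asarray(s, dtype=float) for s in samples]
    z = np.sort(np.concatenate(samples))
    n_total = z.size
    zstar, lj = np.unique(z, return_counts=True)
    if zstar.size < 2:
        raise ValueError("pooled sample is constant")
    bj = np.cumsum(lj) - lj / 2.0
    denom = bj * (n_total - bj) - n_total * lj / 4.0
    a2 = 0.0
    for s in samples:
        s_sorted = np.sort(s)
        right = np.searchsorted(s_sorted, zstar, side="right")
        left = np.searchsorted(s_sorted, zstar, side="left")
        mij = right - (right - left) / 2.0
        inner = lj / n_total * (n_total * mij - bj * s.size) ** 2 / denom
        a2 += inner.sum() / s.size
    return float((n_total - 1.0) / n_total * a2)


def ad_standardize(a2: float, sizes: list[int]) -> float:
    """Standardize A2akN by its exact null mean (k-1) and variance."""
    k = len(sizes)
    n_total = int(np.sum(sizes))
    h_cap = float(np.sum(1.0 / np.asarray(sizes, dtype=float)))
    hs_cs = np.cumsum(1.0 / np.arange(n_total - 1, 1, -1))
    h = hs_cs[-1] + 1.0
    g = float(np.sum(hs_cs / np.arange(2, n_total)))
    a = (4 * g - 6) * (k - 1) + (10 - 6 * g) * h_cap
    b = (2 * g - 4) * k**2 + 8 * h * k + (2 * g - 14 * h - 4) * h_cap - 8 * h + 4 * g - 6
    c = (6 * h + 2 * g - 2) * k**2 + (4 * h - 4 * g + 6) * k + (2 * h - 6) * h_cap + 4 * h
    d = (2 * h + 6) * k**2 - 4 * h * k
    sigmasq = (a * n_total**3 + b * n_total**2 + c * n_total + d) / (
        (n_total - 1.0) * (n_total - 2.0) * (n_total - 3.0)
    )
    return float((a2 - (k - 1)) / np.sqrt(sigmasq))


def ad_ksample(
    samples,
    p_method: str = "auto",
    n_resamples: int = 999,
    rng: np.random.Generator | int | None = None,
) -> TwoSampleTestResult:
    """Test whether k count samples come from one common population.

    Reports the standardized A2akN statistic.  ``p_method="asymptotic"``
    uses the standard-normal approximation of the standardized statistic;
    ``"permutation"`` permutes the pooled sample.  ``"auto"`` picks
    permutation when the pooled size is below 200.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    for s in samples:
        if s.size < 5:
            raise ValueError("each sample needs at least 5 observations")
    sizes = [s.size for s in samples]
    n_total = int(np.sum(sizes))
    if p_method == "auto":
        p_method = "permutation" if n_total < 200 else "asymptotic"
    a2 = ad_statistic(samples)
    t_obs = ad_standardize(a2, sizes)
    if p_method == "asymptotic":
        p = float(stats.norm.sf(t_obs))
    elif p_method == "permutation":
        rng = np.random.default_rng(rng)
        pooled = np.concatenate(samples)
        bounds = np.cumsum(sizes)[:-1]
        exceed = 0
        for _ in range(n_resamples):
            perm = rng.permutation(pooled)
            if ad_statistic(np.split(perm, bounds)) >= a2:
                exceed += 1
        p = (1.0 + exceed) / (n_resamples + 1.0)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return TwoSampleTestResult(
        statistic=t_obs, p_value=p, method="AD-k-sample", p_method=p_method
    )


def ks_two_sample(a, b) -> TwoSampleTestResult:
    """Classical two-sample Kolmogorov-Smirnov test with asymptotic p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, method="asymp")
    return TwoSampleTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="KS-two-sample",
        p_method="asymptotic",
    )


def qq_pairs(a, b, n_quantiles: int = 99) -> np.ndarray:
    """Matched empirical quantiles of two samples for a Q-Q plot.

    Returns an ``(n_quantiles, 2)`` array of (quantile of a, quantile of b)
    at equally spaced probability points.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    probs = np.linspace(0, 1, n_quantiles + 2)[1:-1]
    return np.column_stack([np.quantile(a, probs), np.quantile(b, probs)])
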