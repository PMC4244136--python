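"""Drivers of online peer-recruitment.

Logistic regression of the intention to recruit (did the respondent request
invitations for recruitees on the last survey page?) on degree, age, sex,
education and household size, fitted on the full sample and on the sample
without seeds, plus predicted probability-versus-degree curves with
delta-method confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .io_model import RDSForest, compute_degree

COVARIATES = ("degree", "age", "sex_female", "education", "household_size")


class SeparationError(RuntimeError):
    """The likelihood is unbounded (complete or quasi-complete separation)."""


class SingleClassError(ValueError):
    """The outcome takes a single value in the requested subset."""


@dataclass
class LogisticFit:
    coefficients: pd.Series  # const + COVARIATES
    standard_errors: pd.Series
    covariance: pd.DataFrame
    loglik: float
    n: int
    converged: bool
    subset: str  # "all" or "excluding-seeds"

    def p_values(self) -> pd.Series:
        from scipy import stats

        z = self.coefficients / self.standard_errors
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.coefficients.index)


@dataclass
class PredictionCurve:
    degree_grid: np.ndarray
    probability: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    profile: dict[str, float]


def design_frame(forest: RDSForest, subset: str = "all") -> pd.DataFrame:
    """Outcome and covariates, one row per participant in the subset."""
    if subset not in ("all", "excluding-seeds"):
        raise ValueError(f"unknown subset {subset!r}")
    rows = []
    for rec in forest.participants.values():
        if subset == "excluding-seeds" and rec.wave == 0:
            continue
        rows.append(
            {
                "id": rec.id,
                "requested": int(rec.requested_invitations),
                "degree": compute_degree(rec),
                "age": rec.age,
                "sex_female": int(rec.sex == "female"),
                "education": rec.education,
                "household_size": rec.household_size,
            }
        )
    return pd.DataFrame(rows)


def fit_logistic(
    forest: RDSForest,
    subset: str = "all",
    log_degree: bool = False,
    covariates: tuple[str, ...] = COVARIATES,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of the intention to recruit.

    Fitted by iteratively reweighted least squares; standard errors come
    from the inverse observed information.  ``log_degree=True`` replaces
    raw degree with log(degree + 1); ``covariates=()`` gives the
    intercept-only model.
    """
    df = design_frame(forest, subset)
    if df.empty or df["requested"].nunique() < 2:
        raise SingleClassError(
            f"outcome has a single class in subset {subset!r}"
        )
    X = df[list(covariates)].astype(float).copy()
    if log_degree and "degree" in X:
        X["degree"] = np.log1p(X["degree"])
    X = sm.add_constant(X, prepend=True)
    y = df["requested"].astype(float)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=100, tol=1e-8)
    except Exception as err:  # statsmodels raises PerfectSeparationError
        raise SeparationError(str(err)) from err
    bse = res.bse
    if not np.all(np.isfinite(bse)) or np.any(bse > 1e4):
        worst = bse.index[int(np.nanargmax(bse.values))]
        raise SeparationError(
            f"non-finite standard errors; covariate {worst!r} appears to "
            "separate the outcome"
        )
    return LogisticFit(
        coefficients=res.params,
        standard_errors=bse,
        covariance=res.cov_params(),
        loglik=float(res.llf),
        n=int(df.shape[0]),
        converged=bool(res.converged),
        subset=subset,
    )


def probability_vs_degree(
    fit: LogisticFit,
    grid,
    profile: dict[str, float] | None = None,
) -> PredictionCurve:
    """Predicted probability of intending to recruit along a degree grid.

    Remaining covariates are held at the supplied profile (e.g. the sample
    means).  The 95% band is the linear predictor's +-1.96 standard errors,
    transformed through the inverse logit, so it always stays in [0, 1]
    and contains the point estimate.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    profile = dict(profile or {})
    grid = np.asarray(grid, dtype=float)
    names = list(fit.coefficients.index)
    X = np.zeros((grid.size, len(names)))
    for j, name in enumerate(names):
        if name == "const":
            X[:, j] = 1.0
        elif name == "degree":
            X[:, j] = grid
        else:
            X[:, j] = profile.get(name, 0.0)
    beta = fit.coefficients.values
    cov = fit.covariance.values
    eta = X @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
    return PredictionCurve(
        degree_grid=grid,
        probability=expit(eta),
        band_low=expit(eta - 1.959963984540054 * se),
        band_high=expit(eta + 1.959963984540054 * se),
        profile=profile,
    )


def fit_table(fits: list[LogisticFit]) -> pd.DataFrame:
    """Coefficient table over one or more fits (long format)."""
    rows = []
    for fit in fits:
        p = fit.p_values()
        for name in fit.coefficients.index:
            rows.append(
                {
                    "subset": fit.subset,
                    "term": name,
                    "estimate": fit.coefficients[name],
                    "se": fit.standard_errors[name],
                    "p_value": p[name],
                    "n": fit.n,
                }
            )
    return pd.DataFrame(rows)
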