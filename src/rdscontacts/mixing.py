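"""Mixing patterns in the recruitment forest.

Pairs of participants are enumerated by their link distance (tree shortest
path) within a recruitment tree — 1, 2, 3, with distances of four or more
lumped together — and attribute correlations are computed over those pairs:
Pearson's r for integer attributes, the phi coefficient for binary ones and
Spearman's rank correlation for ordinal ones.  A positive correlation at
distance 1 is assortative recruitment; decay towards zero with distance
shows how quickly homophily washes out along the chains.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import RDSForest, ParticipantRecord, compute_degree

DISTANCE_LABELS = (1, 2, 3, "4+")

#: attribute name -> (value getter, default correlation method)
ATTRIBUTES: dict[str, tuple] = {
    "age": (lambda r: float(r.age), "pearson"),
    "degree": (lambda r: float(compute_degree(r)), "pearson"),
    "eating": (lambda r: float(r.eating_count), "pearson"),
    "household_size": (lambda r: float(r.household_size), "pearson"),
    "sex": (lambda r: 1.0 if r.sex == "female" else 0.0, "phi"),
    "two_or_more_symptoms": (lambda r: 1.0 if len(r.symptoms) >= 2 else 0.0, "phi"),
    "education": (lambda r: float(r.education), "spearman"),
}


class UndefinedCorrelationError(ValueError):
    """A margin of the pair list has zero variance."""


@dataclass
class PairSet:
    distance_label: int | str
    pairs: list[tuple[str, str]]
    mode: str  # "all-pairs" or "lineal-only"


@dataclass
class MixingCorrelation:
    attribute: str
    method: str
    distance_label: int | str
    estimate: float
    ci_95: tuple[float, float]
    p_value: float
    n_pairs: int


@dataclass
class ContactIntensityMatrix:
    bins: np.ndarray  # bin edges
    counts: np.ndarray  # recruiter bin x recruitee bin
    proportions: np.ndarray


@dataclass
class AgeDirectionMatrix:
    table: pd.DataFrame  # columns: age_group, context, younger, same, older


# ---------------------------------------------------------------------------
# pair enumeration


def _ancestors(forest: RDSForest, pid: str) -> list[str]:
    out = [pid]
    while out[-1] in forest.parent:
        out.append(forest.parent[out[-1]])
    return out


def tree_distances(forest: RDSForest) -> dict[tuple[str, str], int]:
    """Shortest-path length for every unordered pair within a tree.

    Uses depths and lowest common ancestors along the unique root paths,
    so it is independent of any graph-library traversal.
    """
    anc = {pid: _ancestors(forest, pid) for pid in forest.participants}
    depth = {pid: len(anc[pid]) - 1 for pid in forest.participants}
    rank = {pid: {a: i for i, a in enumerate(chain)} for pid, chain in anc.items()}
    out: dict[tuple[str, str], int] = {}
    for members in forest.trees.values():
        for u, v in itertools.combinations(sorted(members), 2):
            ru = rank[u]
            lca_depth = None
            for a in anc[v]:
                if a in ru:
                    lca_depth = depth[a]
                    break
            out[(u, v)] = depth[u] + depth[v] - 2 * lca_depth
    return out


def _is_lineal(forest: RDSForest, u: str, v: str) -> bool:
    return u in _ancestors(forest, v) or v in _ancestors(forest, u)


def pairs_at_distance(
    forest: RDSForest, d: int | str, mode: str = "all-pairs"
) -> PairSet:
    """All unordered within-tree pairs at link distance ``d``.

    ``d`` is 1, 2, 3 or ``"4+"`` (distances of four or more lumped).
    ``mode="lineal-only"`` keeps ancestor-descendant pairs only, i.e. pairs
    along a single recruitment chain.
    """
    if d not in DISTANCE_LABELS:
        raise ValueError(f"distance must be one of {DISTANCE_LABELS}")
    if mode not in ("all-pairs", "lineal-only"):
        raise ValueError(f"unknown mode {mode!r}")
    dist = tree_distances(forest)
    if d == "4+":
        selected = [p for p, dd in dist.items() if dd >= 4]
    else:
        selected = [p for p, dd in dist.items() if dd == d]
    if mode == "lineal-only":
        selected = [p for p in selected if _is_lineal(forest, *p)]
    return PairSet(distance_label=d, pairs=sorted(selected), mode=mode)


# ---------------------------------------------------------------------------
# correlations


def _pooled_quintile_codes(values: np.ndarray) -> np.ndarray:
    edges = np.quantile(values, [0.2, 0.4, 0.6, 0.8])
    return np.searchsorted(edges, values, side="right").astype(float)


def _apply_transform(x: np.ndarray, y: np.ndarray, transform: str):
    if transform == "none":
        return x, y
    if transform == "log":
        # natural log of count + 1: zero counts occur
        return np.log1p(x), np.log1p(y)
    if transform == "categorize":
        pooled = np.concatenate([x, y])
        codes = _pooled_quintile_codes(pooled)
        return codes[: x.size], codes[x.size:]
    raise ValueError(f"unknown transform {transform!r}")


def _fisher_ci(r: float, n: int) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1.0:
        return (r, r)
    z = np.arctanh(r)
    half = 1.959963984540054 / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def correlate_pairs(
    forest: RDSForest,
    pairset: PairSet,
    attribute: str,
    method: str | None = None,
    transform: str = "none",
    symmetrize: bool = True,
    complete_only: bool = True,
    ci_method: str = "fisher",
    n_boot: int = 1000,
    rng=None,
) -> MixingCorrelation:
    """Attribute correlation over a pair set.

    For unordered pairs the estimate is computed on the symmetrized list
    (each pair entered in both orientations) so that it does not depend on
    orientation; the confidence interval and p-value use the number of
    distinct pairs.  Fisher-z asymptotics for r and rank r; a chi-square
    p for phi.  ``ci_method="cluster-bootstrap"`` resamples whole trees
    instead, which respects the dependence of pairs sharing a tree.
    Incomplete responses are dropped pairwise.
    """
    getter, default_method = ATTRIBUTES[attribute]
    method = method or default_method
    recs = forest.participants
    pairs = [
        (u, v)
        for u, v in pairset.pairs
        if not complete_only or (recs[u].complete and recs[v].complete)
    ]
    n = len(pairs)
    if n < 2:
        raise ValueError(f"need at least 2 pairs with complete data, got {n}")
    x = np.array([getter(recs[u]) for u, v in pairs])
    y = np.array([getter(recs[v]) for u, v in pairs])
    x, y = _apply_transform(x, y, transform)
    if symmetrize:
        x, y = np.concatenate([x, y]), np.concatenate([y, x])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            f"attribute {attribute!r} has zero variance over the pair margin"
        )
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method not in ("pearson", "phi"):
        raise ValueError(f"unknown method {method!r}")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if method == "phi":
        chi2 = n * r * r
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1 - r * r))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
    if ci_method == "fisher":
        ci = _fisher_ci(r, n)
    elif ci_method == "cluster-bootstrap":
        ci = _cluster_bootstrap_ci(forest, pairs, x, y, symmetrize, n_boot, rng)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return MixingCorrelation(
        attribute=attribute,
        method=method,
        distance_label=pairset.distance_label,
        estimate=r,
        ci_95=ci,
        p_value=p,
        n_pairs=n,
    )


def _cluster_bootstrap_ci(
    forest: RDSForest, pairs, x: np.ndarray, y: np.ndarray,
    symmetrize: bool, n_boot: int, rng,
) -> tuple[float, float]:
    """Percentile CI resampling whole trees (clusters of dependent pairs)."""
    rng = np.random.default_rng(rng)
    tree_of = forest.tree_id
    trees = sorted({tree_of[u] for u, _ in pairs})
    by_tree: dict[str, list[int]] = {t: [] for t in trees}
    for i, (u, _) in enumerate(pairs):
        by_tree[tree_of[u]].append(i)
    n = len(pairs)
    estimates = []
    for _ in range(n_boot):
        chosen = rng.choice(len(trees), size=len(trees), replace=True)
        idx = np.concatenate([by_tree[trees[c]] for c in chosen]).astype(int)
        # when symmetrized upstream, x/y hold both orientations; the first
        # n entries are the original orientation, so re-mirror after indexing
        xb = np.concatenate([x[idx], y[idx]]) if symmetrize else x[idx]
        yb = np.concatenate([y[idx], x[idx]]) if symmetrize else y[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            continue
        estimates.append(np.corrcoef(xb, yb)[0, 1])
    lo, hi = np.percentile(estimates, [2.5, 97.5])
    return (float(lo), float(hi))


def mixing_table(
    forest: RDSForest,
    attributes: dict[str, str] | None = None,
    mode: str = "all-pairs",
) -> pd.DataFrame:
    """Correlation estimates for every attribute at every link distance.

    ``attributes`` maps attribute name to transform (default: the published
    layout — age, sex, education, log degree, degree quintiles, log eating
    contacts, two-or-more symptoms).
    """
    if attributes is None:
        attributes = {
            "age": "none",
            "sex": "none",
            "education": "none",
            "degree": "log",
            "degree-categories": "categorize",
            "eating": "log",
            "two_or_more_symptoms": "none",
        }
    rows = []
    pairsets = {d: pairs_at_distance(forest, d, mode=mode) for d in DISTANCE_LABELS}
    for label, transform in attributes.items():
        attribute = "degree" if label == "degree-categories" else label
        method = "spearman" if label == "degree-categories" else None
        for d, ps in pairsets.items():
            try:
                mc = correlate_pairs(forest, ps, attribute, method, transform)
            except (ValueError, KeyError):
                continue
            rows.append(
                {
                    "attribute": label,
                    "method": mc.method,
                    "transform": transform,
                    "distance": str(d),
                    "estimate": mc.estimate,
                    "ci_low": mc.ci_95[0],
                    "ci_high": mc.ci_95[1],
                    "p_value": mc.p_value,
                    "n_pairs": mc.n_pairs,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recruiter-recruitee matrices and age-direction proportions


def recruiter_recruitee_matrix(
    forest: RDSForest, attribute: str, bins
) -> ContactIntensityMatrix:
    """Counts of distance-1 ordered pairs per (recruiter bin, recruitee bin)."""
    getter, _ = ATTRIBUTES[attribute]
    bins = np.asarray(bins, dtype=float)
    nbin = bins.size - 1
    counts = np.zeros((nbin, nbin), dtype=int)
    for e in forest.edges:
        cells = []
        for pid in (e.recruiter_id, e.recruitee_id):
            v = getter(forest.participants[pid])
            if v < bins[0] or v > bins[-1]:
                raise ValueError(
                    f"record {pid}: {attribute} value {v} outside bins"
                )
            cells.append(min(int(np.searchsorted(bins, v, side="right")) - 1, nbin - 1))
        counts[cells[0], cells[1]] += 1
    total = counts.sum()
    proportions = counts / total if total else counts.astype(float)
    return ContactIntensityMatrix(bins=bins, counts=counts, proportions=proportions)


def age_direction_proportions(
    forest: RDSForest, age_bins=None
) -> AgeDirectionMatrix:
    """Per age-group shares of contacts younger / same age / older.

    Aggregates the reported younger/same/older tallies over participants in
    each age group, separately for the locations and eating contexts.
    """
    if age_bins is None:
        age_bins = np.arange(10, 85, 5)
    age_bins = np.asarray(age_bins)
    rows = []
    for lo, hi in zip(age_bins[:-1], age_bins[1:]):
        members = [
            r for r in forest.participants.values() if lo <= r.age < hi
        ]
        for context in ("locations", "eating"):
            tallies = np.array(
                [r.age_direction_tallies.get(context, (0, 0, 0)) for r in members]
            ).reshape(-1, 3)
            total = tallies.sum()
            props = tallies.sum(axis=0) / total if total else np.full(3, np.nan)
            rows.append(
                {
                    "age_group": f"{lo}-{hi - 1}",
                    "context": context,
                    "younger": props[0],
                    "same": props[1],
                    "older": props[2],
                    "n_contacts": int(total),
                }
            )
    return AgeDirectionMatrix(pd.DataFrame(rows))
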