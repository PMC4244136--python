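"""First-order Markov check on recruitment chains.

If a recruitee's attributes depend only on the direct recruiter, multi-step
correlations factorize: for a numeric attribute the seed-to-wave-3
correlation should match the product of the three stepwise correlations,
and for a binary attribute the phi coefficient implied by the cube of the
one-step transition matrix should match the directly observed one.  A direct
estimate systematically above the factorized prediction indicates a
higher-order (longer-memory) recruitment process.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_model import RDSForest
from .mixing import ATTRIBUTES, PairSet, correlate_pairs

_ROW_TOL = 1e-12


class InsufficientDepthError(ValueError):
    """The forest has no chains reaching the requested wave."""


@dataclass
class TransitionMatrix:
    states: tuple
    P: np.ndarray  # row-stochastic: recruitee state given recruiter state
    marginal: np.ndarray  # state distribution among seeds (wave 0)

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.marginal = np.asarray(self.marginal, dtype=float)
        if (self.P < 0).any() or np.abs(self.P.sum(axis=1) - 1).max() > _ROW_TOL:
            raise ValueError("P must be row-stochastic")
        if abs(self.marginal.sum() - 1) > _ROW_TOL:
            raise ValueError("marginal must sum to 1")


@dataclass
class MarkovCheckResult:
    attribute: str
    r_direct: float
    r_predicted: float
    per_step: dict[str, float]
    n_per_step: dict[str, int]
    n_direct: int


def _step_pairset(forest: RDSForest, wave: int) -> PairSet:
    pairs = [
        (e.recruiter_id, e.recruitee_id)
        for e in forest.edges
        if forest.wave[e.recruiter_id] == wave
    ]
    return PairSet(distance_label=1, pairs=pairs, mode="lineal-only")


def stepwise_correlations(
    forest: RDSForest, attribute: str, max_wave: int = 3
) -> tuple[dict[str, float], dict[str, int]]:
    """Recruiter-recruitee correlation for each wave step w -> w+1.

    Ordered pairs (recruiter value vs recruitee value), not symmetrized,
    matching a seed-to-descendant reading of the chains.  Steps with no
    pairs are reported as missing (NaN).
    """
    estimates: dict[str, float] = {}
    counts: dict[str, int] = {}
    for w in range(max_wave):
        label = f"{w}-{w + 1}"
        ps = _step_pairset(forest, w)
        try:
            mc = correlate_pairs(forest, ps, attribute, symmetrize=False)
            estimates[label] = mc.estimate
            counts[label] = mc.n_pairs
        except ValueError:
            estimates[label] = float("nan")
            counts[label] = len(ps.pairs)
    return estimates, counts


def _lineal_pairs_at_depth(forest: RDSForest, depth: int) -> list[tuple[str, str]]:
    """(wave-0 ancestor, wave-``depth`` descendant) pairs along chains."""
    pairs = []
    for pid, rec in forest.participants.items():
        if forest.wave[pid] != depth:
            continue
        anc = pid
        for _ in range(depth):
            anc = forest.parent[anc]
        pairs.append((anc, pid))
    return pairs


def markov_check_numeric(
    forest: RDSForest, attribute: str = "age", max_wave: int = 3
) -> MarkovCheckResult:
    """Compare the direct 0->3 correlation with the stepwise product.

    ``r_direct`` is computed over (seed, wave-3 descendant) lineal pairs;
    ``r_predicted`` is the product of the three one-step estimates.  Both
    are reported without an automatic verdict.
    """
    direct_pairs = _lineal_pairs_at_depth(forest, max_wave)
    if not direct_pairs:
        raise InsufficientDepthError(
            f"no lineal pairs spanning waves 0-{max_wave}"
        )
    if len(direct_pairs) < 20:
        warnings.warn(
            f"only {len(direct_pairs)} wave-0 to wave-{max_wave} pairs; "
            "estimates will be noisy",
            stacklevel=2,
        )
    ps = PairSet(distance_label=max_wave, pairs=direct_pairs, mode="lineal-only")
    direct = correlate_pairs(forest, ps, attribute, symmetrize=False)
    per_step, n_per_step = stepwise_correlations(forest, attribute, max_wave)
    predicted = float(np.prod(list(per_step.values())))
    return MarkovCheckResult(
        attribute=attribute,
        r_direct=direct.estimate,
        r_predicted=predicted,
        per_step=per_step,
        n_per_step=n_per_step,
        n_direct=direct.n_pairs,
    )


def estimate_transition_matrix(forest: RDSForest, attribute: str) -> TransitionMatrix:
    """Row-normalized recruiter-state -> recruitee-state counts.

    The marginal is the state distribution among wave-0 participants.
    A state that never appears as a recruiter yields an empty row, which is
    left uniform with a warning.
    """
    getter, _ = ATTRIBUTES[attribute]
    values = {pid: getter(rec) for pid, rec in forest.participants.items()}
    states = tuple(sorted(set(values.values())))
    if len(states) < 2:
        raise ValueError(f"attribute {attribute!r} has a single observed state")
    index = {s: i for i, s in enumerate(states)}
    counts = np.zeros((len(states), len(states)))
    for e in forest.edges:
        counts[index[values[e.recruiter_id]], index[values[e.recruitee_id]]] += 1
    row_sums = counts.sum(axis=1)
    P = np.empty_like(counts)
    for i, total in enumerate(row_sums):
        if total == 0:
            warnings.warn(
                f"state {states[i]!r} never recruits; row left uniform",
                stacklevel=2,
            )
            P[i] = 1.0 / len(states)
        else:
            P[i] = counts[i] / total
    seeds = [pid for pid in forest.participants if forest.wave[pid] == 0]
    marginal = np.zeros(len(states))
    for pid in seeds:
        marginal[index[values[pid]]] += 1
    marginal /= marginal.sum()
    return TransitionMatrix(states=states, P=P, marginal=marginal)


def matrix_power_phi(tm: TransitionMatrix, power: int) -> float:
    """Phi coefficient of the joint table diag(marginal) . P**power.

    Defined for two states only.  For the symmetric two-state chain with
    stay probability q and uniform marginal this equals (2q - 1)**power.
    """
    if len(tm.states) != 2:
        raise ValueError("phi is defined for 2 states only")
    if power < 1:
        raise ValueError("power must be >= 1")
    joint = np.diag(tm.marginal) @ np.linalg.matrix_power(tm.P, power)
    row = joint.sum(axis=1)
    col = joint.sum(axis=0)
    denom = np.sqrt(row[0] * row[1] * col[0] * col[1])
    if denom == 0:
        raise ValueError("degenerate joint table: a margin is empty")
    return float((joint[0, 0] * joint[1, 1] - joint[0, 1] * joint[1, 0]) / denom)


def markov_check_categorical(
    forest: RDSForest, attribute: str = "sex", max_wave: int = 3
) -> MarkovCheckResult:
    """Binary-attribute analogue: observed 0->3 phi vs the P**3 prediction."""
    direct_pairs = _lineal_pairs_at_depth(forest, max_wave)
    if not direct_pairs:
        raise InsufficientDepthError(f"no lineal pairs spanning waves 0-{max_wave}")
    ps = PairSet(distance_label=max_wave, pairs=direct_pairs, mode="lineal-only")
    direct = correlate_pairs(forest, ps, attribute, method="phi", symmetrize=False)
    tm = estimate_transition_matrix(forest, attribute)
    predicted = matrix_power_phi(tm, max_wave)
    per_step, n_per_step = stepwise_correlations(forest, attribute, max_wave)
    return MarkovCheckResult(
        attribute=attribute,
        r_direct=direct.estimate,
        r_predicted=predicted,
        per_step=per_step,
        n_per_step=n_per_step,
        n_direct=direct.n_pairs,
    )
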