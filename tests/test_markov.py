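import numpy as np
import pytest

from rdscontacts import (
    GeneratorConfig,
    estimate_transition_matrix,
    generate_forest,
    make_profile,
    markov_check_numeric,
    matrix_power_phi,
    stepwise_correlations,
)
from rdscontacts.io_model import RDSForest, RecruitmentEdge
from rdscontacts.markov import InsufficientDepthError, TransitionMatrix
from rdscontacts.synthetic import Homophily

from conftest import make_record


def _ar1_forest(rho: float, n_chains: int, seed: int, scale: float = 10.0) -> RDSForest:
    """Forest of single-child chains with a stationary AR(1) age process.

    Ages are rounded to integers around 40 +- ``scale`` * AR(1); the
    rounding noise is negligible relative to the process variance.
    """
    rng = np.random.default_rng(seed)
    records, edges = [], []
    for c in range(n_chains):
        x = rng.normal()
        prev_id = None
        for w in range(4):
            pid = f"c{c}w{w}"
            records.append(make_record(pid, age=int(round(40 + scale * x))))
            if prev_id is not None:
                edges.append(RecruitmentEdge(prev_id, pid))
            prev_id = pid
            x = rho * x + np.sqrt(1 - rho**2) * rng.normal()
    return RDSForest(records, edges)


def test_stepwise_perfect_homophily_chains():
    profile = make_profile(
        "NL-like",
        complete_prob=1.0,
        homophily=Homophily(
            age_sd=0.0,
            sex_stay_prob=1.0,
            education_transition=tuple(
                tuple(float(i == j) for j in range(3)) for i in range(3)
            ),
        ),
    )
    forest = generate_forest(profile, GeneratorConfig(n_seeds=60, max_waves=3,
                                                      rng_seed=2))
    estimates, counts = stepwise_correlations(forest, "age")
    for label, r in estimates.items():
        if counts[label] >= 2 and not np.isnan(r):
            assert r == pytest.approx(1.0, abs=1e-9)


def test_stepwise_equals_manual_wave_correlation(nl_forest):
    estimates, counts = stepwise_correlations(nl_forest, "age")
    pairs = [
        (e.recruiter_id, e.recruitee_id)
        for e in nl_forest.edges
        if nl_forest.wave[e.recruiter_id] == 0
        and nl_forest.participants[e.recruiter_id].complete
        and nl_forest.participants[e.recruitee_id].complete
    ]
    x = np.array([nl_forest.participants[u].age for u, v in pairs], dtype=float)
    y = np.array([nl_forest.participants[v].age for u, v in pairs], dtype=float)
    assert estimates["0-1"] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)
    assert counts["0-1"] == len(pairs)


def test_ar1_direct_matches_product_and_closed_form():
    rho = 0.6
    forest = _ar1_forest(rho, n_chains=3000, seed=10)
    res = markov_check_numeric(forest, "age")
    assert res.n_direct == 3000
    assert res.r_direct == pytest.approx(rho**3, abs=0.05)
    assert abs(res.r_direct - res.r_predicted) < 0.05


def test_independent_chain_correlations_near_zero():
    forest = _ar1_forest(0.0, n_chains=1500, seed=11)
    res = markov_check_numeric(forest, "age")
    assert abs(res.r_direct) < 0.06
    assert abs(res.r_predicted) < 0.06


def test_insufficient_depth_raises(star_forest):
    with pytest.raises(InsufficientDepthError):
        markov_check_numeric(star_forest, "age")


# ------------------------------------------------------ transition matrix


def test_transition_identity_under_perfect_homophily():
    records = [
        make_record("A", sex="female"),
        make_record("B", sex="female"),
        make_record("C", sex="male"),
        make_record("D", sex="male"),
    ]
    forest = RDSForest(records, [RecruitmentEdge("A", "B"), RecruitmentEdge("C", "D")])
    tm = estimate_transition_matrix(forest, "sex")
    assert np.allclose(tm.P, np.eye(2))
    assert np.allclose(tm.P.sum(axis=1), 1.0)


def test_transition_recovers_stay_probability():
    q = 0.7
    profile = make_profile(
        "NL-like",
        complete_prob=1.0,
        homophily=Homophily(
            age_sd=8.0,
            sex_stay_prob=q,
            education_transition=make_profile("NL-like").homophily.education_transition,
        ),
        seed_female_prob=0.5,
    )
    forest = generate_forest(
        profile, GeneratorConfig(n_seeds=900, max_waves=4, rng_seed=19)
    )
    tm = estimate_transition_matrix(forest, "sex")
    assert tm.P[0, 0] == pytest.approx(q, abs=0.03)
    assert tm.P[1, 1] == pytest.approx(q, abs=0.03)


def test_empty_row_left_uniform_with_warning():
    records = [
        make_record("A", sex="female"),
        make_record("B", sex="male"),
    ]
    forest = RDSForest(records, [RecruitmentEdge("A", "B")])
    with pytest.warns(UserWarning, match="never recruits"):
        tm = estimate_transition_matrix(forest, "sex")
    # state 0 (male) never appears as recruiter -> uniform row
    assert np.allclose(tm.P[0], [0.5, 0.5])


# ------------------------------------------------------------ matrix power


def test_phi_of_identity_and_uniform():
    tm = TransitionMatrix(states=(0.0, 1.0), P=np.eye(2), marginal=np.array([0.4, 0.6]))
    assert matrix_power_phi(tm, 5) == pytest.approx(1.0)
    tm = TransitionMatrix(
        states=(0.0, 1.0), P=np.full((2, 2), 0.5), marginal=np.array([0.5, 0.5])
    )
    assert matrix_power_phi(tm, 3) == pytest.approx(0.0, abs=1e-15)


@pytest.mark.parametrize("q", [0.6, 0.75, 0.9])
def test_symmetric_chain_closed_form(q):
    tm = TransitionMatrix(
        states=(0.0, 1.0),
        P=np.array([[q, 1 - q], [1 - q, q]]),
        marginal=np.array([0.5, 0.5]),
    )
    assert matrix_power_phi(tm, 3) == pytest.approx((2 * q - 1) ** 3, rel=1e-12)
    assert matrix_power_phi(tm, 1) == pytest.approx(2 * q - 1, rel=1e-12)


def test_matrix_powers_remain_row_stochastic():
    rng = np.random.default_rng(23)
    P = rng.dirichlet(np.ones(2), size=2)
    for p in (1, 2, 3, 7, 20):
        Pp = np.linalg.matrix_power(P, p)
        assert np.abs(Pp.sum(axis=1) - 1).max() < 1e-10


def test_more_than_two_states_rejected():
    tm = TransitionMatrix.__new__(TransitionMatrix)
    tm.states = (1.0, 2.0, 3.0)
    tm.P = np.full((3, 3), 1 / 3)
    tm.marginal = np.full(3, 1 / 3)
    with pytest.raises(ValueError, match="2 states"):
        matrix_power_phi(tm, 3)
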