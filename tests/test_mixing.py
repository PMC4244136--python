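import itertools

import networkx as nx
import numpy as np
import pytest

from rdscontacts import (
    GeneratorConfig,
    age_direction_proportions,
    correlate_pairs,
    generate_forest,
    make_profile,
    mixing_table,
    pairs_at_distance,
    recruiter_recruitee_matrix,
)
from rdscontacts.io_model import RDSForest, RecruitmentEdge
from rdscontacts.mixing import UndefinedCorrelationError, tree_distances
from rdscontacts.synthetic import Homophily, Recruitment, _homophilous_rows

from conftest import make_record


# ----------------------------------------------------------- pair sets


def test_chain_pairs_by_distance(chain_forest):
    d1 = pairs_at_distance(chain_forest, 1)
    d2 = pairs_at_distance(chain_forest, 2)
    assert d1.pairs == [("A", "B"), ("B", "C")]
    assert d2.pairs == [("A", "C")]


def test_star_sibling_pairs_modes(star_forest):
    all_d2 = pairs_at_distance(star_forest, 2, mode="all-pairs")
    assert len(all_d2.pairs) == 3  # the three sibling pairs
    lineal_d2 = pairs_at_distance(star_forest, 2, mode="lineal-only")
    assert lineal_d2.pairs == []
    assert len(pairs_at_distance(star_forest, 1).pairs) == len(star_forest.edges)


def _bfs_oracle_pairs(forest, d):
    g = nx.Graph()
    g.add_nodes_from(forest.participants)
    g.add_edges_from((e.recruiter_id, e.recruitee_id) for e in forest.edges)
    out = set()
    for u, lengths in nx.all_pairs_shortest_path_length(g):
        for v, dist in lengths.items():
            if u < v and (dist == d if d != "4+" else dist >= 4):
                out.add((u, v))
    return out


@pytest.mark.parametrize("d", [1, 2, 3, "4+"])
def test_pairs_match_bfs_oracle(nl_forest, d):
    ours = set(pairs_at_distance(nl_forest, d).pairs)
    assert ours == _bfs_oracle_pairs(nl_forest, d)


def test_pairs_d1_equals_edge_count(nl_forest):
    assert len(pairs_at_distance(nl_forest, 1).pairs) == len(nl_forest.edges)


def test_distances_invariant_to_relabelling(chain_forest):
    relabel = {"A": "zz", "B": "mm", "C": "aa"}
    records = [
        make_record(relabel[p.id], age=p.age) for p in chain_forest.participants.values()
    ]
    edges = [
        RecruitmentEdge(relabel[e.recruiter_id], relabel[e.recruitee_id])
        for e in chain_forest.edges
    ]
    relabelled = RDSForest(records, edges)
    dist = tree_distances(relabelled)
    assert dist[("aa", "zz")] == 2
    assert dist[("mm", "zz")] == 1


# -------------------------------------------------------- correlations


def test_phi_identical_within_pairs():
    records = [
        make_record("A", sex="female"),
        make_record("B", sex="female"),
        make_record("C", sex="male"),
        make_record("D", sex="male"),
    ]
    edges = [RecruitmentEdge("A", "B"), RecruitmentEdge("C", "D")]
    forest = RDSForest(records, edges)
    ps = pairs_at_distance(forest, 1)
    assert correlate_pairs(forest, ps, "sex").estimate == pytest.approx(1.0)


def test_phi_equals_pearson_on_binary_coding(nl_forest):
    ps = pairs_at_distance(nl_forest, 1)
    phi = correlate_pairs(nl_forest, ps, "sex", method="phi")
    pearson = correlate_pairs(nl_forest, ps, "sex", method="pearson")
    assert phi.estimate == pytest.approx(pearson.estimate, abs=1e-12)


def test_zero_variance_raises():
    records = [make_record(p, age=30) for p in "ABCD"]
    forest = RDSForest(records, [RecruitmentEdge("A", "B"), RecruitmentEdge("C", "D")])
    ps = pairs_at_distance(forest, 1)
    with pytest.raises(UndefinedCorrelationError):
        correlate_pairs(forest, ps, "age")


def test_estimate_invariant_to_pair_order(nl_forest):
    ps = pairs_at_distance(nl_forest, 1)
    mc1 = correlate_pairs(nl_forest, ps, "age")
    ps.pairs = list(reversed(ps.pairs))
    mc2 = correlate_pairs(nl_forest, ps, "age")
    assert mc1.estimate == pytest.approx(mc2.estimate, abs=1e-12)


def test_age_correlation_decreases_with_kernel_width():
    estimates = []
    for age_sd in (2.0, 8.0, 20.0):
        profile = make_profile(
            "NL-like",
            complete_prob=1.0,
            homophily=Homophily(
                age_sd=age_sd,
                sex_stay_prob=0.645,
                education_transition=_homophilous_rows((0.059, 0.042, 0.899), 0.15),
            ),
        )
        forest = generate_forest(
            profile, GeneratorConfig(n_seeds=400, max_waves=4, rng_seed=13)
        )
        ps = pairs_at_distance(forest, 1)
        estimates.append(correlate_pairs(forest, ps, "age").estimate)
    assert estimates[0] > estimates[1] > estimates[2]


def test_correlation_decay_with_distance():
    """On first-order forests the distance-d correlation tracks rho**d."""
    profile = make_profile(
        "NL-like",
        complete_prob=1.0,
        recruitment=Recruitment(invite_intercept=5.0, invite_coef_degree=0.0,
                                invite_coef_female=0.0, success_prob=0.40),
    )
    forest = generate_forest(
        profile, GeneratorConfig(n_seeds=500, max_waves=4, rng_seed=17)
    )
    ps1 = pairs_at_distance(forest, 1, mode="lineal-only")
    ps2 = pairs_at_distance(forest, 2, mode="lineal-only")
    assert len(ps2.pairs) >= 2000
    r1 = correlate_pairs(forest, ps1, "sex").estimate
    r2 = correlate_pairs(forest, ps2, "sex").estimate
    assert r2 == pytest.approx(r1**2, abs=0.06)


def test_cluster_bootstrap_ci_contains_estimate_and_is_wider(nl_forest):
    ps = pairs_at_distance(nl_forest, 1)
    fisher = correlate_pairs(nl_forest, ps, "age")
    boot = correlate_pairs(
        nl_forest, ps, "age", ci_method="cluster-bootstrap", n_boot=200, rng=0
    )
    assert boot.estimate == fisher.estimate
    assert boot.ci_95[0] < boot.estimate < boot.ci_95[1]
    # tree resampling acknowledges within-tree dependence -> no narrower
    assert (boot.ci_95[1] - boot.ci_95[0]) >= 0.8 * (
        fisher.ci_95[1] - fisher.ci_95[0]
    )


def test_mixing_table_layout(nl_forest):
    table = mixing_table(nl_forest)
    assert set(table["distance"]) <= {"1", "2", "3", "4+"}
    assert ((table["estimate"] >= -1) & (table["estimate"] <= 1)).all()
    assert (table["ci_low"] <= table["estimate"]).all()
    assert (table["estimate"] <= table["ci_high"]).all()


# ------------------------------------------------- matrices / directions


def test_recruiter_recruitee_matrix_hand_count():
    records = [
        make_record("A", age=20),
        make_record("B", age=22),
        make_record("C", age=41),
        make_record("D", age=20),
        make_record("E", age=60),
    ]
    edges = [
        RecruitmentEdge("A", "B"),
        RecruitmentEdge("A", "C"),
        RecruitmentEdge("C", "E"),
        RecruitmentEdge("B", "D"),
    ]
    forest = RDSForest(records, edges)
    m = recruiter_recruitee_matrix(forest, "age", bins=[10, 30, 50, 70])
    assert m.counts.tolist() == [[2, 1, 0], [0, 0, 1], [0, 0, 0]]
    assert m.proportions.sum() == pytest.approx(1.0)


def test_matrix_value_outside_bins_names_record(star_forest):
    with pytest.raises(ValueError, match="record"):
        recruiter_recruitee_matrix(star_forest, "age", bins=[0, 10, 20])


def test_matrix_diagonal_under_perfect_homophily():
    records = [make_record(p, age=25) for p in "AB"] + [
        make_record(p, age=45) for p in "CD"
    ]
    forest = RDSForest(records, [RecruitmentEdge("A", "B"), RecruitmentEdge("C", "D")])
    m = recruiter_recruitee_matrix(forest, "age", bins=[20, 30, 40, 50])
    off_diag = m.counts.sum() - np.trace(m.counts)
    assert off_diag == 0


def test_age_direction_rows():
    rec = make_record(
        "A",
        age=22,
        location_counts={"workplace": 10},
        eating_count=4,
        age_direction_tallies={"locations": (0, 10, 0), "eating": (1, 2, 1)},
    )
    forest = RDSForest([rec], [])
    adm = age_direction_proportions(forest)
    row = adm.table[
        (adm.table["age_group"] == "20-24") & (adm.table["context"] == "locations")
    ].iloc[0]
    assert (row["younger"], row["same"], row["older"]) == (0.0, 1.0, 0.0)
    eat = adm.table[
        (adm.table["age_group"] == "20-24") & (adm.table["context"] == "eating")
    ].iloc[0]
    assert eat["younger"] + eat["same"] + eat["older"] == pytest.approx(1.0)


def test_age_direction_matches_aggregation_oracle(nl_forest):
    adm = age_direction_proportions(nl_forest, age_bins=[10, 40, 80])
    members = [
        r for r in nl_forest.participants.values() if 10 <= r.age < 40
    ]
    tallies = np.array([r.age_direction_tallies["locations"] for r in members])
    expected = tallies.sum(axis=0) / tallies.sum()
    row = adm.table[
        (adm.table["age_group"] == "10-39") & (adm.table["context"] == "locations")
    ].iloc[0]
    assert row["younger"] == pytest.approx(expected[0])
    assert row["same"] == pytest.approx(expected[1])
    assert row["older"] == pytest.approx(expected[2])
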