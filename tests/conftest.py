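import pytest

from rdscontacts import GeneratorConfig, generate_forest, make_profile
from rdscontacts.io_model import ParticipantRecord, RDSForest, RecruitmentEdge


def make_record(pid: str, **kwargs) -> ParticipantRecord:
    defaults = dict(
        country="NL",
        age=30,
        sex="female",
        education=3,
        household_size=2,
        location_counts={"workplace": 5},
        transport_counts={"bus-tram": 2},
        eating_count=3,
    )
    defaults.update(kwargs)
    return ParticipantRecord(id=pid, **defaults)


@pytest.fixture
def chain_forest():
    """Single chain A -> B -> C."""
    records = [make_record(p) for p in "ABC"]
    edges = [RecruitmentEdge("A", "B"), RecruitmentEdge("B", "C")]
    return RDSForest(records, edges)


@pytest.fixture
def star_forest():
    """One seed S recruiting three participants."""
    records = [make_record(p) for p in ["S", "R1", "R2", "R3"]]
    edges = [RecruitmentEdge("S", r) for r in ["R1", "R2", "R3"]]
    return RDSForest(records, edges)


@pytest.fixture(scope="session")
def nl_forest():
    """Moderate NL-like synthetic forest shared across read-only tests."""
    return generate_forest(
        make_profile("NL-like"),
        GeneratorConfig(n_seeds=80, max_waves=5, rng_seed=42),
    )
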