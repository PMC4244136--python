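"""Data model and plain-text I/O for respondent-driven contact surveys.

A survey dataset consists of a participant table (one row per respondent)
and an edge table (who recruited whom).  Participants plus edges form a
*recruitment forest*: every node has at most one recruiter, seeds have none,
and a node's wave is its recruiter's wave plus one.

The participant *degree* is the number of contact persons reported at
different locations plus the number reported while travelling; contacts
while eating and household members are tallied separately and are not part
of the degree.
"""

from __future__ import annotations

import dataclasses
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from ._util import percent

# Symptom list as offered by the questionnaire.  The first two triples define
# the influenza-like-illness and common-cold-like symptom classes.
ILI_SYMPTOMS = frozenset({"fever", "headache", "muscle pain"})
COLD_SYMPTOMS = frozenset({"runny nose", "sore throat", "cough"})
OTHER_SYMPTOMS = frozenset({"fatigue", "shortness of breath", "diarrhoea"})
KNOWN_SYMPTOMS = ILI_SYMPTOMS | COLD_SYMPTOMS | OTHER_SYMPTOMS

EDUCATION_LEVELS = (1, 2, 3)  # 1: high-school/other, 2: vocational/diploma, 3: higher
SEX_CATEGORIES = ("female", "male")
RECRUITMENT_METHODS = ("facebook", "indirect-email", "direct-email", "seed")
WEEKDAYS = ("mon", "tue", "wed", "thu", "fri", "sat", "sun")
MAX_RECRUITEES = 4
DEFAULT_MAX_DEGREE = 2200


class ValidationError(ValueError):
    """Base class for dataset validation failures."""


class CycleError(ValidationError):
    """Recruitment edges contain a cycle."""


class MultipleRecruitersError(ValidationError):
    """A participant appears as recruitee in more than one edge."""


class UnknownParticipantError(ValidationError):
    """An edge references an id with no participant row."""


class MalformedValueError(ValidationError):
    """A field could not be parsed or violates a record invariant."""


class UnknownSymptomError(ValidationError):
    """A symptom token is not in the questionnaire list."""


class TooManyRecruiteesError(ValidationError):
    """A participant recruited more than four recruitees."""


@dataclass
class ParticipantRecord:
    """One survey respondent."""

    id: str
    country: str
    age: int
    sex: str
    education: int
    household_size: int
    location_counts: dict[str, int] = field(default_factory=dict)
    transport_counts: dict[str, int] = field(default_factory=dict)
    eating_count: int = 0
    age_direction_tallies: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    symptoms: frozenset[str] = frozenset()
    household_symptomatic: int | None = None
    recording_day: str = "mon"
    recruitment_method: str = "seed"
    requested_invitations: bool = False
    complete: bool = True
    wave: int = 0

    def validate(self) -> None:
        if self.age < 0:
            raise MalformedValueError(f"record {self.id}: negative age")
        if self.sex not in SEX_CATEGORIES:
            raise MalformedValueError(f"record {self.id}: unknown sex {self.sex!r}")
        if self.education not in EDUCATION_LEVELS:
            raise MalformedValueError(
                f"record {self.id}: education must be one of {EDUCATION_LEVELS}"
            )
        if self.household_size < 1:
            raise MalformedValueError(f"record {self.id}: household_size must be >= 1")
        for name, counts in (
            ("location", self.location_counts),
            ("transport", self.transport_counts),
        ):
            for key, v in counts.items():
                if v < 0:
                    raise MalformedValueError(
                        f"record {self.id}: negative {name} count for {key!r}"
                    )
        if self.eating_count < 0:
            raise MalformedValueError(f"record {self.id}: negative eating_count")
        unknown = self.symptoms - KNOWN_SYMPTOMS
        if unknown:
            raise UnknownSymptomError(
                f"record {self.id}: unknown symptom(s) {sorted(unknown)}"
            )
        for context, tallies in self.age_direction_tallies.items():
            if len(tallies) != 3 or any(t < 0 for t in tallies):
                raise MalformedValueError(
                    f"record {self.id}: malformed age-direction tallies for {context!r}"
                )
            total = (
                sum(self.location_counts.values())
                if context == "locations"
                else self.eating_count
            )
            if sum(tallies) > total:
                raise MalformedValueError(
                    f"record {self.id}: age-direction tallies exceed the "
                    f"{context} contact total"
                )
        if self.recruitment_method not in RECRUITMENT_METHODS:
            raise MalformedValueError(
                f"record {self.id}: unknown recruitment method "
                f"{self.recruitment_method!r}"
            )


@dataclass(frozen=True)
class RecruitmentEdge:
    recruiter_id: str
    recruitee_id: str

    def __post_init__(self) -> None:
        if self.recruiter_id == self.recruitee_id:
            raise MalformedValueError(
                f"edge {self.recruiter_id}->{self.recruitee_id}: self recruitment"
            )


def compute_degree(record: ParticipantRecord) -> int:
    """Total contact persons at locations plus while travelling.

    Eating contacts and household members are deliberately excluded.
    """
    return sum(record.location_counts.values()) + sum(record.transport_counts.values())


def classify_symptoms(record: ParticipantRecord) -> str:
    """Classify a respondent's reported symptoms.

    Returns ``"ILI"`` when fever, headache and muscle pain are all present,
    ``"common_cold"`` for runny nose, sore throat and cough, ``"both"`` when
    both triples are complete, else ``"neither"``.
    """
    unknown = record.symptoms - KNOWN_SYMPTOMS
    if unknown:
        raise UnknownSymptomError(
            f"record {record.id}: unknown symptom(s) {sorted(unknown)}"
        )
    ili = ILI_SYMPTOMS <= record.symptoms
    cold = COLD_SYMPTOMS <= record.symptoms
    if ili and cold:
        return "both"
    if ili:
        return "ILI"
    if cold:
        return "common_cold"
    return "neither"


class RDSForest:
    """Participants plus recruitment edges, validated as a forest.

    Waves and tree membership are derived by breadth-first traversal from the
    seeds (nodes with no recruiter); each record's ``wave`` field is set to
    the derived value.
    """

    def __init__(
        self,
        participants: Iterable[ParticipantRecord],
        edges: Iterable[RecruitmentEdge],
    ) -> None:
        self.participants: dict[str, ParticipantRecord] = {}
        for rec in participants:
            if rec.id in self.participants:
                raise MalformedValueError(f"duplicate participant id {rec.id!r}")
            rec.validate()
            self.participants[rec.id] = rec
        self.edges: list[RecruitmentEdge] = []
        self.parent: dict[str, str] = {}
        self.children: dict[str, list[str]] = {pid: [] for pid in self.participants}
        for e in edges:
            for pid in (e.recruiter_id, e.recruitee_id):
                if pid not in self.participants:
                    raise UnknownParticipantError(
                        f"edge {e.recruiter_id}->{e.recruitee_id} references "
                        f"unknown participant {pid!r}"
                    )
            if e.recruitee_id in self.parent:
                raise MultipleRecruitersError(
                    f"participant {e.recruitee_id!r} has more than one recruiter"
                )
            self.parent[e.recruitee_id] = e.recruiter_id
            self.children[e.recruiter_id].append(e.recruitee_id)
            self.edges.append(e)
        for pid, kids in self.children.items():
            if len(kids) > MAX_RECRUITEES:
                raise TooManyRecruiteesError(
                    f"participant {pid!r} recruited {len(kids)} > "
                    f"{MAX_RECRUITEES} recruitees"
                )
        self.wave: dict[str, int] = {}
        self.tree_id: dict[str, str] = {}
        self._assign_waves()

    def _assign_waves(self) -> None:
        seeds = [pid for pid in self.participants if pid not in self.parent]
        queue = deque(seeds)
        for s in seeds:
            self.wave[s] = 0
            self.tree_id[s] = s
        while queue:
            pid = queue.popleft()
            for child in self.children[pid]:
                self.wave[child] = self.wave[pid] + 1
                self.tree_id[child] = self.tree_id[pid]
                queue.append(child)
        unreached = set(self.participants) - set(self.wave)
        if unreached:
            raise CycleError(
                f"recruitment edges contain a cycle through {sorted(unreached)[0]!r}"
            )
        for pid, rec in self.participants.items():
            rec.wave = self.wave[pid]

    # -- convenience ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.participants)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RDSForest):
            return NotImplemented
        return self.participants == other.participants and set(self.edges) == set(
            other.edges
        )

    @property
    def seeds(self) -> list[str]:
        return [pid for pid in self.participants if pid not in self.parent]

    @property
    def trees(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for pid, root in self.tree_id.items():
            out.setdefault(root, []).append(pid)
        return out

    def records(self, complete_only: bool = False) -> list[ParticipantRecord]:
        recs = list(self.participants.values())
        if complete_only:
            recs = [r for r in recs if r.complete]
        return recs

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for pid, rec in self.participants.items():
            g.add_node(
                pid,
                wave=rec.wave,
                degree=compute_degree(rec),
                age_group=f"{10 * (rec.age // 10)}s",
                sex=rec.sex,
                country=rec.country,
            )
        for e in self.edges:
            g.add_edge(e.recruiter_id, e.recruitee_id)
        return g

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


# ---------------------------------------------------------------------------
# CSV dialect: UTF-8, comma-delimited, one row per participant; map-valued
# fields are semicolon-joined ``key=value`` tokens, set-valued fields are
# semicolon-joined tokens.

PARTICIPANT_COLUMNS = [
    "id",
    "country",
    "wave",
    "age",
    "sex",
    "education",
    "household_size",
    "household_symptomatic",
    "symptoms",
    "recording_day",
    "location_counts",
    "transport_counts",
    "eating_count",
    "loc_younger",
    "loc_same",
    "loc_older",
    "eat_younger",
    "eat_same",
    "eat_older",
    "recruitment_method",
    "requested_invitations",
    "complete",
]
EDGE_COLUMNS = ["recruiter_id", "recruitee_id"]


def _encode_counts(counts: Mapping[str, int]) -> str:
    return ";".join(f"{k}={v}" for k, v in sorted(counts.items()))


def _decode_counts(text: str, rec_id: str, column: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    if not text:
        return counts
    for token in text.split(";"):
        if "=" not in token:
            raise MalformedValueError(
                f"record {rec_id}: malformed token {token!r} in column {column!r}"
            )
        key, _, val = token.partition("=")
        counts[key] = _parse_int(val, rec_id, column)
    return counts


def _parse_int(text: str, rec_id: str, column: str) -> int:
    try:
        return int(text)
    except (TypeError, ValueError):
        raise MalformedValueError(
            f"record {rec_id}: malformed count {text!r} in column {column!r}"
        ) from None


def _parse_bool(text: str, rec_id: str, column: str) -> bool:
    if text in ("true", "True", "1"):
        return True
    if text in ("false", "False", "0"):
        return False
    raise MalformedValueError(
        f"record {rec_id}: malformed boolean {text!r} in column {column!r}"
    )


def record_to_row(rec: ParticipantRecord) -> dict[str, object]:
    loc = rec.age_direction_tallies.get("locations", (0, 0, 0))
    eat = rec.age_direction_tallies.get("eating", (0, 0, 0))
    return {
        "id": rec.id,
        "country": rec.country,
        "wave": rec.wave,
        "age": rec.age,
        "sex": rec.sex,
        "education": rec.education,
        "household_size": rec.household_size,
        "household_symptomatic": (
            "" if rec.household_symptomatic is None else rec.household_symptomatic
        ),
        "symptoms": ";".join(sorted(rec.symptoms)),
        "recording_day": rec.recording_day,
        "location_counts": _encode_counts(rec.location_counts),
        "transport_counts": _encode_counts(rec.transport_counts),
        "eating_count": rec.eating_count,
        "loc_younger": loc[0],
        "loc_same": loc[1],
        "loc_older": loc[2],
        "eat_younger": eat[0],
        "eat_same": eat[1],
        "eat_older": eat[2],
        "recruitment_method": rec.recruitment_method,
        "requested_invitations": str(rec.requested_invitations).lower(),
        "complete": str(rec.complete).lower(),
    }


def row_to_record(row: Mapping[str, str]) -> ParticipantRecord:
    rec_id = str(row["id"])
    hh_sym = str(row.get("household_symptomatic", "")).strip()
    symptoms = frozenset(t for t in str(row.get("symptoms", "")).split(";") if t)
    tallies = {
        "locations": (
            _parse_int(row["loc_younger"], rec_id, "loc_younger"),
            _parse_int(row["loc_same"], rec_id, "loc_same"),
            _parse_int(row["loc_older"], rec_id, "loc_older"),
        ),
        "eating": (
            _parse_int(row["eat_younger"], rec_id, "eat_younger"),
            _parse_int(row["eat_same"], rec_id, "eat_same"),
            _parse_int(row["eat_older"], rec_id, "eat_older"),
        ),
    }
    return ParticipantRecord(
        id=rec_id,
        country=str(row["country"]),
        age=_parse_int(row["age"], rec_id, "age"),
        sex=str(row["sex"]),
        education=_parse_int(row["education"], rec_id, "education"),
        household_size=_parse_int(row["household_size"], rec_id, "household_size"),
        household_symptomatic=(
            None if hh_sym == "" else _parse_int(hh_sym, rec_id, "household_symptomatic")
        ),
        symptoms=symptoms,
        recording_day=str(row.get("recording_day", "mon")),
        location_counts=_decode_counts(
            str(row.get("location_counts", "")), rec_id, "location_counts"
        ),
        transport_counts=_decode_counts(
            str(row.get("transport_counts", "")), rec_id, "transport_counts"
        ),
        eating_count=_parse_int(row["eating_count"], rec_id, "eating_count"),
        age_direction_tallies=tallies,
        recruitment_method=str(row.get("recruitment_method", "seed")),
        requested_invitations=_parse_bool(
            str(row.get("requested_invitations", "false")),
            rec_id,
            "requested_invitations",
        ),
        complete=_parse_bool(str(row.get("complete", "true")), rec_id, "complete"),
    )


def load_survey(participant_table, edge_table) -> RDSForest:
    """Read participants.csv / edges.csv and return a validated forest."""
    pdf = pd.read_csv(participant_table, dtype=str, keep_default_na=False)
    missing = {"id", "country", "age", "sex"} - set(pdf.columns)
    if missing:
        raise MalformedValueError(
            f"participant table is missing required columns {sorted(missing)}"
        )
    records = [row_to_record(row) for row in pdf.to_dict("records")]
    edf = pd.read_csv(edge_table, dtype=str, keep_default_na=False)
    missing = set(EDGE_COLUMNS) - set(edf.columns)
    if missing:
        raise MalformedValueError(
            f"edge table is missing required columns {sorted(missing)}"
        )
    edges = [
        RecruitmentEdge(row["recruiter_id"], row["recruitee_id"])
        for row in edf.to_dict("records")
    ]
    return RDSForest(records, edges)


def write_survey(forest: RDSForest, participant_table, edge_table) -> None:
    """Write the forest back out in the same dialect ``load_survey`` reads."""
    pdf = pd.DataFrame(
        [record_to_row(rec) for rec in forest.participants.values()],
        columns=PARTICIPANT_COLUMNS,
    )
    pdf.to_csv(participant_table, index=False)
    edf = pd.DataFrame(
        [(e.recruiter_id, e.recruitee_id) for e in forest.edges],
        columns=EDGE_COLUMNS,
    )
    edf.to_csv(edge_table, index=False)


def filter_records(
    forest: RDSForest,
    max_degree: int = DEFAULT_MAX_DEGREE,
    require_complete: bool = False,
    drop_subtrees: bool = False,
) -> RDSForest:
    """Drop implausible high-degree reports (and optionally incomplete rows).

    Participants with degree above ``max_degree`` are removed, together with
    their incident edges.  Children of a removed node are promoted to seeds
    (wave 0) so that pair distances within surviving subtrees are preserved;
    with ``drop_subtrees=True`` the whole subtree below a removed node is
    discarded instead.
    """
    if max_degree <= 0:
        raise ValueError("max_degree must be positive")

    def keep(rec: ParticipantRecord) -> bool:
        if compute_degree(rec) > max_degree:
            return False
        if require_complete and not rec.complete:
            return False
        return True

    removed = {pid for pid, rec in forest.participants.items() if not keep(rec)}
    if drop_subtrees:
        queue = deque(removed)
        while queue:
            pid = queue.popleft()
            for child in forest.children.get(pid, []):
                if child not in removed:
                    removed.add(child)
                    queue.append(child)
    kept_records = [
        dataclasses.replace(rec)
        for pid, rec in forest.participants.items()
        if pid not in removed
    ]
    kept_edges = [
        e
        for e in forest.edges
        if e.recruiter_id not in removed and e.recruitee_id not in removed
    ]
    return RDSForest(kept_records, kept_edges)


@dataclass
class SummaryTable:
    """Per-country participation, recruitment and symptom tabulations."""

    table: pd.DataFrame  # columns: country, item, count, denominator, percentage

    def value(self, country: str, item: str, field: str = "percentage"):
        sel = self.table[
            (self.table["country"] == country) & (self.table["item"] == item)
        ]
        if sel.empty:
            raise KeyError((country, item))
        return sel.iloc[0][field]


def summarize_sample(forest: RDSForest) -> SummaryTable:
    """Participation / recruitment / symptom tabulation, one block per country.

    Percentages are rounded half-up to one decimal.  Counts that have no
    natural denominator (totals, pair counts, maximum wave) carry an empty
    percentage.
    """
    rows: list[dict[str, object]] = []
    recs = list(forest.participants.values())
    for country in sorted({r.country for r in recs}):
        sub = {r.id: r for r in recs if r.country == country}
        n = len(sub)
        seed_ids = [pid for pid in sub if pid not in forest.parent]
        edges = [
            e for e in forest.edges if e.recruiter_id in sub and e.recruitee_id in sub
        ]
        pairs_complete = sum(
            1
            for e in edges
            if sub[e.recruiter_id].complete and sub[e.recruitee_id].complete
        )
        recruiting = {e.recruiter_id for e in edges}
        trees = {}
        for pid in sub:
            trees.setdefault(forest.tree_id[pid], []).append(pid)
        max_wave = max((sub[pid].wave for pid in sub), default=0)
        deep_trees = sum(
            1
            for members in trees.values()
            if max(sub[m].wave for m in members) >= 2
        )
        non_seed = [sub[pid] for pid in sub if pid in forest.parent]
        classes = {pid: classify_symptoms(rec) for pid, rec in sub.items()}

        def add(item: str, count: int, denominator: int | None) -> None:
            rows.append(
                {
                    "country": country,
                    "item": item,
                    "count": count,
                    "denominator": denominator,
                    "percentage": (
                        percent(count, denominator) if denominator else None
                    ),
                }
            )

        add("total_participants", n, None)
        add("complete_responses", sum(r.complete for r in sub.values()), n)
        add("seeds", len(seed_ids), None)
        add(
            "seeds_complete",
            sum(sub[pid].complete for pid in seed_ids),
            len(seed_ids) or None,
        )
        add(
            "seeds_recruited_one_or_more",
            sum(1 for pid in seed_ids if pid in recruiting),
            len(seed_ids) or None,
        )
        add("recruiter_recruitee_pairs", pairs_complete, None)
        add("max_wave", max_wave, None)
        add("trees_with_two_or_more_waves", deep_trees, len(trees) or None)
        for method in ("facebook", "indirect-email", "direct-email"):
            add(
                f"recruited_by_{method}",
                sum(1 for r in non_seed if r.recruitment_method == method),
                len(non_seed) or None,
            )
        add(
            "two_or_more_symptoms",
            sum(1 for r in sub.values() if len(r.symptoms) >= 2),
            n,
        )
        add("ili_symptoms", sum(1 for c in classes.values() if c in ("ILI", "both")), n)
        add(
            "common_cold_symptoms",
            sum(1 for c in classes.values() if c in ("common_cold", "both")),
            n,
        )
    return SummaryTable(pd.DataFrame(rows))
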