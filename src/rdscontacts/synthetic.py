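"""Synthetic webRDS survey generator.

Emulates the statistical structure the downstream analyses assume: total
degrees are i.i.d. negative binomial with country-specific mean ``mu`` and
dispersion ``k`` (variance ``mu + mu**2 / k``); recruitment forms a forest in
which every participant invites at most four recruitees; and recruitment is
homophilous in age, sex and education with tunable strength and a tunable
Markov order.

Two built-in country profiles mirror the published Dutch and Thai samples:
``NL-like`` (mu = 25.65, k = 1.00) and ``TH-like`` (mu = 58.51, k = 0.83),
with household sizes, symptom prevalences, per-setting contact splits and
recruitment-method shares set from the published tabulations where printed
and from documented defaults otherwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .io_model import (
    COLD_SYMPTOMS,
    ILI_SYMPTOMS,
    OTHER_SYMPTOMS,
    MAX_RECRUITEES,
    ParticipantRecord,
    RDSForest,
    RecruitmentEdge,
    WEEKDAYS,
)

AGE_RANGE = (14, 80)  # observed participant age range across both samples


@dataclass
class Homophily:
    """Strength of assortative recruitment per attribute.

    ``age_sd`` is the standard deviation (years) of the recruitee-age kernel
    centred on the recruiter's age; ``sex_stay_prob`` is the probability the
    recruitee shares the recruiter's sex (0.5 = random, 1 = perfect); and
    ``education_transition`` is the 3x3 row-stochastic matrix of recruitee
    education given recruiter education (levels 1 < 2 < 3).
    """

    age_sd: float
    sex_stay_prob: float
    education_transition: tuple[tuple[float, float, float], ...]

    def validate(self) -> None:
        if not 0.5 <= self.sex_stay_prob <= 1.0:
            raise ValueError("sex_stay_prob must lie in [0.5, 1]")
        if self.age_sd < 0:
            raise ValueError("age_sd must be nonnegative")
        m = np.asarray(self.education_transition, dtype=float)
        if m.shape != (3, 3) or (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0):
            raise ValueError("education_transition must be 3x3 row-stochastic")


@dataclass
class Recruitment:
    """Invitation behaviour: a logistic intent model plus per-invite success.

    The intention to recruit follows
    ``logit p = intercept + coef_degree * degree + coef_female * 1[female]``,
    so the recruitment-model stage has a known signal to recover.  Conditional
    on intending, the number of successful recruitees is binomial
    (``max_invites``, ``success_prob``).
    """

    invite_intercept: float = -0.25
    invite_coef_degree: float = 0.008
    invite_coef_female: float = 0.45
    success_prob: float = 0.30
    max_invites: int = MAX_RECRUITEES

    def invite_probability(self, degree: int, sex: str) -> float:
        eta = (
            self.invite_intercept
            + self.invite_coef_degree * degree
            + self.invite_coef_female * (sex == "female")
        )
        return float(expit(eta))


@dataclass
class CountryProfile:
    """All distributions needed to generate one country's dataset."""

    name: str
    degree_mu: float
    degree_k: float
    # expected shares of the degree across location / transport settings;
    # together they sum to 1
    location_split: dict[str, float]
    transport_split: dict[str, float]
    eating_mu: float
    eating_k: float
    household_dist: dict[int, float]
    # probabilities of symptom classes; the remainder reports no symptoms
    symptom_class_probs: dict[str, float] = field(
        default_factory=lambda: {"ili": 0.02, "cold": 0.07, "both": 0.005,
                                 "two_other": 0.25, "one": 0.15}
    )
    seed_age_mean: float = 26.0
    seed_age_sd: float = 6.0
    seed_female_prob: float = 0.6
    seed_education_dist: tuple[float, float, float] = (0.10, 0.05, 0.85)
    homophily: Homophily = field(
        default_factory=lambda: Homophily(
            age_sd=7.0,
            sex_stay_prob=0.65,
            education_transition=_homophilous_rows((0.10, 0.05, 0.85), 0.3),
        )
    )
    recruitment: Recruitment = field(default_factory=Recruitment)
    recruitment_method_probs: dict[str, float] = field(
        default_factory=lambda: {
            "facebook": 0.3,
            "indirect-email": 0.4,
            "direct-email": 0.3,
        }
    )
    complete_prob: float = 0.9
    household_symptom_prob: float = 0.12
    household_unknown_prob: float = 0.08
    # probability a reported contact is younger / same age / older
    age_direction_probs: tuple[float, float, float] = (0.28, 0.45, 0.27)

    def validate(self) -> None:
        if self.degree_mu <= 0 or self.degree_k <= 0:
            raise ValueError("degree_mu and degree_k must be positive")
        if self.eating_mu <= 0 or self.eating_k <= 0:
            raise ValueError("eating_mu and eating_k must be positive")
        split = sum(self.location_split.values()) + sum(self.transport_split.values())
        if not np.isclose(split, 1.0):
            raise ValueError("location_split + transport_split must sum to 1")
        for name, dist in (
            ("household_dist", list(self.household_dist.values())),
            ("seed_education_dist", list(self.seed_education_dist)),
            ("recruitment_method_probs", list(self.recruitment_method_probs.values())),
            ("age_direction_probs", list(self.age_direction_probs)),
        ):
            arr = np.asarray(dist, dtype=float)
            if (arr < 0).any() or not np.isclose(arr.sum(), 1.0):
                raise ValueError(f"{name} must be a probability vector")
        if sum(self.symptom_class_probs.values()) > 1.0 + 1e-9:
            raise ValueError("symptom class probabilities exceed 1")
        self.homophily.validate()


def _homophilous_rows(
    marginal: tuple[float, float, float], weight: float
) -> tuple[tuple[float, float, float], ...]:
    """Rows ``(1-w) * marginal + w * identity``: w=0 random, w=1 perfect."""
    rows = []
    for i in range(3):
        row = [(1.0 - weight) * m for m in marginal]
        row[i] += weight
        rows.append(tuple(row))
    return tuple(rows)


def make_profile(name: str, **overrides) -> CountryProfile:
    """Built-in country profiles ``"NL-like"`` and ``"TH-like"``.

    Degree parameters are the published negative-binomial fits; setting
    splits reproduce the published per-category contact means (locations vs
    travelling); eating moments, household sizes, symptom shares, seed
    attributes and recruitment-method shares follow the published
    tabulations.  Any field can be overridden by keyword.
    """
    if name == "NL-like":
        profile = CountryProfile(
            name="NL",
            degree_mu=25.65,
            degree_k=1.00,
            # locations mean 21.4 vs travel 4.2 out of 25.6
            location_split={"workplace": 0.40, "school": 0.15, "shops": 0.15,
                            "leisure": 0.10, "other-location": 0.036},
            transport_split={"bus-tram": 0.07, "train": 0.05, "other-transport": 0.044},
            eating_mu=7.3,
            eating_k=0.54,  # matches printed mean 7.3 / variance 106.5
            household_dist={1: 0.22, 2: 0.28, 3: 0.16, 4: 0.15, 5: 0.09,
                            6: 0.05, 7: 0.03, 8: 0.02},
            symptom_class_probs={"ili": 0.019, "cold": 0.074, "both": 0.005,
                                 "two_other": 0.30, "one": 0.15},
            seed_age_mean=26.7,
            seed_age_sd=6.5,
            seed_female_prob=0.62,
            seed_education_dist=(0.059, 0.042, 0.899),
            homophily=Homophily(
                age_sd=8.0,
                sex_stay_prob=0.645,  # phi at distance 1 ~ 2q - 1 = 0.29
                education_transition=_homophilous_rows((0.059, 0.042, 0.899), 0.15),
            ),
            recruitment=Recruitment(success_prob=0.30),
            recruitment_method_probs={"facebook": 0.104, "indirect-email": 0.526,
                                      "direct-email": 0.370},
            complete_prob=0.899,
        )
    elif name == "TH-like":
        profile = CountryProfile(
            name="TH",
            degree_mu=58.51,
            degree_k=0.83,
            # locations mean 40.9 vs travel 17.6 out of 58.5
            location_split={"workplace": 0.30, "school": 0.17, "shops": 0.13,
                            "leisure": 0.06, "other-location": 0.04},
            transport_split={"bus-tram": 0.15, "train": 0.08, "other-transport": 0.07},
            eating_mu=11.8,
            eating_k=0.65,  # matches printed mean 11.8 / variance 225.0
            household_dist={1: 0.08, 2: 0.17, 3: 0.20, 4: 0.20, 5: 0.15,
                            6: 0.10, 7: 0.06, 8: 0.04},
            symptom_class_probs={"ili": 0.032, "cold": 0.059, "both": 0.005,
                                 "two_other": 0.20, "one": 0.15},
            seed_age_mean=26.2,
            seed_age_sd=6.0,
            seed_female_prob=0.614,
            seed_education_dist=(0.153, 0.008, 0.839),
            homophily=Homophily(
                age_sd=6.0,
                sex_stay_prob=0.60,
                education_transition=_homophilous_rows((0.153, 0.008, 0.839), 0.55),
            ),
            recruitment=Recruitment(success_prob=0.24),
            recruitment_method_probs={"facebook": 0.836, "indirect-email": 0.050,
                                      "direct-email": 0.114},
            complete_prob=0.856,
        )
    else:
        raise ValueError(f"unknown profile {name!r}; expected 'NL-like' or 'TH-like'")
    if overrides:
        profile = dataclasses.replace(profile, **overrides)
    profile.validate()
    return profile


@dataclass
class GeneratorConfig:
    n_seeds: int = 90
    max_waves: int = 6
    markov_order: int = 1
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if self.max_waves < 0:
            raise ValueError("max_waves must be >= 0")
        if self.markov_order not in (1, 2):
            raise ValueError("markov_order must be 1 or 2")


def _negbin(rng: np.random.Generator, mu: float, k: float, size=None):
    return rng.negative_binomial(n=k, p=k / (k + mu), size=size)


def decompose_contacts(
    degree: int, profile: CountryProfile, rng: np.random.Generator
) -> tuple[dict[str, int], dict[str, int], int, dict[str, tuple[int, int, int]]]:
    """Split a total degree over settings and draw the side tallies.

    The degree is distributed multinomially over the location and transport
    types in proportion to the profile's setting split, so location plus
    transport counts always sum back to the degree.  Eating contacts are an
    independent negative-binomial draw, and younger/same/older tallies are
    multinomial over the corresponding totals.
    """
    if degree < 0:
        raise ValueError("degree must be nonnegative")
    loc_types = sorted(profile.location_split)
    tr_types = sorted(profile.transport_split)
    probs = np.array(
        [profile.location_split[t] for t in loc_types]
        + [profile.transport_split[t] for t in tr_types],
        dtype=float,
    )
    counts = rng.multinomial(degree, probs / probs.sum())
    location_counts = dict(zip(loc_types, (int(c) for c in counts[: len(loc_types)])))
    transport_counts = dict(zip(tr_types, (int(c) for c in counts[len(loc_types):])))
    eating_count = int(_negbin(rng, profile.eating_mu, profile.eating_k))
    dirs = np.asarray(profile.age_direction_probs, dtype=float)
    tallies = {
        "locations": tuple(
            int(x) for x in rng.multinomial(sum(location_counts.values()), dirs)
        ),
        "eating": tuple(int(x) for x in rng.multinomial(eating_count, dirs)),
    }
    return location_counts, transport_counts, eating_count, tallies


def _draw_symptoms(profile: CountryProfile, rng: np.random.Generator) -> frozenset[str]:
    u = rng.random()
    p = profile.symptom_class_probs
    pool = sorted(ILI_SYMPTOMS | COLD_SYMPTOMS | OTHER_SYMPTOMS)
    cum = 0.0
    for cls in ("ili", "cold", "both", "two_other", "one"):
        cum += p.get(cls, 0.0)
        if u < cum:
            if cls == "ili":
                return frozenset(ILI_SYMPTOMS)
            if cls == "cold":
                return frozenset(COLD_SYMPTOMS)
            if cls == "both":
                return frozenset(ILI_SYMPTOMS | COLD_SYMPTOMS)
            if cls == "two_other":
                return frozenset(rng.choice(pool, size=2, replace=False))
            return frozenset(rng.choice(pool, size=1))
    return frozenset()


def _child_attributes(
    parent: ParticipantRecord,
    grandparent: ParticipantRecord | None,
    profile: CountryProfile,
    markov_order: int,
    rng: np.random.Generator,
) -> tuple[int, str, int]:
    """Recruitee (age, sex, education) from the homophily kernels.

    With ``markov_order=2`` each attribute is anchored on the recruiter or
    (with probability 1/2) the grand-recruiter, a minimal long-memory
    deviation the Markov check is expected to detect.
    """
    h = profile.homophily

    def anchor() -> ParticipantRecord:
        if markov_order == 2 and grandparent is not None and rng.random() < 0.5:
            return grandparent
        return parent

    a = anchor()
    age = int(round(np.clip(a.age + rng.normal(0.0, h.age_sd), *AGE_RANGE)))
    a = anchor()
    if rng.random() < h.sex_stay_prob:
        sex = a.sex
    else:
        sex = "male" if a.sex == "female" else "female"
    a = anchor()
    row = np.asarray(h.education_transition[a.education - 1], dtype=float)
    education = int(rng.choice((1, 2, 3), p=row / row.sum()))
    return age, sex, education


def generate_forest(profile: CountryProfile, config: GeneratorConfig) -> RDSForest:
    """Generate one country's recruitment forest.

    Seeds draw age, sex and education from the seed distributions; recruitees
    inherit them through the homophily kernels.  Degrees are i.i.d. negative
    binomial, decomposed over settings.  Identical ``rng_seed`` values give
    bit-identical datasets.
    """
    profile.validate()
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    records: list[ParticipantRecord] = []
    edges: list[RecruitmentEdge] = []
    hh_sizes = sorted(profile.household_dist)
    hh_probs = np.array([profile.household_dist[s] for s in hh_sizes], dtype=float)
    methods = sorted(profile.recruitment_method_probs)
    method_probs = np.array(
        [profile.recruitment_method_probs[m] for m in methods], dtype=float
    )
    counter = 0

    def new_participant(
        wave: int, age: int, sex: str, education: int, method: str
    ) -> ParticipantRecord:
        nonlocal counter
        counter += 1
        degree = int(_negbin(rng, profile.degree_mu, profile.degree_k))
        loc, tr, eating, tallies = decompose_contacts(degree, profile, rng)
        household = int(rng.choice(hh_sizes, p=hh_probs / hh_probs.sum()))
        if rng.random() < profile.household_unknown_prob:
            hh_sym: int | None = None
        else:
            hh_sym = int(rng.binomial(household - 1, profile.household_symptom_prob))
        requested = rng.random() < profile.recruitment.invite_probability(degree, sex)
        rec = ParticipantRecord(
            id=f"{profile.name}-{counter:05d}",
            country=profile.name,
            age=age,
            sex=sex,
            education=education,
            household_size=household,
            location_counts=loc,
            transport_counts=tr,
            eating_count=eating,
            age_direction_tallies=tallies,
            symptoms=_draw_symptoms(profile, rng),
            household_symptomatic=hh_sym,
            recording_day=str(rng.choice(WEEKDAYS)),
            recruitment_method=method,
            requested_invitations=bool(requested),
            complete=bool(rng.random() < profile.complete_prob),
            wave=wave,
        )
        records.append(rec)
        return rec

    frontier: list[tuple[ParticipantRecord, ParticipantRecord | None]] = []
    for _ in range(config.n_seeds):
        age = int(round(np.clip(
            rng.normal(profile.seed_age_mean, profile.seed_age_sd), *AGE_RANGE
        )))
        sex = "female" if rng.random() < profile.seed_female_prob else "male"
        education = int(rng.choice((1, 2, 3), p=profile.seed_education_dist))
        frontier.append((new_participant(0, age, sex, education, "seed"), None))

    wave = 0
    while frontier and wave < config.max_waves:
        next_frontier: list[tuple[ParticipantRecord, ParticipantRecord | None]] = []
        for parent, grandparent in frontier:
            if not parent.requested_invitations:
                continue
            n_children = int(
                rng.binomial(
                    profile.recruitment.max_invites, profile.recruitment.success_prob
                )
            )
            for _ in range(n_children):
                age, sex, education = _child_attributes(
                    parent, grandparent, profile, config.markov_order, rng
                )
                method = str(rng.choice(methods, p=method_probs / method_probs.sum()))
                child = new_participant(wave + 1, age, sex, education, method)
                edges.append(RecruitmentEdge(parent.id, child.id))
                next_frontier.append((child, parent))
        frontier = next_frontier
        wave += 1
    return RDSForest(records, edges)
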