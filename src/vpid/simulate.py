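"""Synthetic claims worlds with ground truth.

The generator emulates the mechanisms that make anonymized claim identifiers
churn in a national insurance claims database:

* **insurance change** — a citizen changes jobs/insurers; the insured
  identifier behind ID1 is reissued, so ID1 changes while ID2 persists;
* **name change** — marriage etc.; the name behind ID2 changes while ID1
  persists;
* **simultaneous change** — both change in the same month with no claim in
  between (e.g. marriage plus job change), the one churn pattern a
  co-occurrence-based consolidation cannot bridge;
* **clerical errors** — a typo on a single document yields a one-off wrong
  identifier value on one claim without changing the citizen's real state;
* **same-sex twins** — two citizens sharing insured identifier, gender and
  birthdate, hence sharing ID1;
* **garbage claims** — erroneous claims with blank name / zeroed birthdate
  all hash to one shared sentinel ID2 value, wrongly bridging unrelated
  citizens.

Identifier values are hex digests of surrogate tokens (no personal data is
modeled); a standard cryptographic digest plays the role of the production
hash.  Everything is driven by one seeded generator in a fixed iteration
order, so an identical :class:`SimConfig` yields a byte-identical world.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .claims_model import (
    Claim,
    EnrollmentRecord,
    GroundTruth,
    month_index,
    month_str,
)
from .linkage import ID1, ID2

__all__ = [
    "SimConfig",
    "CitizenState",
    "SimWorld",
    "derive_id",
    "garbage_sentinel",
    "simulate_world",
    "scenario_preset",
    "PRESETS",
]


@dataclass(frozen=True)
class SimConfig:
    """Rates and sizes of a synthetic claims world.

    Event probabilities are per citizen-month (changes) or per claim
    (clerical errors, garbage); ``claims_per_citizen_month`` is the mean of
    the Poisson claim-count distribution.  ``twin_fraction`` is the fraction
    of citizens who are one member of a same-sex twin pair.
    """

    n_citizens: int = 1000
    n_months: int = 36
    claims_per_citizen_month: float = 1.0
    p_id1_change: float = 0.0
    p_id2_change: float = 0.0
    p_simultaneous: float = 0.0
    p_clerical_id1: float = 0.0
    p_clerical_id2: float = 0.0
    twin_fraction: float = 0.0
    p_garbage: float = 0.0
    seed: int = 0
    start_month: str = "2013-04"

    def __post_init__(self) -> None:
        if self.n_citizens < 1 or self.n_months < 1:
            raise ValueError("n_citizens and n_months must be >= 1")
        if self.claims_per_citizen_month < 0:
            raise ValueError("claims_per_citizen_month must be >= 0")
        for name in (
            "p_id1_change",
            "p_id2_change",
            "p_simultaneous",
            "p_clerical_id1",
            "p_clerical_id2",
            "twin_fraction",
            "p_garbage",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        month_index(self.start_month)


@dataclass
class CitizenState:
    """Current identity surrogates of one citizen."""

    citizen_number: str
    insured_token: str
    name_token: str
    gender: str
    birthdate: str


@dataclass
class SimWorld:
    """A generated world: claims, enrollment eras, truth, and the event log."""

    config: SimConfig
    claims: list[Claim]
    enrollment: list[EnrollmentRecord]
    truth: GroundTruth
    event_log: list[tuple[str, str, str]]  # (month, citizen_number, event kind)


def derive_id(kind: int, state: CitizenState) -> str:
    """Anonymized identifier of a citizen state.

    ID1 digests the insured identifier + gender + birthdate; ID2 digests the
    name + gender + birthdate.  Equal source fields give equal values; any
    field change gives an unrelated value (digest avalanche).  Output is hex,
    free of the reserved ``:`` and ``|`` characters.
    """
    if kind == ID1:
        source = f"1\x1f{state.insured_token}\x1f{state.gender}\x1f{state.birthdate}"
    elif kind == ID2:
        source = f"2\x1f{state.name_token}\x1f{state.gender}\x1f{state.birthdate}"
    else:
        raise ValueError(f"kind must be {ID1} or {ID2}, got {kind!r}")
    return hashlib.sha1(source.encode()).hexdigest()[:16]


def garbage_sentinel() -> str:
    """The shared ID2 value of erroneous claims (blank name, zeroed birthdate)."""
    blank = CitizenState("", insured_token="", name_token="", gender="", birthdate="0000-00-00")
    return derive_id(ID2, blank)


def _init_citizens(config: SimConfig, rng: np.random.Generator) -> list[CitizenState]:
    n = config.n_citizens
    n_twins = int(round(config.twin_fraction * n / 2)) * 2
    genders = rng.choice(["M", "F"], size=n)
    birth_years = rng.integers(1920, 2013, size=n)
    birth_months = rng.integers(1, 13, size=n)
    birth_days = rng.integers(1, 29, size=n)
    citizens: list[CitizenState] = []
    insured_seq = 0
    for i in range(n):
        if n_twins and i < n_twins and i % 2 == 1:
            # second member of a twin pair: share insured token, gender, birthdate
            twin = citizens[i - 1]
            state = CitizenState(
                citizen_number=f"u{i:07d}",
                insured_token=twin.insured_token,
                name_token=f"N{i:08d}",
                gender=twin.gender,
                birthdate=twin.birthdate,
            )
        else:
            state = CitizenState(
                citizen_number=f"u{i:07d}",
                insured_token=f"I{insured_seq:08d}",
                name_token=f"N{i:08d}",
                gender=str(genders[i]),
                birthdate=f"{birth_years[i]:04d}-{birth_months[i]:02d}-{birth_days[i]:02d}",
            )
            insured_seq += 1
        citizens.append(state)
    return citizens


def simulate_world(config: SimConfig) -> SimWorld:
    """Generate a full synthetic world under ``config``.

    Per citizen per month: change events fire first (updating the citizen's
    state and closing the current enrollment era), then a Poisson number of
    claims is stamped with the current ID1/ID2.  Clerical errors and garbage
    perturb individual claims only — the underlying state, and hence the
    enrollment history and ground truth, are untouched.  Change events start
    from the second month, so every citizen's first era is observable.
    """
    rng = np.random.default_rng(config.seed)
    citizens = _init_citizens(config, rng)
    sentinel = garbage_sentinel()

    claims: list[Claim] = []
    enrollment: list[EnrollmentRecord] = []
    truth = GroundTruth()
    event_log: list[tuple[str, str, str]] = []

    start = month_index(config.start_month)
    months = [month_str(start + m) for m in range(config.n_months)]
    claim_seq = 0
    error_seq = 0

    p_sim = config.p_simultaneous
    p1 = config.p_id1_change
    p2 = config.p_id2_change
    pc1 = config.p_clerical_id1
    pc2 = config.p_clerical_id2
    pg = config.p_garbage

    for citizen in citizens:
        n_m = config.n_months
        counts = rng.poisson(config.claims_per_citizen_month, size=n_m)
        sim_flags = rng.random(n_m) < p_sim if p_sim > 0 else None
        id1_flags = rng.random(n_m) < p1 if p1 > 0 else None
        id2_flags = rng.random(n_m) < p2 if p2 > 0 else None

        id1 = derive_id(ID1, citizen)
        id2 = derive_id(ID2, citizen)
        era_start = 0

        for m in range(n_m):
            changed = False
            if m > 0:
                if sim_flags is not None and sim_flags[m]:
                    citizen.insured_token = f"I{citizen.citizen_number}m{m}"
                    citizen.name_token = f"N{citizen.citizen_number}m{m}"
                    event_log.append((months[m], citizen.citizen_number, "simultaneous"))
                    changed = True
                else:
                    if id1_flags is not None and id1_flags[m]:
                        citizen.insured_token = f"I{citizen.citizen_number}m{m}"
                        event_log.append((months[m], citizen.citizen_number, "id1_change"))
                        changed = True
                    if id2_flags is not None and id2_flags[m]:
                        citizen.name_token = f"N{citizen.citizen_number}m{m}"
                        event_log.append((months[m], citizen.citizen_number, "id2_change"))
                        changed = True
            if changed:
                enrollment.append(
                    EnrollmentRecord(
                        citizen.citizen_number, id1, id2, months[era_start], months[m - 1]
                    )
                )
                id1 = derive_id(ID1, citizen)
                id2 = derive_id(ID2, citizen)
                era_start = m

            k = int(counts[m])
            for _ in range(k):
                c_id1, c_id2 = id1, id2
                if pc1 > 0 and rng.random() < pc1:
                    c_id1 = hashlib.sha1(f"err{error_seq}".encode()).hexdigest()[:16]
                    error_seq += 1
                    event_log.append((months[m], citizen.citizen_number, "clerical_id1"))
                if pg > 0 and rng.random() < pg:
                    c_id2 = sentinel
                    event_log.append((months[m], citizen.citizen_number, "garbage"))
                elif pc2 > 0 and rng.random() < pc2:
                    c_id2 = hashlib.sha1(f"err{error_seq}".encode()).hexdigest()[:16]
                    error_seq += 1
                    event_log.append((months[m], citizen.citizen_number, "clerical_id2"))
                claim_id = f"c{claim_seq:09d}"
                claim_seq += 1
                claims.append(Claim(claim_id, months[m], c_id1, c_id2))
                truth.mapping[claim_id] = citizen.citizen_number

        enrollment.append(
            EnrollmentRecord(citizen.citizen_number, id1, id2, months[era_start], months[-1])
        )

    return SimWorld(config, claims, enrollment, truth, event_log)


# Scenario presets.  "clean" is the no-error baseline; each failure preset
# switches on exactly one mechanism so its effect on the scores can be
# observed in isolation.  "mie_like"/"gifu_like" combine all mechanisms at
# rates calibrated so each citizen accumulates on average ~1.2 ID1 values and
# ~1.5 ID2 values over three years — the churn regime in which consolidation
# pays off — with a small simultaneous-change rate and (gifu_like only) a
# garbage-claim rate that noticeably pollutes identifiability.
PRESETS: dict[str, SimConfig] = {
    "clean": SimConfig(n_citizens=10_000, n_months=36, seed=101),
    "churn": SimConfig(
        n_citizens=10_000,
        n_months=36,
        p_id1_change=0.006,
        p_id2_change=0.012,
        p_clerical_id1=0.001,
        p_clerical_id2=0.004,
        seed=102,
    ),
    "twins": SimConfig(n_citizens=10_000, n_months=36, twin_fraction=0.05, seed=103),
    "garbage": SimConfig(n_citizens=10_000, n_months=36, p_garbage=0.005, seed=104),
    "simultaneous": SimConfig(n_citizens=10_000, n_months=36, p_simultaneous=0.002, seed=105),
    "mie_like": SimConfig(
        n_citizens=10_000,
        n_months=36,
        claims_per_citizen_month=1.5,
        p_id1_change=0.004,
        p_id2_change=0.009,
        p_clerical_id1=0.0015,
        p_clerical_id2=0.004,
        p_simultaneous=0.0001,
        twin_fraction=0.002,
        p_garbage=0.0,
        seed=106,
    ),
    "gifu_like": SimConfig(
        n_citizens=10_000,
        n_months=36,
        claims_per_citizen_month=1.4,
        p_id1_change=0.0035,
        p_id2_change=0.008,
        p_clerical_id1=0.001,
        p_clerical_id2=0.002,
        p_simultaneous=0.00006,
        twin_fraction=0.002,
        p_garbage=0.0005,
        seed=107,
    ),
}


def scenario_preset(name: str, **overrides) -> SimConfig:
    """A documented preset configuration; ``overrides`` replace fields (e.g. seed)."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
    return replace(base, **overrides) if overrides else base
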