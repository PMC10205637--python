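"""Domain types and file I/O for anonymized healthcare insurance claims.

A *claim* is one monthly billing record carrying two anonymized patient
identifiers: ID1 (hashed from insured identifier + gender + birthdate, churns
when insurance coverage changes) and ID2 (hashed from name + gender +
birthdate, churns on name changes and typos).  An *enrollment record* is the
insurer-side era binding those identifier values to an anonymized unique
citizen number over a validity period; joining claims to enrollment history
yields ground truth for evaluating any derived identifier.

All identifier values are opaque, case-sensitive strings.  Values containing
``:`` or ``|`` are rejected at validation time because those characters are
reserved by the canonical vPID encoding.  Missing identifiers are ``None`` in
memory and empty cells on disk — never the empty string as a linkable value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Claim",
    "EnrollmentRecord",
    "GroundTruth",
    "FormatError",
    "ValidationError",
    "read_claims",
    "write_claims",
    "read_enrollment",
    "write_enrollment",
    "read_truth",
    "write_truth",
    "resolve_ground_truth",
    "month_index",
    "month_str",
]

_MONTH_RE = re.compile(r"^\d{4}-(0[1-9]|1[0-2])$")
_RESERVED = (":", "|")

CLAIMS_COLUMNS = ["claim_id", "service_month", "id1", "id2"]
ENROLLMENT_COLUMNS = ["citizen_number", "id1", "id2", "start_month", "end_month"]
TRUTH_COLUMNS = ["claim_id", "citizen_number"]


class FormatError(ValueError):
    """A file does not have the expected layout (missing/renamed columns)."""


class ValidationError(ValueError):
    """Parsed rows violate a domain invariant (duplicates, bad months...)."""


@lru_cache(maxsize=8192)
def month_index(month: str) -> int:
    """Number of months since 0000-01 for a ``YYYY-MM`` string.

    Claims are monthly statements, so all timing in the package is at
    calendar-month granularity; indices make period-containment checks and
    month arithmetic trivial.
    """
    if not _MONTH_RE.match(month):
        raise ValidationError(f"service month {month!r} is not of the form YYYY-MM")
    year, mon = month.split("-")
    return int(year) * 12 + int(mon) - 1


def month_str(index: int) -> str:
    """Inverse of :func:`month_index`."""
    return f"{index // 12:04d}-{index % 12 + 1:02d}"


def _check_identifier(value: str | None, where: str) -> str | None:
    if value is None:
        return None
    if value == "":
        return None
    for ch in _RESERVED:
        if ch in value:
            raise ValidationError(
                f"identifier value {value!r} in {where} contains reserved character {ch!r}"
            )
    return value


@dataclass(frozen=True)
class Claim:
    """One insurance claim: an (ID1, ID2) value pair stamped with a service month.

    At least one identifier must be present for the claim to participate in
    linkage; claims with neither are carried through the pipeline but cannot
    be merged with anything.
    """

    claim_id: str
    service_month: str
    id1: str | None = None
    id2: str | None = None

    def __post_init__(self) -> None:
        month_index(self.service_month)  # raises on malformed month
        object.__setattr__(self, "id1", _check_identifier(self.id1, f"claim {self.claim_id}"))
        object.__setattr__(self, "id2", _check_identifier(self.id2, f"claim {self.claim_id}"))

    @property
    def has_identifier(self) -> bool:
        return self.id1 is not None or self.id2 is not None


@dataclass(frozen=True)
class EnrollmentRecord:
    """Ground-truth era: a citizen held (id1, id2) from start_month to end_month inclusive."""

    citizen_number: str
    id1: str
    id2: str
    start_month: str
    end_month: str

    def __post_init__(self) -> None:
        if month_index(self.start_month) > month_index(self.end_month):
            raise ValidationError(
                f"enrollment era for {self.citizen_number}: start {self.start_month} "
                f"after end {self.end_month}"
            )
        _check_identifier(self.id1, f"enrollment of {self.citizen_number}")
        _check_identifier(self.id2, f"enrollment of {self.citizen_number}")

    def contains(self, month: str) -> bool:
        return month_index(self.start_month) <= month_index(month) <= month_index(self.end_month)


@dataclass
class GroundTruth:
    """Resolution of claims to citizens.

    Every claim id appears in exactly one of ``mapping`` (uniquely resolved)
    or ``unresolved`` (matched zero or several citizens — ambiguity is data,
    not an error).
    """

    mapping: dict[str, str] = field(default_factory=dict)
    unresolved: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = set(self.mapping) & self.unresolved
        if overlap:
            raise ValidationError(
                f"claim ids both mapped and unresolved: {sorted(overlap)[:3]}"
            )

    def __len__(self) -> int:
        return len(self.mapping) + len(self.unresolved)


def _read_table(path: str | Path, columns: Sequence[str], sep: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in columns:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df[list(columns)]


def read_claims(path: str | Path, sep: str = ",") -> list[Claim]:
    """Read a claims table (header ``claim_id,service_month,id1,id2``).

    Empty identifier cells become absent identifiers.  Row order is
    preserved; a repeated claim_id is a validation error naming the first
    duplicate.
    """
    df = _read_table(path, CLAIMS_COLUMNS, sep)
    dup = df["claim_id"].duplicated()
    if dup.any():
        first = df.loc[dup, "claim_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate claim_id {first!r}")
    return [
        Claim(
            claim_id=row.claim_id,
            service_month=row.service_month,
            id1=row.id1 or None,
            id2=row.id2 or None,
        )
        for row in df.itertuples(index=False)
    ]


def write_claims(claims: Iterable[Claim], path: str | Path, sep: str = ",") -> None:
    """Write claims so that :func:`read_claims` round-trips them field-for-field."""
    df = pd.DataFrame(
        [(c.claim_id, c.service_month, c.id1 or "", c.id2 or "") for c in claims],
        columns=CLAIMS_COLUMNS,
    )
    df.to_csv(path, sep=sep, index=False)


def read_enrollment(path: str | Path, sep: str = ",") -> list[EnrollmentRecord]:
    """Read an enrollment-history table; invalid eras report their row number."""
    df = _read_table(path, ENROLLMENT_COLUMNS, sep)
    records: list[EnrollmentRecord] = []
    seen: set[tuple[str, str, str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            rec = EnrollmentRecord(*row)
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i + 2}: {exc}") from exc
        key = (rec.citizen_number, rec.id1, rec.id2, rec.start_month)
        if key in seen:
            raise ValidationError(f"{path} row {i + 2}: duplicate enrollment era {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_enrollment(records: Iterable[EnrollmentRecord], path: str | Path, sep: str = ",") -> None:
    df = pd.DataFrame(
        [
            (r.citizen_number, r.id1, r.id2, r.start_month, r.end_month)
            for r in records
        ],
        columns=ENROLLMENT_COLUMNS,
    )
    df.to_csv(path, sep=sep, index=False)


def read_truth(path: str | Path, sep: str = ",") -> GroundTruth:
    """Read a ``claim_id,citizen_number`` truth file.

    An empty citizen cell marks an unresolved claim.
    """
    df = _read_table(path, TRUTH_COLUMNS, sep)
    dup = df["claim_id"].duplicated()
    if dup.any():
        first = df.loc[dup, "claim_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate claim_id {first!r}")
    truth = GroundTruth()
    for row in df.itertuples(index=False):
        if row.citizen_number:
            truth.mapping[row.claim_id] = row.citizen_number
        else:
            truth.unresolved.add(row.claim_id)
    return truth


def write_truth(
    truth: GroundTruth, path: str | Path, sep: str = ",", claim_order: Sequence[str] | None = None
) -> None:
    """Write a truth file; unresolved claims get an empty citizen cell.

    ``claim_order`` fixes the row order (e.g. the claims-table order); by
    default rows are sorted by claim_id for determinism.
    """
    if claim_order is None:
        claim_order = sorted(truth.mapping) + sorted(truth.unresolved)
    rows = [(cid, truth.mapping.get(cid, "")) for cid in claim_order]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep=sep, index=False)


def resolve_ground_truth(
    claims: Sequence[Claim], enrollment: Sequence[EnrollmentRecord]
) -> GroundTruth:
    """Join claims to enrollment history to resolve each claim to a citizen.

    A claim resolves to citizen ``u`` iff exactly one citizen has an
    enrollment era whose period contains the claim's service month and whose
    id1 equals the claim's id1 or whose id2 equals the claim's id2.  The
    OR-match tolerates a clerical error in a single identifier; requiring a
    unique citizen keeps the truth conservative — claims matching zero or
    several citizens are reported as unresolved rather than guessed.
    """
    by_id1: dict[str, list[EnrollmentRecord]] = {}
    by_id2: dict[str, list[EnrollmentRecord]] = {}
    for rec in enrollment:
        by_id1.setdefault(rec.id1, []).append(rec)
        by_id2.setdefault(rec.id2, []).append(rec)

    truth = GroundTruth()
    for claim in claims:
        candidates: set[str] = set()
        if claim.id1 is not None:
            for rec in by_id1.get(claim.id1, ()):
                if rec.contains(claim.service_month):
                    candidates.add(rec.citizen_number)
        if claim.id2 is not None:
            for rec in by_id2.get(claim.id2, ()):
                if rec.contains(claim.service_month):
                    candidates.add(rec.citizen_number)
        if len(candidates) == 1:
            truth.mapping[claim.claim_id] = candidates.pop()
        else:
            truth.unresolved.add(claim.claim_id)
    return truth
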