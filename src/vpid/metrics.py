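"""Linkage-quality evaluation of an anonymized identifier against ground truth.

Two patient-level, all-or-nothing scores:

* **traceability** — the fraction of citizens all of whose scored claims
  carry a single value of the identifier (every claim of the patient is
  collectible under one value).  Equivalently ``1 − m/n`` where ``m`` is the
  number of citizens holding two or more values and ``n`` the number of
  citizens with at least one scored claim.
* **identifiability** — the fraction of citizens none of whose values is
  shared with another citizen (the patient's claims can be distinguished
  from everyone else's).

Both are deliberately stricter than pairwise precision/recall: one stray
claim or one shared value disqualifies the whole citizen.  A raw identifier
tends to score high identifiability but poor traceability (values churn with
life events); a consolidated identifier trades a little identifiability
(wrong merges) for near-perfect traceability.

Only claims that carry the evaluated identifier AND resolve to a citizen in
the ground truth enter scoring; excluded counts are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Mapping, Sequence

import pandas as pd

from .claims_model import Claim, GroundTruth
from .linkage import VpidAssignment

__all__ = [
    "LabeledClaims",
    "ScoreReport",
    "label_claims",
    "values_per_citizen",
    "citizens_per_value",
    "traceability_score",
    "identifiability_score",
    "cardinality",
    "score_report",
    "evaluate_all",
    "render_table",
]


@dataclass
class LabeledClaims:
    """Scored claims for one identifier: (citizen, label) pairs plus exclusion counts."""

    identifier_name: str
    pairs: list[tuple[str, str]]  # (citizen_number, label value), one per scored claim
    n_claims_total: int
    n_excluded_no_label: int
    n_excluded_unresolved: int

    @property
    def n_claims_scored(self) -> int:
        return len(self.pairs)


class UndefinedScoreError(ValueError):
    """Raised when a score is requested over zero citizens."""


def label_claims(
    claims: Sequence[Claim],
    truth: GroundTruth,
    identifier_name: str,
    label_of_claim: Callable[[Claim], str | None] | Mapping[str, str],
) -> LabeledClaims:
    """Attach the evaluated identifier's value and the true citizen to each claim.

    ``label_of_claim`` is either a function of the claim (e.g. ``lambda c:
    c.id1``) or a precomputed claim_id → label mapping (e.g. a vPID
    assignment).  Claims without a label or without a resolved citizen are
    excluded and counted.
    """
    pairs: list[tuple[str, str]] = []
    no_label = 0
    unresolved = 0
    getter = (
        label_of_claim.get if isinstance(label_of_claim, Mapping) else None
    )
    for claim in claims:
        label = getter(claim.claim_id) if getter else label_of_claim(claim)
        if label is None:
            no_label += 1
            continue
        citizen = truth.mapping.get(claim.claim_id)
        if citizen is None:
            unresolved += 1
            continue
        pairs.append((citizen, label))
    return LabeledClaims(identifier_name, pairs, len(claims), no_label, unresolved)


def values_per_citizen(lc: LabeledClaims) -> dict[str, set[str]]:
    """V(u): the set of label values over citizen u's scored claims."""
    out: dict[str, set[str]] = {}
    for citizen, label in lc.pairs:
        out.setdefault(citizen, set()).add(label)
    return out


def citizens_per_value(lc: LabeledClaims) -> dict[str, set[str]]:
    """U(v): the set of citizens whose scored claims carry label value v."""
    out: dict[str, set[str]] = {}
    for citizen, label in lc.pairs:
        out.setdefault(label, set()).add(citizen)
    return out


def traceability_score(lc: LabeledClaims) -> float:
    """1 − (citizens with ≥2 values) / (citizens with ≥1 scored claim)."""
    V = values_per_citizen(lc)
    if not V:
        raise UndefinedScoreError("traceability undefined: no scored citizens")
    n_multi = sum(1 for values in V.values() if len(values) > 1)
    return 1.0 - n_multi / len(V)


def identifiability_score(lc: LabeledClaims) -> float:
    """Fraction of citizens none of whose label values is shared with another citizen."""
    V = values_per_citizen(lc)
    if not V:
        raise UndefinedScoreError("identifiability undefined: no scored citizens")
    U = citizens_per_value(lc)
    n_clean = sum(
        1 for citizen, values in V.items() if all(len(U[v]) == 1 for v in values)
    )
    return n_clean / len(V)


def cardinality(lc: LabeledClaims) -> int:
    """Number of distinct label values among scored claims."""
    return len({label for _, label in lc.pairs})


@dataclass
class ScoreReport:
    """Per-identifier evaluation summary (one column of the comparison table)."""

    identifier_name: str
    n_citizens: int
    n_claims_scored: int
    n_claims_total: int
    n_excluded_no_label: int
    n_excluded_unresolved: int
    cardinality: int
    identifiability: float
    traceability: float
    avg_instances_per_citizen: float
    n_multi_value_citizens: int
    n_shared_values: int

    def to_dict(self) -> dict:
        return asdict(self)


def score_report(lc: LabeledClaims) -> ScoreReport:
    """Full evaluation of one identifier.

    The multi-value citizen count is recomputed here with pandas groupby,
    independently of the set-based counting inside
    :func:`traceability_score`, so the identity
    ``traceability == 1 − n_multi_value_citizens / n_citizens``
    is a genuine cross-check of two code paths, not a restatement.
    """
    if not lc.pairs:
        raise UndefinedScoreError(
            f"no scored claims for identifier {lc.identifier_name!r}"
        )
    df = pd.DataFrame(lc.pairs, columns=["citizen", "label"])
    values_per = df.groupby("citizen")["label"].nunique()
    citizens_per = df.groupby("label")["citizen"].nunique()
    n_citizens = int(values_per.size)
    return ScoreReport(
        identifier_name=lc.identifier_name,
        n_citizens=n_citizens,
        n_claims_scored=lc.n_claims_scored,
        n_claims_total=lc.n_claims_total,
        n_excluded_no_label=lc.n_excluded_no_label,
        n_excluded_unresolved=lc.n_excluded_unresolved,
        cardinality=cardinality(lc),
        identifiability=identifiability_score(lc),
        traceability=traceability_score(lc),
        avg_instances_per_citizen=float(values_per.mean()),
        n_multi_value_citizens=int((values_per > 1).sum()),
        n_shared_values=int((citizens_per > 1).sum()),
    )


def evaluate_all(
    claims: Sequence[Claim],
    truth: GroundTruth,
    assignment: VpidAssignment,
) -> dict[str, ScoreReport]:
    """Evaluate ID1, ID2 and vPID over the same claim set and ground truth."""
    reports = {}
    for name, labeler in (
        ("ID1", lambda c: c.id1),
        ("ID2", lambda c: c.id2),
        ("vPID", assignment.vpid_of_claim),
    ):
        reports[name] = score_report(label_claims(claims, truth, name, labeler))
    return reports


def render_table(reports: Mapping[str, ScoreReport]) -> str:
    """Human-readable comparison grid; scores shown to three decimals."""
    names = list(reports)
    rows = [
        ("Number of instances", [f"{reports[n].cardinality}" for n in names]),
        ("Identifiability score", [f"{reports[n].identifiability:.3f}" for n in names]),
        ("Traceability score", [f"{reports[n].traceability:.3f}" for n in names]),
        (
            "Average instances per insured citizen",
            [f"{reports[n].avg_instances_per_citizen:.3f}" for n in names],
        ),
        ("Citizens scored", [f"{reports[n].n_citizens}" for n in names]),
    ]
    label_w = max(len(r[0]) for r in rows)
    col_w = max(12, *(len(n) for n in names))
    lines = [" " * label_w + "  " + "  ".join(f"{n:>{col_w}}" for n in names)]
    for label, cells in rows:
        lines.append(f"{label:<{label_w}}  " + "  ".join(f"{c:>{col_w}}" for c in cells))
    return "\n".join(lines)
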