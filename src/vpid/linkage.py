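"""The vPID consolidation algorithm.

Each claim carries an (ID1, ID2) pair.  Treat every distinct identifier value
as a node of a bipartite co-occurrence graph — an ID1 value and an ID2 value
are joined whenever they appear on the same claim — and take connected
components.  Each component is one *virtual patient*: any chain of claims in
which only one identifier changed at a time stays inside one component, so
the derived vPID traces a patient across insurance changes (ID1 churn) and
name changes (ID2 churn), as long as both never change with no claim in
between.

The canonical vPID value of a component is the sorted concatenation of its
member renderings (``1:<id1 value>`` / ``2:<id2 value>``) joined by ``|``.
The kind prefix keeps an ID1 and an ID2 with equal bytes distinct, and the
reserved separators keep the value decodable back into its members.

Components are computed with a disjoint-set forest (union by size, path
compression) — near-linear in the number of claims, which matters at the
tens-of-millions-of-claims scale these databases have.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from .claims_model import Claim

__all__ = [
    "ID1",
    "ID2",
    "IdentifierNode",
    "Partition",
    "VpidAssignment",
    "DisjointSet",
    "build_edges",
    "consolidate",
    "derive_vpid_value",
    "assign_vpids",
    "link_claims",
    "merge_histogram",
    "digest_vpid",
]

ID1 = 1
ID2 = 2


class IdentifierNode(NamedTuple):
    """A distinct identifier value; ``(kind, value)`` is the node identity."""

    kind: int  # ID1 or ID2
    value: str

    def render(self) -> str:
        return f"{self.kind}:{self.value}"


class EdgeSet(NamedTuple):
    """Output of :func:`build_edges`."""

    edges: list[tuple[IdentifierNode, IdentifierNode]]
    isolated: list[IdentifierNode]
    skipped: list[str]  # claim_ids with neither identifier


@dataclass
class Partition:
    """Connected components of the co-occurrence graph.

    ``label_of`` maps each node to its component label; ``components`` maps
    each label to the node set.  Labels are the lexicographically smallest
    member rendering, so they are stable under claim reordering.
    """

    label_of: dict[IdentifierNode, str] = field(default_factory=dict)
    components: dict[str, frozenset[IdentifierNode]] = field(default_factory=dict)


@dataclass
class VpidAssignment:
    """vPID values for every claim plus the decoded membership of each vPID."""

    vpid_of_claim: dict[str, str] = field(default_factory=dict)
    vpid_members: dict[str, tuple[frozenset[str], frozenset[str]]] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)


class DisjointSet:
    """Disjoint-set forest over hashable items, union by size + path compression."""

    def __init__(self) -> None:
        self._parent: dict = {}
        self._size: dict = {}

    def add(self, item) -> None:
        if item not in self._parent:
            self._parent[item] = item
            self._size[item] = 1

    def find(self, item):
        root = item
        while self._parent[root] != root:
            root = self._parent[root]
        # path compression
        while self._parent[item] != root:
            self._parent[item], item = root, self._parent[item]
        return root

    def union(self, a, b) -> None:
        self.add(a)
        self.add(b)
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self._size[ra] < self._size[rb]:
            ra, rb = rb, ra
        self._parent[rb] = ra
        self._size[ra] += self._size[rb]

    def groups(self) -> dict:
        out: dict = {}
        for item in self._parent:
            out.setdefault(self.find(item), set()).add(item)
        return out


def build_edges(claims: Sequence[Claim]) -> EdgeSet:
    """One edge per two-identifier claim; one isolated node per single-identifier claim.

    Duplicate edges are kept (they are harmless to the disjoint-set forest and
    deduplicating here would cost a pass); claims with neither identifier are
    skipped and their ids returned for the caller's skip log.
    """
    edges: list[tuple[IdentifierNode, IdentifierNode]] = []
    isolated: list[IdentifierNode] = []
    skipped: list[str] = []
    for claim in claims:
        n1 = IdentifierNode(ID1, claim.id1) if claim.id1 is not None else None
        n2 = IdentifierNode(ID2, claim.id2) if claim.id2 is not None else None
        if n1 and n2:
            edges.append((n1, n2))
        elif n1:
            isolated.append(n1)
        elif n2:
            isolated.append(n2)
        else:
            skipped.append(claim.claim_id)
    return EdgeSet(edges, isolated, skipped)


def consolidate(edge_set: EdgeSet) -> Partition:
    """Connected components of the co-occurrence graph via the disjoint-set forest."""
    dsu = DisjointSet()
    for a, b in edge_set.edges:
        dsu.union(a, b)
    for node in edge_set.isolated:
        dsu.add(node)
    partition = Partition()
    for members in dsu.groups().values():
        comp = frozenset(members)
        label = min(n.render() for n in comp)
        partition.components[label] = comp
        for node in comp:
            partition.label_of[node] = label
    return partition


def derive_vpid_value(component: Iterable[IdentifierNode]) -> str:
    """Canonical vPID value: sorted member renderings joined with ``|``.

    Equal components always yield equal values regardless of the order claims
    were seen in, so the vPID is a pure function of the merged identifier set.
    """
    renderings = sorted(n.render() for n in component)
    if not renderings:
        raise ValueError("cannot derive a vPID value for an empty component")
    return "|".join(renderings)


def digest_vpid(vpid: str) -> str:
    """Fixed-width hex form of a canonical vPID value (not decodable)."""
    return hashlib.sha256(vpid.encode()).hexdigest()[:32]


def assign_vpids(
    claims: Sequence[Claim], partition: Partition, digest: bool = False
) -> VpidAssignment:
    """Map every claim to the vPID of its component.

    A claim with neither identifier gets the per-claim fallback value
    ``0:<claim_id>`` so claim counts are conserved end-to-end.  With
    ``digest=True`` vPID values are compact hex tokens instead of the
    decodable canonical strings (the partition is unchanged).
    """
    vpid_of_label: dict[str, str] = {}
    assignment = VpidAssignment()
    for label, comp in partition.components.items():
        value = derive_vpid_value(comp)
        if digest:
            value = digest_vpid(value)
        vpid_of_label[label] = value
        assignment.vpid_members[value] = (
            frozenset(n.value for n in comp if n.kind == ID1),
            frozenset(n.value for n in comp if n.kind == ID2),
        )
    for claim in claims:
        if not claim.has_identifier:
            assignment.vpid_of_claim[claim.claim_id] = f"0:{claim.claim_id}"
            assignment.skipped.append(claim.claim_id)
            continue
        node = (
            IdentifierNode(ID1, claim.id1)
            if claim.id1 is not None
            else IdentifierNode(ID2, claim.id2)
        )
        if node not in partition.label_of:
            raise RuntimeError(
                f"claim {claim.claim_id}: identifier {node} absent from partition "
                "(partition was not built from these claims)"
            )
        assignment.vpid_of_claim[claim.claim_id] = vpid_of_label[partition.label_of[node]]
    return assignment


def link_claims(claims: Sequence[Claim], digest: bool = False) -> VpidAssignment:
    """End-to-end convenience: build edges, consolidate, assign."""
    return assign_vpids(claims, consolidate(build_edges(claims)), digest=digest)


def merge_histogram(assignment: VpidAssignment, kind: int) -> dict[int, float]:
    """Fraction histogram of how many values of one kind each vPID merged.

    For each vPID count its distinct member values of the requested kind;
    normalize over vPIDs containing at least one value of that kind.  A mass
    above k=1 is the consolidation the algorithm achieved — patients whose
    identifier churned but whose claims a single vPID still collects.
    """
    if kind not in (ID1, ID2):
        raise ValueError(f"kind must be {ID1} (ID1) or {ID2} (ID2), got {kind!r}")
    counts: dict[int, int] = {}
    for id1_values, id2_values in assignment.vpid_members.values():
        k = len(id1_values if kind == ID1 else id2_values)
        if k >= 1:
            counts[k] = counts.get(k, 0) + 1
    total = sum(counts.values())
    return {k: counts[k] / total for k in sorted(counts)}
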