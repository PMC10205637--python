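"""vPID consolidation: components, canonical values, assignment, histograms.

The union-find consolidation is cross-checked against an independent
connected-components computation (networkx breadth-first search) on both
hand-built and randomly generated claim sets.
"""

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from vpid.claims_model import Claim
from vpid.linkage import (
    ID1,
    ID2,
    IdentifierNode,
    build_edges,
    consolidate,
    derive_vpid_value,
    digest_vpid,
    assign_vpids,
    link_claims,
    merge_histogram,
)


def oracle_components(claims):
    """Independent oracle: component node-sets via networkx BFS."""
    g = nx.Graph()
    for c in claims:
        n1 = IdentifierNode(ID1, c.id1) if c.id1 is not None else None
        n2 = IdentifierNode(ID2, c.id2) if c.id2 is not None else None
        if n1:
            g.add_node(n1)
        if n2:
            g.add_node(n2)
        if n1 and n2:
            g.add_edge(n1, n2)
    return {frozenset(comp) for comp in nx.connected_components(g)}


def random_claims(rng, n_claims, n_id1, n_id2, p_missing=0.15):
    claims = []
    for i in range(n_claims):
        id1 = f"a{rng.integers(n_id1)}"
        id2 = f"b{rng.integers(n_id2)}"
        u = rng.random()
        if u < p_missing / 2:
            id1 = None
        elif u < p_missing:
            id2 = None
        claims.append(Claim(f"c{i}", "2013-04", id1, id2))
    return claims


def make_claims(pairs):
    return [
        Claim(f"c{i}", "2013-04", id1, id2) for i, (id1, id2) in enumerate(pairs)
    ]


class TestBuildEdges:
    def test_one_edge_per_two_identifier_claim(self):
        es = build_edges(make_claims([("A", "X"), ("B", "X"), ("B", "Y")]))
        assert es.edges == [
            (IdentifierNode(ID1, "A"), IdentifierNode(ID2, "X")),
            (IdentifierNode(ID1, "B"), IdentifierNode(ID2, "X")),
            (IdentifierNode(ID1, "B"), IdentifierNode(ID2, "Y")),
        ]
        assert not es.isolated and not es.skipped

    def test_single_identifier_claim_is_isolated_node(self):
        es = build_edges(make_claims([("C", None)]))
        assert es.isolated == [IdentifierNode(ID1, "C")] and not es.edges

    def test_identifierless_claim_goes_to_skip_log(self):
        es = build_edges(make_claims([(None, None)]))
        assert es.skipped == ["c0"] and not es.edges and not es.isolated

    def test_empty_input(self):
        es = build_edges([])
        assert es == ([], [], [])


class TestConsolidate:
    def test_toy_components_match_enumeration(self):
        claims = make_claims([("A", "X"), ("B", "X"), ("B", "Y"), ("C", "Z")])
        part = consolidate(build_edges(claims))
        comps = {frozenset(n.render() for n in c) for c in part.components.values()}
        assert comps == {
            frozenset({"1:A", "1:B", "2:X", "2:Y"}),
            frozenset({"1:C", "2:Z"}),
        }

    def test_chain_collapses_to_single_component(self):
        # claims (id1_i, id2_i) and (id1_{i+1}, id2_i) chain 1000 links together
        pairs = []
        for i in range(1000):
            pairs.append((f"A{i}", f"X{i}"))
            pairs.append((f"A{i+1}", f"X{i}"))
        part = consolidate(build_edges(make_claims(pairs)))
        assert len(part.components) == 1
        (comp,) = part.components.values()
        assert len(comp) == 2001

    def test_fresh_pairs_stay_separate(self):
        claims = make_claims([(f"A{i}", f"X{i}") for i in range(50)])
        part = consolidate(build_edges(claims))
        assert len(part.components) == 50
        assert all(len(c) == 2 for c in part.components.values())

    def test_equal_id1_and_id2_byte_strings_are_distinct_nodes(self):
        part = consolidate(build_edges(make_claims([("Z", None), (None, "Z")])))
        assert len(part.components) == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bfs_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        claims = random_claims(rng, 300, 60, 60)
        part = consolidate(build_edges(claims))
        assert set(part.components.values()) == oracle_components(claims)

    @given(st.lists(
        st.tuples(st.integers(0, 12), st.integers(0, 12),
                  st.sampled_from(["both", "id1", "id2"])),
        max_size=40,
    ))
    @settings(derandomize=True, max_examples=80)
    def test_oracle_equivalence_property(self, rows):
        claims = []
        for i, (a, b, present) in enumerate(rows):
            id1 = f"a{a}" if present in ("both", "id1") else None
            id2 = f"b{b}" if present in ("both", "id2") else None
            claims.append(Claim(f"c{i}", "2013-04", id1, id2))
        part = consolidate(build_edges(claims))
        assert set(part.components.values()) == oracle_components(claims)


class TestVpidValue:
    def test_sorted_concatenation(self):
        comp = [
            IdentifierNode(ID1, "B"),
            IdentifierNode(ID2, "X"),
            IdentifierNode(ID1, "A"),
            IdentifierNode(ID2, "Y"),
        ]
        assert derive_vpid_value(comp) == "1:A|1:B|2:X|2:Y"
        assert derive_vpid_value(reversed(comp)) == "1:A|1:B|2:X|2:Y"

    def test_pair_component(self):
        assert derive_vpid_value(
            [IdentifierNode(ID1, "C"), IdentifierNode(ID2, "Z")]
        ) == "1:C|2:Z"

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError):
            derive_vpid_value([])

    def test_digest_is_fixed_width_hex(self):
        d = digest_vpid("1:A|2:X")
        assert len(d) == 32 and int(d, 16) >= 0


class TestAssign:
    def test_toy_assignment(self):
        claims = make_claims([("A", "X"), ("B", "X"), ("B", "Y"), ("C", "Z")])
        a = link_claims(claims)
        assert a.vpid_of_claim == {
            "c0": "1:A|1:B|2:X|2:Y",
            "c1": "1:A|1:B|2:X|2:Y",
            "c2": "1:A|1:B|2:X|2:Y",
            "c3": "1:C|2:Z",
        }
        assert a.vpid_members["1:C|2:Z"] == (frozenset({"C"}), frozenset({"Z"}))

    def test_single_identifier_claim_joins_its_component(self):
        a = link_claims(make_claims([("C", None), ("C", "Z")]))
        assert a.vpid_of_claim["c0"] == a.vpid_of_claim["c1"] == "1:C|2:Z"

    def test_identifierless_claim_gets_per_claim_fallback(self):
        claims = [Claim("c9", "2013-04", None, None)]
        a = link_claims(claims)
        assert a.vpid_of_claim == {"c9": "0:c9"}
        assert a.skipped == ["c9"]

    def test_stale_partition_detected(self):
        part = consolidate(build_edges(make_claims([("A", "X")])))
        with pytest.raises(RuntimeError):
            assign_vpids(make_claims([("Q", "R")]), part)

    def test_digest_relabels_without_changing_partition(self):
        claims = make_claims([("A", "X"), ("B", "X"), ("C", "Z")])
        plain = link_claims(claims)
        hexed = link_claims(claims, digest=True)
        def classes(a):
            groups = {}
            for cid, v in a.vpid_of_claim.items():
                groups.setdefault(v, set()).add(cid)
            return set(frozenset(g) for g in groups.values())
        assert classes(plain) == classes(hexed)
        assert all(len(v) == 32 for v in hexed.vpid_of_claim.values())


class TestProperties:
    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        claims = random_claims(rng, 200, 40, 40)
        base = link_claims(claims).vpid_of_claim
        for _ in range(3):
            perm = [claims[i] for i in rng.permutation(len(claims))]
            assert link_claims(perm).vpid_of_claim == base

    def test_idempotence_vpid_as_both_identifiers(self):
        # rewriting each claim's identifiers as (vpid, vpid) and re-linking
        # must not change which claims share a vPID
        rng = np.random.default_rng(11)
        claims = random_claims(rng, 150, 30, 30)
        first = link_claims(claims, digest=True)
        rewritten = [
            Claim(c.claim_id, c.service_month,
                  first.vpid_of_claim[c.claim_id], first.vpid_of_claim[c.claim_id])
            for c in claims
        ]
        second = link_claims(rewritten)
        def classes(m):
            groups = {}
            for cid, v in m.items():
                groups.setdefault(v, set()).add(cid)
            return set(frozenset(g) for g in groups.values())
        assert classes(first.vpid_of_claim) == classes(second.vpid_of_claim)

    def test_growth_only_merges_components(self):
        rng = np.random.default_rng(13)
        claims = random_claims(rng, 250, 50, 50, p_missing=0.0)
        half = consolidate(build_edges(claims[:125]))
        full = consolidate(build_edges(claims))
        # every component of the half-world is contained in one full component
        for comp in half.components.values():
            labels = {full.label_of[n] for n in comp}
            assert len(labels) == 1

    def test_component_count_bounded_by_identifier_cardinalities(self):
        rng = np.random.default_rng(17)
        claims = random_claims(rng, 300, 40, 55, p_missing=0.0)
        part = consolidate(build_edges(claims))
        n_id1 = len({c.id1 for c in claims})
        n_id2 = len({c.id2 for c in claims})
        assert len(part.components) <= min(n_id1, n_id2)


class TestMergeHistogram:
    def test_toy_id1_histogram(self):
        a = link_claims(make_claims([("A", "X"), ("B", "X"), ("B", "Y"), ("C", "Z")]))
        assert merge_histogram(a, ID1) == {1: 0.5, 2: 0.5}
        assert merge_histogram(a, ID2) == {1: 0.5, 2: 0.5}

    def test_singletons_give_unit_mass_at_one(self):
        a = link_claims(make_claims([(f"A{i}", f"X{i}") for i in range(10)]))
        assert merge_histogram(a, ID1) == {1: 1.0}

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(23)
        a = link_claims(random_claims(rng, 300, 50, 50))
        for kind in (ID1, ID2):
            assert sum(merge_histogram(a, kind).values()) == pytest.approx(1.0, abs=1e-9)

    def test_unknown_kind_rejected(self):
        a = link_claims(make_claims([("A", "X")]))
        with pytest.raises(ValueError):
            merge_histogram(a, 3)
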