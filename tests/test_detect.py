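"""Insertion detection: gaps, containment, exclusive assignment, nesting."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_protein, oracle_assignments
from domainsert.detect import (
    assign_events,
    candidate_containments,
    compute_nesting_depths,
    detect_all,
    enumerate_gaps,
    position_third,
    relative_position,
)
from domainsert.model import DomainInstance, FamilyKey, ResidueRange
from domainsert.simulate import (
    SyntheticConfig,
    generate_architectures,
    make_nested_protein,
)


def _dom(segs, uid="h", f_id="1.1.1.1"):
    return DomainInstance(
        "p", uid, FamilyKey(f_id), tuple(ResidueRange(a, b) for a, b in segs)
    )


class TestEnumerateGaps:
    def test_single_gap_from_split_host(self):
        gaps = enumerate_gaps(_dom([(1, 111), (177, 409)]))
        assert [(g.start, g.end, g.length) for g in gaps] == [(112, 176, 65)]

    def test_gap_below_threshold_dropped(self):
        assert enumerate_gaps(_dom([(1, 100), (130, 200)]), min_gap=30) == []

    def test_boundary_gap_of_exactly_min_gap_kept(self):
        gaps = enumerate_gaps(_dom([(1, 100), (131, 200), (300, 400)]))
        assert [(g.start, g.end, g.length) for g in gaps] == [
            (101, 130, 30),
            (201, 299, 99),
        ]

    def test_continuous_domain_yields_no_gaps(self):
        assert enumerate_gaps(_dom([(1, 300)])) == []


class TestCandidateContainments:
    def test_single_insertion_candidate(self, mod5_protein):
        pairs = candidate_containments(mod5_protein)
        assert [(uid, g.start, g.end) for uid, g in pairs] == [("insert", 112, 176)]

    def test_nested_insert_pairs_with_both_gaps(self, nested_protein):
        pairs = candidate_containments(nested_protein)
        by_uid = {}
        for uid, g in pairs:
            by_uid.setdefault(uid, []).append(g.host_uid)
        assert sorted(by_uid["dC"]) == ["dA", "dB"]
        assert by_uid["dB"] == ["dA"]

    def test_side_by_side_inserts_share_one_gap(self, side_by_side_protein):
        pairs = candidate_containments(side_by_side_protein)
        assert {(uid, g.host_uid) for uid, g in pairs} == {("dB", "dA"), ("dC", "dA")}


class TestAssignEvents:
    def test_nested_assignment_prefers_smallest_gap(self, nested_protein):
        events = assign_events(nested_protein)
        assert {(e.host_uid, e.insert_uid) for e in events} == {
            ("dA", "dB"),
            ("dB", "dC"),
        }

    def test_worked_single_insertion_event(self, mod5_protein):
        (e,) = assign_events(mod5_protein)
        assert e.host_family.f_id == "2004.1.1.71"
        assert e.insert_family.f_id == "3949.1.1.1"
        assert e.host_length == 344 and e.insert_length == 65
        assert e.cross_h_group  # 2004.1 vs 3949.1

    def test_side_by_side_yields_two_events_one_host(self, side_by_side_protein):
        events = assign_events(side_by_side_protein)
        assert {(e.host_uid, e.insert_uid) for e in events} == {
            ("dA", "dB"),
            ("dA", "dC"),
        }
        assert all(e.depth == 1 for e in events)

    def test_matches_oracle_on_fixtures(
        self, mod5_protein, nested_protein, side_by_side_protein
    ):
        for p in (mod5_protein, nested_protein, side_by_side_protein):
            got = {(e.host_uid, e.insert_uid) for e in assign_events(p)}
            assert got == oracle_assignments(p)


class TestNestingDepth:
    def test_nested_depths(self, nested_protein):
        events, max_depth = compute_nesting_depths(assign_events(nested_protein))
        depths = {(e.host_uid, e.insert_uid): e.depth for e in events}
        assert depths == {("dA", "dB"): 1, ("dB", "dC"): 2}
        assert max_depth == 2

    def test_single_insertion_depth_one(self, mod5_protein):
        events, max_depth = compute_nesting_depths(assign_events(mod5_protein))
        assert [e.depth for e in events] == [1] and max_depth == 1

    @pytest.mark.parametrize("k", range(1, 9))
    def test_constructed_k_level_nest_has_depth_k(self, k):
        events, max_depth = compute_nesting_depths(
            assign_events(make_nested_protein(k))
        )
        assert max_depth == k
        assert sorted(e.depth for e in events) == list(range(1, k + 1))


class TestRelativePosition:
    def test_worked_example_position(self, mod5_protein):
        (e,) = assign_events(mod5_protein)
        assert e.relative_position == pytest.approx(111 / 344)
        assert position_third(e.relative_position) == "N-terminal"

    def test_near_n_terminal_limit(self):
        host = _dom([(1, 1), (40, 200)])
        gap = enumerate_gaps(host)[0]
        assert relative_position(host, gap) == pytest.approx(1 / 162)

    def test_symmetric_host_is_middle(self):
        host = _dom([(1, 100), (201, 300)])
        gap = enumerate_gaps(host)[0]
        assert relative_position(host, gap) == 0.5
        assert position_third(0.5) == "middle"

    def test_thirds_boundaries_half_open(self):
        assert position_third(1 / 3) == "middle"
        assert position_third(2 / 3) == "C-terminal"
        assert position_third(0.0) == "N-terminal"
        assert position_third(1.0) == "C-terminal"


class TestDetectAll:
    def test_summary_over_mixed_fixture_set(
        self, mod5_protein, nested_protein
    ):
        linear = make_protein(
            "LIN", [("a", "1.1.1.1", [(1, 100)]), ("b", "2.1.1.1", [(110, 250)])]
        )
        events, s = detect_all([mod5_protein, nested_protein, linear])
        assert s.n_events == 3
        assert s.n_proteins == 3 and s.n_multidomain == 3
        assert s.n_proteins_with_insertion == 2
        assert s.prevalence == pytest.approx(2 / 3)
        # families counted once each across roles
        assert s.n_unique_families_in_events == 5
        assert s.depth_histogram == {1: 1, 2: 1}

    def test_all_single_domain_input_flags_undefined_prevalence(self):
        singles = [
            make_protein(f"S{i}", [("a", "1.1.1.1", [(1, 100)])]) for i in range(3)
        ]
        events, s = detect_all(singles)
        assert events == [] and s.prevalence == 0.0 and s.prevalence_undefined

    def test_exclusive_assignment_no_insert_repeated(self):
        cfg = SyntheticConfig(n_proteins=200, seed=11, p_nest=0.4, p_multi_insert=0.2)
        proteins, _ = generate_architectures(cfg)
        events, _ = detect_all(proteins)
        per_protein = {}
        for e in events:
            key = (e.protein_id, e.insert_uid)
            assert key not in per_protein, "insert assigned twice"
            per_protein[key] = e

    def test_min_gap_monotonicity(self):
        cfg = SyntheticConfig(n_proteins=150, seed=7)
        proteins, _ = generate_architectures(cfg)
        counts = [len(detect_all(proteins, g)[0]) for g in (30, 40, 60, 100, 200)]
        assert counts == sorted(counts, reverse=True)

    def test_containment_invariant(self):
        cfg = SyntheticConfig(n_proteins=150, seed=23, p_nest=0.3)
        proteins, _ = generate_architectures(cfg)
        events, _ = detect_all(proteins)
        by_pid = {p.protein_id: p for p in proteins}
        for e in events:
            ins = by_pid[e.protein_id].domain(e.insert_uid)
            assert all(
                e.gap.start <= s.start and s.end <= e.gap.end for s in ins.segments
            )


@st.composite
def random_protein(draw):
    """Random multidomain protein: a chain of blocks, some split around
    a sub-block, occasionally recursively."""
    rng_specs = []
    cursor = 1
    n_blocks = draw(st.integers(1, 4))
    uid = [0]

    def block(depth):
        nonlocal cursor
        uid[0] += 1
        my_uid = f"d{uid[0]}"
        f_id = f"{100 + uid[0]}.1.1.1"
        length = draw(st.integers(25, 160))
        split = depth < 2 and length >= 2 and draw(st.booleans())
        if split:
            a1 = draw(st.integers(1, length - 1))
            s1 = (cursor, cursor + a1 - 1)
            cursor = s1[1] + 1 + draw(st.integers(0, 3))
            n_children = draw(st.integers(1, 2))
            for _ in range(n_children):
                block(depth + 1)
                cursor += draw(st.integers(0, 3))
            s2 = (cursor, cursor + (length - a1) - 1)
            cursor = s2[1] + 1
            rng_specs.append((my_uid, f_id, [s1, s2]))
        else:
            rng_specs.append((my_uid, f_id, [(cursor, cursor + length - 1)]))
            cursor += length
        cursor += draw(st.integers(0, 2))

    for _ in range(n_blocks):
        block(0)
    return make_protein("RND", rng_specs)


class TestOracleEquivalence:
    @given(random_protein())
    @settings(max_examples=300, deadline=None)
    def test_assignment_equals_brute_force(self, protein):
        got = {(e.host_uid, e.insert_uid) for e in assign_events(protein)}
        assert got == oracle_assignments(protein)

    @given(random_protein(), st.sampled_from([15, 29, 30, 31, 50]))
    @settings(max_examples=150, deadline=None)
    def test_assignment_equals_brute_force_varied_min_gap(self, protein, min_gap):
        got = {(e.host_uid, e.insert_uid) for e in assign_events(protein, min_gap)}
        assert got == oracle_assignments(protein, min_gap)
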