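"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import pytest

from domainsert.model import (
    DomainInstance,
    FamilyKey,
    ProteinArchitecture,
    ResidueRange,
)


def make_protein(pid, specs):
    """Build a protein from (uid, f_id, [(start, end), ...]) triples."""
    return ProteinArchitecture(
        pid,
        [
            DomainInstance(
                pid, uid, FamilyKey(f_id),
                tuple(ResidueRange(a, b) for a, b in segs),
            )
            for uid, f_id, segs in specs
        ],
    )


def oracle_assignments(protein, min_gap=30):
    """Brute-force insertion assignment, independent of the detector.

    Enumerates every (domain, other-domain-gap) containment directly from
    segment arithmetic and applies minimal-gap-length selection with the
    (length, start, host uid) tie-break.  Returns {(host_uid, insert_uid)}.
    """
    doms = {d.domain_uid: [(s.start, s.end) for s in d.segments] for d in protein.domains}
    gaps = []  # (host_uid, start, end)
    for uid, segs in doms.items():
        for (_, e1), (s2, _) in zip(segs, segs[1:]):
            if (s2 - 1) - (e1 + 1) + 1 >= min_gap:
                gaps.append((uid, e1 + 1, s2 - 1))
    out = set()
    for uid, segs in doms.items():
        containing = [
            g for g in gaps
            if g[0] != uid and all(g[1] <= a and b <= g[2] for a, b in segs)
        ]
        if containing:
            host, s, e = min(containing, key=lambda g: (g[2] - g[1] + 1, g[1], g[0]))
            out.add((host, uid))
    return out


@pytest.fixture
def mod5_protein():
    """P-loop hydrolase host split by a tRNA-modification insert, plus one
    unrelated continuous domain (the worked single-insertion example)."""
    return make_protein(
        "3EPL",
        [
            ("host", "2004.1.1.71", [(1, 111), (177, 409)]),
            ("insert", "3949.1.1.1", [(112, 176)]),
            ("other", "5000.1.1.2", [(420, 520)]),
        ],
    )


@pytest.fixture
def nested_protein():
    """A1-B1-C-B2-A2: B inserted in A, C inserted in B."""
    return make_protein(
        "NESTED",
        [
            ("dA", "100.1.1.1", [(1, 100), (331, 430)]),
            ("dB", "200.1.1.1", [(101, 180), (251, 330)]),
            ("dC", "300.1.1.1", [(181, 250)]),
        ],
    )


@pytest.fixture
def side_by_side_protein():
    """A1-B-C-A2: two independent inserts sharing one gap of A."""
    return make_protein(
        "SIDE",
        [
            ("dA", "100.1.1.1", [(1, 100), (301, 400)]),
            ("dB", "200.1.1.1", [(101, 180)]),
            ("dC", "300.1.1.1", [(201, 300)]),
        ],
    )
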