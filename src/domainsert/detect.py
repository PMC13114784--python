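"""A1-B-A2 insertion event detection.

A host domain is one whose sequence is split into two or more segments;
the stretches between consecutive segments are its *gaps*.  A candidate
insert is any other domain of the same protein whose segments all lie
inside one gap of length >= ``min_gap`` residues.  Each candidate is
assigned exclusively to the smallest gap that fully contains it, so every
domain participates in at most one insertion event per protein; nesting
depth then follows from the host relation (an insert whose host is itself
an assigned insert has depth host-depth + 1).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

from .errors import ConsistencyError
from .model import DomainInstance, FamilyKey, ProteinArchitecture

__all__ = [
    "DEFAULT_MIN_GAP",
    "Gap",
    "InsertionEvent",
    "DetectionSummary",
    "enumerate_gaps",
    "candidate_containments",
    "assign_events",
    "compute_nesting_depths",
    "relative_position",
    "position_third",
    "detect_all",
]

#: Minimum gap length (residues) for a gap to be able to accommodate a
#: folded domain rather than an extended loop; "at least" is inclusive.
DEFAULT_MIN_GAP = 30


@dataclass(frozen=True)
class Gap:
    """A stretch of residues strictly between two consecutive host segments."""

    host_uid: str
    gap_index: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains_domain(self, d: DomainInstance) -> bool:
        return all(self.start <= s.start and s.end <= self.end for s in d.segments)


@dataclass(frozen=True)
class InsertionEvent:
    """One detected A1-B-A2 relation between a host and an inserted domain."""

    protein_id: str
    host_uid: str
    insert_uid: str
    host_family: FamilyKey
    insert_family: FamilyKey
    gap: Gap
    depth: int
    host_length: int
    insert_length: int
    relative_position: float
    cross_h_group: bool
    host_architecture: str | None = None
    insert_architecture: str | None = None

    def key(self) -> tuple[str, str, str]:
        """Identity of the event: (protein, host, insert)."""
        return (self.protein_id, self.host_uid, self.insert_uid)


@dataclass
class DetectionSummary:
    """Aggregate counts over one detection run."""

    n_proteins: int = 0
    n_multidomain: int = 0
    n_proteins_with_insertion: int = 0
    prevalence: float = 0.0
    prevalence_undefined: bool = False
    n_events: int = 0
    n_unique_families_in_events: int = 0
    mean_domains_per_insertion_protein: float = 0.0
    depth_histogram: dict[int, int] = field(default_factory=dict)


def enumerate_gaps(host: DomainInstance, min_gap: int = DEFAULT_MIN_GAP) -> list[Gap]:
    """Gaps of at least ``min_gap`` residues between consecutive segments.

    A continuous domain yields an empty list.  Gap boundaries count
    residues strictly between segments: ``(prev.end + 1, next.start - 1)``.
    """
    gaps: list[Gap] = []
    idx = 0
    for a, b in zip(host.segments, host.segments[1:]):
        start, end = a.end + 1, b.start - 1
        length = end - start + 1
        if length >= min_gap:
            gaps.append(Gap(host.domain_uid, idx, start, end))
            idx += 1
    return gaps


def candidate_containments(
    protein: ProteinArchitecture, min_gap: int = DEFAULT_MIN_GAP
) -> list[tuple[str, Gap]]:
    """All (domain_uid, gap) pairs where the domain lies entirely in the gap.

    A domain may pair with several gaps at this stage; exclusive assignment
    happens in :func:`assign_events`.
    """
    all_gaps = [g for d in protein.domains for g in enumerate_gaps(d, min_gap)]
    pairs: list[tuple[str, Gap]] = []
    for d in protein.domains:
        for g in all_gaps:
            if g.host_uid != d.domain_uid and g.contains_domain(d):
                pairs.append((d.domain_uid, g))
    return pairs


def relative_position(host: DomainInstance, gap: Gap) -> float:
    """Fraction of host residues strictly before the gap, in [0, 1]."""
    before = sum(s.length for s in host.segments if s.end < gap.start)
    return before / host.length


def position_third(p: float) -> str:
    """Bucket a relative position into N-terminal / middle / C-terminal thirds.

    Half-open convention: [0, 1/3) N-terminal, [1/3, 2/3) middle,
    [2/3, 1] C-terminal.
    """
    if p < 1 / 3:
        return "N-terminal"
    if p < 2 / 3:
        return "middle"
    return "C-terminal"


def assign_events(
    protein: ProteinArchitecture, min_gap: int = DEFAULT_MIN_GAP
) -> list[InsertionEvent]:
    """Detect insertion events in one protein with exclusive gap assignment.

    Each insertable domain is assigned to the smallest gap it completely
    occupies (ties: smaller gap start, then host_uid lexicographic), so a
    domain participates in at most one event; several domains may share a
    gap.  Event depths are filled in by recursive nesting computation.
    """
    pairs = candidate_containments(protein, min_gap)
    by_insert: dict[str, list[Gap]] = {}
    for uid, gap in pairs:
        by_insert.setdefault(uid, []).append(gap)

    events: list[InsertionEvent] = []
    for uid in sorted(by_insert):
        gap = min(by_insert[uid], key=lambda g: (g.length, g.start, g.host_uid))
        host = protein.domain(gap.host_uid)
        insert = protein.domain(uid)
        events.append(
            InsertionEvent(
                protein_id=protein.protein_id,
                host_uid=host.domain_uid,
                insert_uid=insert.domain_uid,
                host_family=host.family,
                insert_family=insert.family,
                gap=gap,
                depth=0,
                host_length=host.length,
                insert_length=insert.length,
                relative_position=relative_position(host, gap),
                cross_h_group=host.family.h_group != insert.family.h_group,
                host_architecture=host.architecture_label,
                insert_architecture=insert.architecture_label,
            )
        )
    return compute_nesting_depths(events)[0]


def compute_nesting_depths(
    events: list[InsertionEvent],
) -> tuple[list[InsertionEvent], int]:
    """Fill in recursive nesting depths for one protein's events.

    depth(event) = 1 if the host is not itself an assigned insert, else
    depth(host's own event) + 1.  The host relation is a forest by
    construction; a cycle indicates an assignment bug.

    Returns the events (depths set, input order preserved) and the protein
    maximum depth (0 if no events).
    """
    by_insert = {e.insert_uid: e for e in events}
    memo: dict[str, int] = {}

    def depth_of(uid: str, trail: frozenset[str]) -> int:
        if uid in memo:
            return memo[uid]
        if uid in trail:
            raise ConsistencyError(f"cycle in nesting forest at domain {uid}")
        e = by_insert[uid]
        if e.host_uid in by_insert:
            d = depth_of(e.host_uid, trail | {uid}) + 1
        else:
            d = 1
        memo[uid] = d
        return d

    out = [replace(e, depth=depth_of(e.insert_uid, frozenset())) for e in events]
    max_depth = max((e.depth for e in out), default=0)
    return out, max_depth


def detect_all(
    proteins: list[ProteinArchitecture], min_gap: int = DEFAULT_MIN_GAP
) -> tuple[list[InsertionEvent], DetectionSummary]:
    """Run per-protein detection over a dataset and summarise.

    Prevalence is the fraction of multidomain proteins containing at least
    one insertion event; with zero multidomain proteins it is reported as 0
    with ``prevalence_undefined`` set.  The unique-family count counts each
    family once regardless of role.  The depth histogram bins proteins with
    insertions by their maximum nesting depth.
    """
    events: list[InsertionEvent] = []
    summary = DetectionSummary(n_proteins=len(proteins))
    depth_hist: Counter[int] = Counter()
    n_dom_ins = 0
    for protein in proteins:
        if protein.multidomain:
            summary.n_multidomain += 1
        ev, max_depth = compute_nesting_depths(assign_events(protein, min_gap))
        if ev:
            summary.n_proteins_with_insertion += 1
            depth_hist[max_depth] += 1
            n_dom_ins += protein.n_domains
            events.extend(ev)
    summary.n_events = len(events)
    fams = {e.host_family.f_id for e in events} | {e.insert_family.f_id for e in events}
    summary.n_unique_families_in_events = len(fams)
    if summary.n_multidomain > 0:
        summary.prevalence = summary.n_proteins_with_insertion / summary.n_multidomain
    else:
        summary.prevalence = 0.0
        summary.prevalence_undefined = True
    if summary.n_proteins_with_insertion:
        summary.mean_domains_per_insertion_protein = (
            n_dom_ins / summary.n_proteins_with_insertion
        )
    summary.depth_histogram = dict(sorted(depth_hist.items()))
    return events, summary
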