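"""Family-level role profiles, H-group categorisation, partnerships and
host-diversity spectrum.

A family appearing in >= ``min_events`` total events is *host-consistent*
if it never appears as an insert, *insertion-consistent* if it never
appears as a host, and *versatile* if it appears in both roles; families
below the threshold are *insufficient* for role assessment.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from statistics import mean

from .detect import InsertionEvent
from .model import FamilyKey

__all__ = [
    "DEFAULT_MIN_EVENTS",
    "GENERALIST_CUTOFF",
    "FamilyRoleProfile",
    "PartnershipRecord",
    "HostDiversityRecord",
    "aggregate_roles",
    "classify_h_groups",
    "partnership_counts",
    "host_diversity",
    "rank_families",
]

DEFAULT_MIN_EVENTS = 10
GENERALIST_CUTOFF = 11

HOST_CONSISTENT = "host_consistent"
INSERTION_CONSISTENT = "insertion_consistent"
VERSATILE = "versatile"
INSUFFICIENT = "insufficient"


@dataclass(frozen=True)
class FamilyRoleProfile:
    family: FamilyKey
    host_events: int
    insert_events: int
    role: str
    mean_length_as_host: float | None
    mean_length_as_insert: float | None

    @property
    def total(self) -> int:
        return self.host_events + self.insert_events


@dataclass(frozen=True)
class PartnershipRecord:
    host_family: FamilyKey
    insert_family: FamilyKey
    count: int

    @property
    def host_h_group(self) -> str:
        return self.host_family.h_group

    @property
    def insert_h_group(self) -> str:
        return self.insert_family.h_group

    @property
    def cross_h_group(self) -> bool:
        return self.host_h_group != self.insert_h_group


@dataclass(frozen=True)
class HostDiversityRecord:
    insert_family: FamilyKey
    n_events: int
    n_distinct_host_h_groups: int
    classification: str  # specialist / intermediate / generalist


def _role(host_events: int, insert_events: int, min_events: int) -> str:
    if host_events + insert_events < min_events:
        return INSUFFICIENT
    if insert_events == 0:
        return HOST_CONSISTENT
    if host_events == 0:
        return INSERTION_CONSISTENT
    return VERSATILE


def aggregate_roles(
    events: list[InsertionEvent],
    min_events: int = DEFAULT_MIN_EVENTS,
    *,
    exclude_t_group_only: bool = False,
) -> list[FamilyRoleProfile]:
    """Aggregate events into per-family role profiles.

    Each event contributes one host tally to its host family and one
    insert tally to its insert family (double-entry: summed host counts ==
    summed insert counts == number of events).  Families classified at
    topology level only are included unless ``exclude_t_group_only``.
    """
    host_n: dict[str, int] = defaultdict(int)
    ins_n: dict[str, int] = defaultdict(int)
    host_len: dict[str, list[int]] = defaultdict(list)
    ins_len: dict[str, list[int]] = defaultdict(list)
    keys: dict[str, FamilyKey] = {}
    for e in events:
        hf, inf = e.host_family, e.insert_family
        host_n[hf.f_id] += 1
        host_len[hf.f_id].append(e.host_length)
        keys[hf.f_id] = hf
        ins_n[inf.f_id] += 1
        ins_len[inf.f_id].append(e.insert_length)
        keys[inf.f_id] = inf
    profiles = []
    for f_id in sorted(keys):
        fam = keys[f_id]
        if exclude_t_group_only and fam.t_group_only:
            continue
        h, i = host_n[f_id], ins_n[f_id]
        profiles.append(
            FamilyRoleProfile(
                family=fam,
                host_events=h,
                insert_events=i,
                role=_role(h, i, min_events),
                mean_length_as_host=mean(host_len[f_id]) if h else None,
                mean_length_as_insert=mean(ins_len[f_id]) if i else None,
            )
        )
    return profiles


def classify_h_groups(
    profiles: list[FamilyRoleProfile],
    min_families: int = 3,
    min_events: int = DEFAULT_MIN_EVENTS,
) -> dict[str, str]:
    """Categorise H-groups by the role mix of their qualifying families.

    An H-group qualifies when it contains at least ``min_families``
    families with >= ``min_events`` events; it is labelled
    ``exclusively_consistent`` (all families role-consistent),
    ``exclusively_versatile``, or ``mixed``.  Others are ``insufficient``.
    """
    by_h: dict[str, list[FamilyRoleProfile]] = defaultdict(list)
    for p in profiles:
        if p.total >= min_events and p.role != INSUFFICIENT:
            by_h[p.family.h_group].append(p)
    out: dict[str, str] = {}
    for h, ps in sorted(by_h.items()):
        if len(ps) < min_families:
            out[h] = INSUFFICIENT
            continue
        roles = {p.role for p in ps}
        if roles <= {HOST_CONSISTENT, INSERTION_CONSISTENT}:
            out[h] = "exclusively_consistent"
        elif roles == {VERSATILE}:
            out[h] = "exclusively_versatile"
        else:
            out[h] = "mixed"
    return out


def partnership_counts(
    events: list[InsertionEvent],
) -> tuple[list[PartnershipRecord], float | None]:
    """Directional (host family, insert family) partnership counts.

    Returns the records sorted by descending count (ties: family IDs) and
    the fraction of events whose host and insert families belong to
    different H-groups (None when there are no events).
    """
    counts: dict[tuple[str, str], int] = defaultdict(int)
    keys: dict[str, FamilyKey] = {}
    n_cross = 0
    for e in events:
        counts[(e.host_family.f_id, e.insert_family.f_id)] += 1
        keys[e.host_family.f_id] = e.host_family
        keys[e.insert_family.f_id] = e.insert_family
        if e.cross_h_group:
            n_cross += 1
    records = [
        PartnershipRecord(keys[h], keys[i], c) for (h, i), c in counts.items()
    ]
    records.sort(key=lambda r: (-r.count, r.host_family.f_id, r.insert_family.f_id))
    frac = n_cross / len(events) if events else None
    return records, frac


def host_diversity(
    events: list[InsertionEvent],
    min_events: int = DEFAULT_MIN_EVENTS,
    generalist_cutoff: int = GENERALIST_CUTOFF,
) -> list[HostDiversityRecord]:
    """Specialist/generalist spectrum of insert families.

    For each family with >= ``min_events`` events as an insert, count the
    distinct host H-groups: 1 -> specialist, >= ``generalist_cutoff`` ->
    generalist, otherwise intermediate.
    """
    n: dict[str, int] = defaultdict(int)
    hosts: dict[str, set[str]] = defaultdict(set)
    keys: dict[str, FamilyKey] = {}
    for e in events:
        f = e.insert_family.f_id
        n[f] += 1
        hosts[f].add(e.host_family.h_group)
        keys[f] = e.insert_family
    out = []
    for f in sorted(n):
        if n[f] < min_events:
            continue
        k = len(hosts[f])
        cls = (
            "specialist"
            if k == 1
            else "generalist" if k >= generalist_cutoff else "intermediate"
        )
        out.append(HostDiversityRecord(keys[f], n[f], k, cls))
    return out


def rank_families(
    profiles: list[FamilyRoleProfile], role: str, top_n: int = 5
) -> list[FamilyRoleProfile]:
    """Top families of a role category, ranked by that role's event count.

    Host-consistent families rank by host events, insertion-consistent by
    insert events, versatile by total; ties break lexicographically on the
    family ID for determinism.
    """
    pool = [p for p in profiles if p.role == role]
    if role == HOST_CONSISTENT:
        metric = lambda p: p.host_events  # noqa: E731
    elif role == INSERTION_CONSISTENT:
        metric = lambda p: p.insert_events  # noqa: E731
    else:
        metric = lambda p: p.total  # noqa: E731
    pool.sort(key=lambda p: (-metric(p), p.family.f_id))
    return pool[:top_n]
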