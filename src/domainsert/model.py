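"""Core types for proteins, domains and hierarchical family identifiers.

Domains are classified in a four-level hierarchy of dot-separated integer
fields (X-group > H-group > T-group > F-group, e.g. ``"2004.1.1.71"``).
A family assigned at topology level only carries an ID ending ``".0.0"``.
Residue coordinates are 1-based and inclusive on both ends throughout; a
discontinuous domain is represented as an ordered list of disjoint segments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import OverlapError, ParseError, ValidationError

__all__ = [
    "ResidueRange",
    "FamilyKey",
    "DomainInstance",
    "ProteinArchitecture",
    "parse_family_id",
    "parse_range_string",
    "format_range_string",
    "domain_length",
]


@dataclass(frozen=True, order=True)
class ResidueRange:
    """A contiguous residue interval, 1-based and inclusive on both ends."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"range start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"reversed range: end {self.end} < start {self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "ResidueRange") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "ResidueRange") -> bool:
        return self.start <= other.end and other.start <= self.end

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"{self.start}-{self.end}"


@dataclass(frozen=True)
class FamilyKey:
    """Hierarchical family identifier with its X/H/T-level prefixes.

    ``t_group_only`` marks domains classified at topology level only,
    i.e. family IDs whose final two fields are both ``"0"``.
    """

    f_id: str

    @property
    def _fields(self) -> tuple[str, ...]:
        return tuple(self.f_id.split("."))

    @property
    def x_group(self) -> str:
        return self._fields[0]

    @property
    def h_group(self) -> str:
        return ".".join(self._fields[:2])

    @property
    def t_group(self) -> str:
        return ".".join(self._fields[:3]) if len(self._fields) >= 3 else self.f_id

    @property
    def t_group_only(self) -> bool:
        f = self._fields
        return len(f) >= 2 and f[-1] == "0" and f[-2] == "0"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.f_id


_FIELD_RE = re.compile(r"^\d+$")


def parse_family_id(f_id: str) -> FamilyKey:
    """Parse a dot-separated hierarchical family ID into a :class:`FamilyKey`.

    Both 4-field and deeper IDs are accepted; the X/H/T prefixes are always
    the first 1/2/3 fields.

    Raises
    ------
    ParseError
        If the string has fewer than two fields or a non-integer field.
    """
    if not isinstance(f_id, str) or not f_id:
        raise ParseError("family ID must be a non-empty string")
    fields = f_id.split(".")
    if len(fields) < 2:
        raise ParseError(f"family ID {f_id!r} has fewer than 2 fields")
    for tok in fields:
        if not _FIELD_RE.match(tok):
            raise ParseError(f"non-integer field {tok!r} in family ID {f_id!r}")
    return FamilyKey(f_id)


def parse_range_string(s: str, *, with_chain: bool = False):
    """Parse a residue-range string like ``"1-111,177-409"``.

    Tokens are comma-separated ``a-b`` intervals, optionally prefixed
    ``CHAIN:``.  A chain prefix, if present, must be identical on every
    token and is stripped.  Segments must be sorted ascending and
    non-overlapping; out-of-order or overlapping input is rejected.

    Returns the list of :class:`ResidueRange`; with ``with_chain=True``
    returns ``(segments, chain_or_None)``.
    """
    if not isinstance(s, str) or not s.strip():
        raise ParseError("empty range string")
    segments: list[ResidueRange] = []
    chain: str | None = None
    for i, raw in enumerate(s.split(",")):
        tok = raw.strip()
        if ":" in tok:
            ch, tok = tok.split(":", 1)
            ch = ch.strip()
            if chain is None:
                chain = ch
            elif ch != chain:
                raise ParseError(f"mixed chains {chain!r} and {ch!r} in {s!r}")
        elif chain is not None:
            raise ParseError(f"token {tok!r} lacks the chain prefix used earlier in {s!r}")
        m = re.match(r"^(\d+)\s*-\s*(\d+)$", tok)
        if not m:
            raise ParseError(f"malformed range token {raw!r} in {s!r}")
        a, b = int(m.group(1)), int(m.group(2))
        if b < a:
            raise ParseError(f"reversed range {a}-{b} in {s!r}")
        seg = ResidueRange(a, b)
        if segments and seg.start <= segments[-1].end:
            raise ParseError(
                f"segments out of order or overlapping at token {raw!r} in {s!r}"
            )
        segments.append(seg)
    if with_chain:
        return segments, chain
    return segments


def format_range_string(segments: list[ResidueRange]) -> str:
    """Canonical textual form of a segment list (inverse of parsing)."""
    return ",".join(f"{r.start}-{r.end}" for r in segments)


@dataclass(frozen=True)
class DomainInstance:
    """One classified domain instance within a protein.

    A discontinuous domain (two or more segments) is a single instance; the
    segments share one ``domain_uid``.  ``length`` counts residues covered
    by the segments only — for a split host, A1 + A2 combined, never the
    intervening gap.
    """

    protein_id: str
    domain_uid: str
    family: FamilyKey
    segments: tuple[ResidueRange, ...]
    architecture_label: str | None = None
    chain: str | None = None

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError(f"domain {self.domain_uid} has no segments")
        object.__setattr__(self, "segments", tuple(self.segments))
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"domain {self.domain_uid}: segments unsorted or overlapping "
                    f"({a} then {b})"
                )

    @property
    def length(self) -> int:
        return sum(r.length for r in self.segments)

    @property
    def discontinuous(self) -> bool:
        return len(self.segments) >= 2

    @property
    def start(self) -> int:
        return self.segments[0].start

    @property
    def end(self) -> int:
        return self.segments[-1].end


def domain_length(d: DomainInstance) -> int:
    """Residues covered by the domain's segments (host = A1 + A2 combined)."""
    return d.length


@dataclass
class ProteinArchitecture:
    """All classified domains of one protein, validated for disjointness."""

    protein_id: str
    domains: list[DomainInstance] = field(default_factory=list)

    def __post_init__(self) -> None:
        uids = [d.domain_uid for d in self.domains]
        if len(set(uids)) != len(uids):
            dup = sorted({u for u in uids if uids.count(u) > 1})
            raise ValidationError(
                f"protein {self.protein_id}: duplicate domain_uid(s) {dup}"
            )
        # Disjointness across domains: sweep all segments by start.
        tagged = sorted(
            ((seg, d.domain_uid) for d in self.domains for seg in d.segments),
            key=lambda t: (t[0].start, t[0].end),
        )
        for (a, ua), (b, ub) in zip(tagged, tagged[1:]):
            if b.start <= a.end:
                raise OverlapError(
                    f"protein {self.protein_id}: domains {ua} and {ub} overlap "
                    f"({a} vs {b})"
                )
        self.domains = sorted(self.domains, key=lambda d: (d.start, d.domain_uid))

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def multidomain(self) -> bool:
        return self.n_domains >= 2

    def domain(self, uid: str) -> DomainInstance:
        for d in self.domains:
            if d.domain_uid == uid:
                return d
        raise KeyError(uid)
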