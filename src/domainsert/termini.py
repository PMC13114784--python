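"""N/C-termini Cα distance analysis.

Inserted domains must bridge both sides of their host's sequence gap, so
their N- and C-termini are expected to sit close in space; host and
background domains carry no such constraint.  This module measures the
Euclidean Cα distance between a domain's first and last residues and
compares the distributions by role, overall and within size bins, using
the Mann-Whitney U test with the rank-biserial effect size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import CaTrace
from .model import DomainInstance

__all__ = [
    "SIZE_BIN_EDGES",
    "TerminiRecord",
    "RoleComparison",
    "termini_distance",
    "size_bin",
    "mann_whitney_rank_biserial",
    "compare_roles",
]

#: Size-bin lower edges: bins of width 50 from 50 to 500, open-ended top,
#: plus a catch-all below 50.
SIZE_BIN_EDGES = list(range(50, 501, 50))

ROLES = ("insert", "host", "background")


def size_bin(length: int) -> str:
    """Label the 50-residue size bin containing ``length`` ("500+" above)."""
    if length < 50:
        return "<50"
    if length >= 500:
        return "500+"
    lo = (length // 50) * 50
    return f"{lo}-{lo + 49}"


@dataclass(frozen=True)
class TerminiRecord:
    domain_uid: str
    role: str  # insert | host | background
    ca_distance: float  # Angstrom
    length: int

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if not (self.ca_distance >= 0):
            raise ValueError("ca_distance must be non-negative")

    @property
    def size_bin(self) -> str:
        return size_bin(self.length)


def termini_distance(trace: CaTrace, domain: DomainInstance) -> float:
    """Cα distance (Å) between the domain's first and last residues.

    For a discontinuous domain these are the first residue of the first
    segment and the last residue of the last segment.

    Raises
    ------
    KeyError
        If either terminal residue has no Cα in the trace; callers
        collecting records skip the domain and record the reason.
    """
    first = domain.segments[0].start
    last = domain.segments[-1].end
    p = trace.coord(first)
    q = trace.coord(last)
    return float(np.linalg.norm(np.asarray(p) - np.asarray(q)))


def mann_whitney_rank_biserial(x, y) -> tuple[float, float, float]:
    """Mann-Whitney U with rank-biserial effect size r = 1 - 2U/(nx*ny).

    U counts pairs where x exceeds y (ties count one half), so x
    stochastically *smaller* than y gives positive r, up to +1 when every
    x lies below every y.  Returns (U, r, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided")
    r = 1.0 - 2.0 * float(u) / (x.size * y.size)
    return float(u), r, float(p)


@dataclass
class RoleComparison:
    comparison: str  # e.g. "insert_vs_background"
    size_bin: str  # "all" for the pooled comparison
    n_x: int
    n_y: int
    median_x: float
    median_y: float
    u: float
    rank_biserial_r: float
    p_value: float
    underpowered: bool  # either sample < 5


def compare_roles(
    records: list[TerminiRecord], min_bin_n: int = 5
) -> list[RoleComparison]:
    """Insert-vs-background and host-vs-background termini comparisons.

    Each comparison is run pooled ("all") and within every size bin
    populated by both roles; bins with either sample below ``min_bin_n``
    are flagged as underpowered.  Empty comparisons are skipped.
    """
    by_role: dict[str, list[TerminiRecord]] = {r: [] for r in ROLES}
    for rec in records:
        by_role[rec.role].append(rec)

    out: list[RoleComparison] = []
    for focal in ("insert", "host"):
        xs, ys = by_role[focal], by_role["background"]
        if not xs or not ys:
            continue
        bins = ["all"] + sorted(
            {r.size_bin for r in xs} & {r.size_bin for r in ys},
            key=lambda b: (-1 if b == "<50" else 999 if b == "500+" else int(b.split("-")[0])),
        )
        for b in bins:
            bx = [r.ca_distance for r in xs if b == "all" or r.size_bin == b]
            by = [r.ca_distance for r in ys if b == "all" or r.size_bin == b]
            if not bx or not by:
                continue
            u, r, p = mann_whitney_rank_biserial(bx, by)
            out.append(
                RoleComparison(
                    comparison=f"{focal}_vs_background",
                    size_bin=b,
                    n_x=len(bx),
                    n_y=len(by),
                    median_x=float(np.median(bx)),
                    median_y=float(np.median(by)),
                    u=u,
                    rank_biserial_r=r,
                    p_value=p,
                    underpowered=min(len(bx), len(by)) < min_bin_n,
                )
            )
    return out
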