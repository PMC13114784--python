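"""Size, position and enrichment statistics for insertion events.

The paired host-vs-insert size comparison uses the Wilcoxon signed-rank
test: exact signed-rank enumeration (dynamic programming over the signed
rank sum, valid with tied ranks) for n <= 25 pairs after zero removal, and
the normal approximation with continuity and tie corrections for larger n.
Fisher's exact test, BH false-discovery control and Spearman correlation
are delegated to scipy.  Enrichment odds ratios use Haldane-Anscombe 0.5
pseudocounts throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .detect import InsertionEvent, position_third
from .families import FamilyRoleProfile

__all__ = [
    "WilcoxonResult",
    "PairedSizeSummary",
    "EnrichmentResult",
    "wilcoxon_signed_rank",
    "paired_size_analysis",
    "family_size_contrast",
    "fisher_exact_two_sided",
    "bh_fdr",
    "architecture_enrichment",
    "xgroup_insert_enrichment",
    "position_distribution",
    "spearman_rho",
]

EXACT_N_MAX = 25


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ : sum of ranks of positive differences
    p_value: float
    n_used: int  # pairs remaining after zero removal
    method: str  # "exact" | "normal" | "undefined"

    @property
    def undefined(self) -> bool:
        return self.method == "undefined"


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for the signed-rank statistic by DP enumeration.

    Enumerates the distribution of W+ over all 2^n sign assignments via
    polynomial convolution.  Ranks may be tied (average ranks, possibly
    half-integer); doubling makes them integral.
    """
    r2 = np.rint(ranks * 2).astype(np.int64)
    total = int(r2.sum())
    # counts[w] = number of sign assignments with doubled W+ == w
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(w_plus * 2))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(differences) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking (Wilcoxon's original
    treatment); absolute values are ranked with average ranks for ties.
    If every difference is zero the test is undefined and flagged rather
    than raised.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0 or np.all(d == 0):
        return WilcoxonResult(math.nan, math.nan, 0, "undefined")
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        return WilcoxonResult(w_plus, _signed_rank_exact_p(ranks, w_plus), n, "exact")
    mu = n * (n + 1) / 4.0
    # variance with tie correction: sum r^2 / 4 over the observed ranks
    sigma2 = float(np.sum(ranks**2)) / 4.0
    z_num = w_plus - mu
    z = (z_num - 0.5 * np.sign(z_num)) / math.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(abs(z))
    return WilcoxonResult(w_plus, float(min(1.0, p)), n, "normal")


@dataclass
class PairedSizeSummary:
    n_pairs: int
    median_insert_length: float | None
    median_host_length: float | None
    fraction_insert_smaller: float | None
    median_size_ratio: float | None  # insert / host
    wilcoxon_statistic: float
    p_value: float
    test_method: str


def paired_size_analysis(events: list[InsertionEvent]) -> PairedSizeSummary:
    """Host-vs-insert size comparison over paired event measurements.

    Reports medians, the fraction of events with insert strictly smaller
    than host, the median insert/host length ratio, and a Wilcoxon
    signed-rank test on the per-event (host - insert) differences.
    """
    if not events:
        return PairedSizeSummary(0, None, None, None, None, math.nan, math.nan, "undefined")
    host = np.array([e.host_length for e in events], dtype=float)
    ins = np.array([e.insert_length for e in events], dtype=float)
    res = wilcoxon_signed_rank(host - ins)
    return PairedSizeSummary(
        n_pairs=len(events),
        median_insert_length=float(np.median(ins)),
        median_host_length=float(np.median(host)),
        fraction_insert_smaller=float(np.mean(ins < host)),
        median_size_ratio=float(np.median(ins / host)),
        wilcoxon_statistic=res.statistic,
        p_value=res.p_value,
        test_method=res.method,
    )


def family_size_contrast(
    profiles: list[FamilyRoleProfile], events: list[InsertionEvent]
) -> dict:
    """Mean domain lengths per role category and the within-family contrast.

    Category means average over all domain instances observed in events
    whose family carries that role.  For families observed in both roles
    (regardless of the role threshold), the within-family contrast is
    mean(length as host) - mean(length as insert), averaged over families.
    """
    role_of = {p.family.f_id: p.role for p in profiles}
    cat_lengths: dict[str, list[int]] = {}
    host_len: dict[str, list[int]] = {}
    ins_len: dict[str, list[int]] = {}
    for e in events:
        cat_lengths.setdefault(role_of[e.host_family.f_id], []).append(e.host_length)
        cat_lengths.setdefault(role_of[e.insert_family.f_id], []).append(e.insert_length)
        host_len.setdefault(e.host_family.f_id, []).append(e.host_length)
        ins_len.setdefault(e.insert_family.f_id, []).append(e.insert_length)
    category_means = {
        cat: float(np.mean(v)) for cat, v in sorted(cat_lengths.items()) if v
    }
    both = sorted(set(host_len) & set(ins_len))
    diffs = [float(np.mean(host_len[f]) - np.mean(ins_len[f])) for f in both]
    return {
        "category_mean_length": category_means,
        "n_families_in_both_roles": len(both),
        "mean_within_family_host_minus_insert": (
            float(np.mean(diffs)) if diffs else None
        ),
    }


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Any zero margin gives p = 1 by convention (scipy's behaviour).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return sps.false_discovery_control(p, method="bh")


@dataclass
class EnrichmentResult:
    group_id: str
    a: int  # group in the focal role (host for architecture mode, insert for X-group mode)
    b: int  # group in the contrast set
    c: int  # other groups, focal role
    d: int  # other groups, contrast set
    log2_or: float = math.nan
    fisher_p: float = math.nan
    fdr_q: float = math.nan
    classification: str = "neutral"
    significant: bool = False


def _log2_or(a, b, c, d, pc=0.5) -> float:
    return math.log2(((a + pc) * (d + pc)) / ((b + pc) * (c + pc)))


def architecture_enrichment(
    events: list[InsertionEvent],
    pseudocount: float = 0.5,
    threshold: float = 0.5,
) -> tuple[list[EnrichmentResult], int]:
    """Per-architecture host-vs-insert role enrichment.

    For each architecture label: a = host-role instances with that label,
    b = insert-role instances with that label, c/d the same over all other
    labels; log2 odds ratio with Haldane-Anscombe pseudocount, positive
    values meaning host enrichment.  |log2OR| > ``threshold`` classifies
    the architecture as host_enriched / insertion_enriched.  Instances
    with no label are excluded; their count is returned alongside.
    """
    host_counts: dict[str, int] = {}
    ins_counts: dict[str, int] = {}
    n_missing = 0
    for e in events:
        for label, counts in (
            (e.host_architecture, host_counts),
            (e.insert_architecture, ins_counts),
        ):
            if label is None:
                n_missing += 1
            else:
                counts[label] = counts.get(label, 0) + 1
    labels = sorted(set(host_counts) | set(ins_counts))
    tot_h = sum(host_counts.values())
    tot_i = sum(ins_counts.values())
    results = []
    for lab in labels:
        a = host_counts.get(lab, 0)
        b = ins_counts.get(lab, 0)
        c, d = tot_h - a, tot_i - b
        lo = _log2_or(a, b, c, d, pseudocount)
        cls = (
            "host_enriched"
            if lo > threshold
            else "insertion_enriched" if lo < -threshold else "neutral"
        )
        results.append(
            EnrichmentResult(lab, a, b, c, d, log2_or=lo,
                             fisher_p=fisher_exact_two_sided(a, b, c, d),
                             classification=cls)
        )
    qs = bh_fdr([r.fisher_p for r in results])
    for r, q in zip(results, qs):
        r.fdr_q = float(q)
        r.significant = q < 0.05
    return results, n_missing


def xgroup_insert_enrichment(
    events: list[InsertionEvent],
    background_x_groups: list[str],
    min_count: int = 10,
    pseudocount: float = 0.5,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-X-group insert-role enrichment/depletion against a background.

    ``background_x_groups`` is the X-group of every classified domain
    instance in the background universe.  For each X-group with at least
    ``min_count`` background instances: a = insert-role instances in the
    group, b = background instances in the group, c/d = the same outside
    it.  log2 enrichment is the pseudocounted odds ratio of insert share
    vs background share (positive = enriched as insert); significance by
    Fisher + BH FDR < ``alpha``.
    """
    ins_counts: dict[str, int] = {}
    for e in events:
        x = e.insert_family.x_group
        ins_counts[x] = ins_counts.get(x, 0) + 1
    bg_counts: dict[str, int] = {}
    for x in background_x_groups:
        bg_counts[x] = bg_counts.get(x, 0) + 1
    tot_i = sum(ins_counts.values())
    tot_b = sum(bg_counts.values())
    results = []
    for x in sorted(bg_counts):
        if bg_counts[x] < min_count:
            continue
        a = ins_counts.get(x, 0)
        b = bg_counts[x]
        c, d = tot_i - a, tot_b - b
        lo = _log2_or(a, b, c, d, pseudocount)
        cls = "insert_enriched" if lo > 0 else "insert_depleted" if lo < 0 else "neutral"
        results.append(
            EnrichmentResult(x, a, b, c, d, log2_or=lo,
                             fisher_p=fisher_exact_two_sided(a, b, c, d),
                             classification=cls)
        )
    qs = bh_fdr([r.fisher_p for r in results])
    for r, q in zip(results, qs):
        r.fdr_q = float(q)
        r.significant = q < alpha
    return results


def position_distribution(events: list[InsertionEvent]) -> dict:
    """Fractions of insertion positions in N-terminal/middle/C-terminal
    thirds of the host, plus the mean relative position."""
    if not events:
        return {"n": 0, "fractions": None, "mean_position": None}
    buckets = {"N-terminal": 0, "middle": 0, "C-terminal": 0}
    for e in events:
        buckets[position_third(e.relative_position)] += 1
    n = len(events)
    return {
        "n": n,
        "fractions": {k: v / n for k, v in buckets.items()},
        "mean_position": float(np.mean([e.relative_position for e in events])),
    }


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns (rho, p).  A constant input vector makes the coefficient
    undefined; (nan, nan) is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
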