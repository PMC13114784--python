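"""Statistics: Wilcoxon, Fisher, FDR, enrichment, positions, Spearman."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from domainsert.detect import Gap, InsertionEvent
from domainsert.model import FamilyKey
from domainsert.stats import (
    architecture_enrichment,
    bh_fdr,
    family_size_contrast,
    fisher_exact_two_sided,
    paired_size_analysis,
    position_distribution,
    spearman_rho,
    wilcoxon_signed_rank,
    xgroup_insert_enrichment,
)


def brute_wilcoxon_p(diffs):
    """Two-sided signed-rank p by explicit 2^n sign enumeration."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([0, 1], repeat=n)
    ]
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(p_le, p_ge))


def brute_fisher_p(a, b, c, d, tol=1e-12):
    """Two-sided Fisher p by hypergeometric enumeration over one margin."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {
        k: math.comb(c1, k) * math.comb(n - c1, r1 - k) / math.comb(n, r1)
        for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + tol))


def _ev(host_len, ins_len, host_f="1.1.1.1", ins_f="2.1.1.1",
        host_arch=None, ins_arch=None, pos=0.5, pid="p"):
    return InsertionEvent(
        protein_id=pid, host_uid="h", insert_uid="i",
        host_family=FamilyKey(host_f), insert_family=FamilyKey(ins_f),
        gap=Gap("h", 0, 10, 100), depth=1,
        host_length=host_len, insert_length=ins_len,
        relative_position=pos,
        cross_h_group=True,
        host_architecture=host_arch, insert_architecture=ins_arch,
    )


class TestWilcoxon:
    def test_all_zero_differences_undefined(self):
        res = wilcoxon_signed_rank([0, 0, 0])
        assert res.undefined and math.isnan(res.p_value)

    def test_n6_all_positive_exact(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 64)
        assert res.statistic == 21.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.integers(-5, 6, size=rng.integers(4, 11))
        if np.all(d == 0):
            d[0] = 1
        res = wilcoxon_signed_rank(d)
        assert res.p_value == pytest.approx(brute_wilcoxon_p(d), abs=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            d = rng.normal(size=12)  # continuous: no ties, no zeros
            ours = wilcoxon_signed_rank(d)
            theirs = sps.wilcoxon(d, method="exact").pvalue
            assert ours.p_value == pytest.approx(theirs, abs=1e-12)

    def test_exact_and_approx_agree_at_boundary(self):
        # same data pushed through both paths at n = 25
        rng = np.random.default_rng(3)
        d = rng.normal(loc=0.3, size=25)
        exact = wilcoxon_signed_rank(d)
        assert exact.method == "exact"
        approx = sps.wilcoxon(d, method="approx", correction=True).pvalue
        assert exact.p_value == pytest.approx(approx, rel=0.10)

    def test_large_n_shifted_sample_significant(self):
        rng = np.random.default_rng(8)
        d = rng.normal(loc=1.0, size=300)
        res = wilcoxon_signed_rank(d)
        assert res.method == "normal" and res.p_value < 1e-10


class TestPairedSizes:
    def test_worked_three_event_summary(self):
        events = [_ev(200, 100), _ev(150, 160), _ev(300, 120)]
        s = paired_size_analysis(events)
        assert s.fraction_insert_smaller == pytest.approx(2 / 3)
        assert s.median_size_ratio == pytest.approx(0.5)

    def test_single_event_medians(self):
        s = paired_size_analysis([_ev(199, 115)])
        assert s.median_host_length == 199 and s.median_insert_length == 115

    def test_empty_events(self):
        s = paired_size_analysis([])
        assert s.n_pairs == 0 and s.median_host_length is None


class TestFamilySizeContrast:
    def test_within_family_difference(self):
        # family 9.1.1.1 as host twice (200, 220) and insert once (120)
        events = [
            _ev(200, 50, host_f="9.1.1.1", ins_f="2.1.1.1"),
            _ev(220, 60, host_f="9.1.1.1", ins_f="3.1.1.1"),
            _ev(400, 120, host_f="4.1.1.1", ins_f="9.1.1.1"),
        ]
        from domainsert.families import aggregate_roles

        out = family_size_contrast(aggregate_roles(events), events)
        assert out["n_families_in_both_roles"] == 1
        assert out["mean_within_family_host_minus_insert"] == pytest.approx(90.0)

    def test_absent_categories_not_reported(self):
        events = [_ev(200, 100)]
        from domainsert.families import aggregate_roles

        out = family_size_contrast(aggregate_roles(events), events)
        assert set(out["category_mean_length"]) == {"insufficient"}


class TestFisher:
    def test_matches_enumeration_on_sampled_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
            assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
                brute_fisher_p(a, b, c, d), abs=1e-12
            )

    def test_empty_margin_is_one(self):
        assert fisher_exact_two_sided(0, 0, 5, 5) == 1.0

    def test_diagonal_table(self):
        assert fisher_exact_two_sided(5, 0, 0, 5) == pytest.approx(2 / 252)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 2, 3, 4)


class TestBhFdr:
    def test_hand_computed_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_monotone_and_permutation_invariant(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=40)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        perm = rng.permutation(40)
        assert bh_fdr(p[perm]) == pytest.approx(q[perm])


class TestArchitectureEnrichment:
    def test_balanced_architecture_neutral(self):
        events = [_ev(200, 100, host_arch="a.12", ins_arch="a.12") for _ in range(10)]
        results, _ = architecture_enrichment(events)
        (r,) = results
        assert r.log2_or == 0.0 and r.classification == "neutral"

    def test_insertion_enriched_arithmetic(self):
        # a.19: 1 host vs 8 insert; other labels 8 host vs 1 insert
        events = [_ev(200, 100, host_arch="a.19", ins_arch="a.12")] + [
            _ev(200, 100, host_arch="a.12", ins_arch="a.19") for _ in range(8)
        ]
        results, _ = architecture_enrichment(events)
        r = {x.group_id: x for x in results}["a.19"]
        assert r.log2_or == pytest.approx(math.log2((1.5 * 1.5) / (8.5 * 8.5)))
        assert r.classification == "insertion_enriched"

    def test_host_heavy_architecture_positive(self):
        events = [_ev(200, 100, host_arch="a.12", ins_arch="a.19") for _ in range(9)]
        results, _ = architecture_enrichment(events)
        by = {x.group_id: x for x in results}
        assert by["a.12"].log2_or > 0 > by["a.19"].log2_or

    def test_antisymmetric_under_role_swap(self):
        rng = np.random.default_rng(2)
        labels = ["a.2", "a.9", "a.17"]
        events = [
            _ev(200, 100, host_arch=str(rng.choice(labels)),
                ins_arch=str(rng.choice(labels)))
            for _ in range(60)
        ]
        fwd = {r.group_id: r.log2_or for r in architecture_enrichment(events)[0]}
        swapped = [
            _ev(200, 100, host_arch=e.insert_architecture,
                ins_arch=e.host_architecture)
            for e in events
        ]
        rev = {r.group_id: r.log2_or for r in architecture_enrichment(swapped)[0]}
        for lab in fwd:
            assert fwd[lab] == pytest.approx(-rev[lab])

    def test_missing_labels_counted(self):
        events = [_ev(200, 100, host_arch=None, ins_arch="a.2")]
        _, n_missing = architecture_enrichment(events)
        assert n_missing == 1


class TestXGroupEnrichment:
    def test_zero_insert_group_depleted(self):
        events = [_ev(200, 100, ins_f="1.1.1.1") for _ in range(30)]
        background = ["1"] * 30 + ["7"] * 30
        by = {
            r.group_id: r
            for r in xgroup_insert_enrichment(events, background, min_count=10)
        }
        assert by["7"].a == 0
        assert by["7"].log2_or < 0
        assert by["7"].classification == "insert_depleted"

    def test_background_matched_group_neutral(self):
        events = [_ev(200, 100, ins_f="1.1.1.1")] * 5 + [
            _ev(200, 100, ins_f="7.1.1.1")
        ] * 5
        background = ["1"] * 50 + ["7"] * 50
        by = {
            r.group_id: r
            for r in xgroup_insert_enrichment(events, background, min_count=10)
        }
        assert by["1"].log2_or == pytest.approx(0.0, abs=0.05)

    def test_enriched_group_recovered(self):
        # group "9" inserts at 8x its background share
        rng = np.random.default_rng(4)
        background = ["9"] * 20 + [str(i) for i in rng.integers(10, 40, size=380)]
        events = [_ev(200, 100, ins_f="9.1.1.1") for _ in range(100)] + [
            _ev(200, 100, ins_f=f"{i}.1.1.1") for i in rng.integers(10, 40, size=140)
        ]
        by = {
            r.group_id: r
            for r in xgroup_insert_enrichment(events, background, min_count=10)
        }
        assert by["9"].log2_or > 2.0 and by["9"].significant


class TestPositions:
    def test_even_thirds(self):
        events = [_ev(200, 100, pos=p) for p in (0.1, 0.5, 0.9)]
        out = position_distribution(events)
        assert out["fractions"] == {
            "N-terminal": pytest.approx(1 / 3),
            "middle": pytest.approx(1 / 3),
            "C-terminal": pytest.approx(1 / 3),
        }
        assert out["mean_position"] == pytest.approx(0.5)

    def test_boundary_goes_to_middle(self):
        out = position_distribution([_ev(200, 100, pos=1 / 3)])
        assert out["fractions"]["middle"] == 1.0

    def test_uniform_positions_near_equal_thirds(self):
        rng = np.random.default_rng(9)
        events = [_ev(200, 100, pos=float(p)) for p in rng.uniform(size=3000)]
        out = position_distribution(events)
        for frac in out["fractions"].values():
            assert frac == pytest.approx(1 / 3, abs=0.03)
        assert sum(out["fractions"].values()) == pytest.approx(1.0)


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_rho([1, 2, 3, 4], [8, 6, 4, 2])
        assert rho == pytest.approx(-1.0)

    def test_constant_vector_undefined(self):
        rho, p = spearman_rho([1, 1, 1], [2, 3, 4])
        assert math.isnan(rho) and math.isnan(p)

    def test_ties_match_brute_force_ranks(self):
        x = [1, 2, 2, 3, 5]
        y = [4, 4, 6, 7, 9]
        rho, _ = spearman_rho(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected)
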