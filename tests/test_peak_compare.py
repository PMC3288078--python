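import pytest

from chromintegrate.genomic_model import (
    Condition,
    GenomicInterval,
    Mark,
    PeakSet,
    Strand,
    TssRecord,
)
from chromintegrate.peak_compare import (
    EXTENSION_BOTH,
    EXTENSION_DOWN,
    EXTENSION_NONE,
    EXTENSION_UP,
    CommonPeakComponent,
    compare_conditions,
    extension_call,
    length_summary,
    replicated_peaks,
)
from conftest import random_intervals
from oracles import components_bruteforce, replicated_bruteforce


def ps(intervals, condition=Condition.MINUS, mark=Mark.H3AC):
    return PeakSet(mark, condition, intervals)


def iv(start, end, seq="chr1"):
    return GenomicInterval(seq, start, end)


class TestReplicatedPeaks:
    def test_reference_interval_kept_whole(self):
        out = replicated_peaks(ps([iv(0, 100)]), ps([iv(50, 60)]))
        assert out.intervals == [iv(0, 100)]

    def test_no_overlap_empty(self):
        out = replicated_peaks(ps([iv(0, 100)]), ps([iv(200, 300)]))
        assert len(out) == 0

    def test_mark_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            replicated_peaks(ps([iv(0, 10)]), ps([iv(0, 10)], mark=Mark.SP1))

    def test_symmetric_flag_unions_both_directions(self):
        r1, r2 = ps([iv(0, 100)]), ps([iv(90, 200), iv(500, 600)])
        asym = replicated_peaks(r1, r2)
        sym = replicated_peaks(r1, r2, symmetric=True)
        assert asym.intervals == [iv(0, 100)]
        assert sym.intervals == [iv(0, 200)]

    def test_min_overlap_threshold(self):
        r1, r2 = ps([iv(0, 100)]), ps([iv(95, 200)])
        assert len(replicated_peaks(r1, r2, min_overlap_bp=5)) == 1
        assert len(replicated_peaks(r1, r2, min_overlap_bp=6)) == 0

    def test_agrees_with_quadratic_oracle(self, rng):
        for _ in range(4):
            r1 = ps(random_intervals(rng, 500, span=5000, max_len=40))
            r2 = ps(random_intervals(rng, 500, span=5000, max_len=40))
            got = replicated_peaks(r1, r2)
            assert got.intervals == replicated_bruteforce(
                r1.intervals, r2.intervals
            )


class TestCompareConditions:
    def test_simple_pair(self):
        res = compare_conditions(
            ps([iv(100, 200)]), ps([iv(150, 400)], Condition.PLUS)
        )
        assert len(res.components) == 1
        assert len(res.unique_minus) == 0 and len(res.unique_plus) == 0
        s = length_summary(res)
        assert s["mean_len_common_minus"] == 100
        assert s["mean_len_common_plus"] == 250

    def test_many_to_one_chain(self):
        res = compare_conditions(
            ps([iv(0, 50), iv(60, 100)]), ps([iv(40, 70)], Condition.PLUS)
        )
        assert len(res.components) == 1
        (c,) = res.components
        assert len(c.members_minus) == 2 and len(c.members_plus) == 1

    def test_partition_property(self, rng):
        minus = ps(random_intervals(rng, 300, span=4000, max_len=50))
        plus = ps(random_intervals(rng, 300, span=4000, max_len=50),
                  Condition.PLUS)
        res = compare_conditions(minus, plus)
        got_minus = sorted(res.common_minus_peaks + list(res.unique_minus))
        got_plus = sorted(res.common_plus_peaks + list(res.unique_plus))
        assert got_minus == list(minus.intervals)
        assert got_plus == list(plus.intervals)

    def test_symmetric_under_condition_swap(self, rng):
        a = ps(random_intervals(rng, 200, span=3000, max_len=50))
        b = ps(random_intervals(rng, 200, span=3000, max_len=50), Condition.PLUS)
        res = compare_conditions(a, b)
        swapped = compare_conditions(
            ps(list(b.intervals)), ps(list(a.intervals), Condition.PLUS)
        )
        assert sorted(res.unique_minus) == sorted(swapped.unique_plus.intervals)
        assert sorted(res.unique_plus) == sorted(swapped.unique_minus.intervals)
        assert len(res.components) == len(swapped.components)

    def test_agrees_with_union_find_oracle(self, rng):
        for _ in range(5):
            minus = ps(random_intervals(rng, 100, span=2500, max_len=40))
            plus = ps(random_intervals(rng, 100, span=2500, max_len=40),
                      Condition.PLUS)
            res = compare_conditions(minus, plus)
            comps, um, up = components_bruteforce(
                list(minus.intervals), list(plus.intervals)
            )
            got = {
                frozenset(
                    [("m", i) for i in c.members_minus]
                    + [("p", i) for i in c.members_plus]
                )
                for c in res.components
            }
            assert got == set(comps)
            assert sorted(res.unique_minus) == um
            assert sorted(res.unique_plus) == up

    def test_every_member_has_cross_condition_partner(self, rng):
        minus = ps(random_intervals(rng, 200, span=2000, max_len=40))
        plus = ps(random_intervals(rng, 200, span=2000, max_len=40),
                  Condition.PLUS)
        for c in compare_conditions(minus, plus).components:
            for m in c.members_minus:
                assert any(m.overlaps(p) for p in c.members_plus)
            for p in c.members_plus:
                assert any(p.overlaps(m) for m in c.members_minus)

    def test_component_count_bound(self, rng):
        minus = ps(random_intervals(rng, 150, span=1500, max_len=40))
        plus = ps(random_intervals(rng, 150, span=1500, max_len=40),
                  Condition.PLUS)
        res = compare_conditions(minus, plus)
        assert len(res.components) <= min(
            len(res.common_minus_peaks), len(res.common_plus_peaks)
        )


def component(minus_iv, plus_iv):
    return CommonPeakComponent(members_minus=[minus_iv], members_plus=[plus_iv])


def gene(pos=3000, strand="+"):
    return TssRecord("g", "chr1", pos, Strand(strand))


class TestExtensionCall:
    def test_upstream_growth_plus_strand(self):
        c = component(iv(3000, 3500), iv(2500, 3500))
        assert extension_call(c, gene(), 200) == EXTENSION_UP

    def test_equal_extents(self):
        c = component(iv(3000, 3500), iv(3000, 3500))
        assert extension_call(c, gene(), 200) == EXTENSION_NONE

    def test_downstream_growth_plus_strand(self):
        c = component(iv(3000, 3500), iv(3000, 4000))
        assert extension_call(c, gene(), 200) == EXTENSION_DOWN

    def test_both_sides(self):
        c = component(iv(3000, 3500), iv(2500, 4000))
        assert extension_call(c, gene(), 200) == EXTENSION_BOTH

    def test_strand_flips_direction(self):
        c = component(iv(3000, 3500), iv(2500, 3500))
        assert extension_call(c, gene(3400, "-"), 200) == EXTENSION_DOWN

    def test_below_threshold_is_none(self):
        c = component(iv(3000, 3500), iv(2900, 3500))
        assert extension_call(c, gene(), 200) == EXTENSION_NONE

    def test_shrinkage_never_yields_direction(self):
        c = component(iv(2500, 4000), iv(3000, 3500))
        assert extension_call(c, gene(), 1) == EXTENSION_NONE

    def test_seq_mismatch_errors(self):
        c = component(iv(3000, 3500), iv(2500, 3500))
        with pytest.raises(ValueError):
            extension_call(c, TssRecord("g", "chr2", 3000, Strand.PLUS), 200)

    def test_planted_containment_never_none_when_grown(self, rng):
        """minus subset of plus with growth >= threshold on some side."""
        for _ in range(100):
            s, e = 5000, 5000 + int(rng.integers(200, 2000))
            left = int(rng.integers(0, 500))
            right = int(rng.integers(0, 500))
            if max(left, right) < 200:
                continue
            c = component(iv(s, e), iv(s - left, e + right))
            assert extension_call(c, gene(), 200) != EXTENSION_NONE


class TestLengthSummary:
    def test_single_pair_ratio(self):
        res = compare_conditions(
            ps([iv(100, 200)]), ps([iv(100, 350)], Condition.PLUS)
        )
        assert length_summary(res)["widening_ratio"] == pytest.approx(2.5)

    def test_empty_classes_not_available(self):
        res = compare_conditions(ps([]), ps([], Condition.PLUS))
        s = length_summary(res)
        assert s["mean_len_common_minus"] is None
        assert s["mean_len_unique_plus"] is None
        assert s["widening_ratio"] is None
        assert s["n_components"] == 0
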