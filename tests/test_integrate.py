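import pytest

from chromintegrate.diffexpr import DEResult
from chromintegrate.genomic_model import (
    Condition,
    GenomicInterval,
    Mark,
    PeakSet,
    Strand,
    TssRecord,
    make_promoter_window,
)
from chromintegrate.integrate import (
    TssFeatureProfile,
    build_profile,
    classify_group,
    colocalization_summary,
    consistency_score,
    gene_rollup,
    intragenic_unique_analysis,
)
from chromintegrate.peak_compare import compare_conditions
from oracles import overlaps_bruteforce


def iv(start, end, seq="chr1"):
    return GenomicInterval(seq, start, end)


def gene(pos=10_000, strand="+", gid="g1", exons=None):
    return TssRecord(gid, "chr1", pos, Strand(strand), exons or [])


def cmp_result(minus_ivs, plus_ivs, mark=Mark.H3AC):
    return compare_conditions(
        PeakSet(mark, Condition.MINUS, minus_ivs),
        PeakSet(mark, Condition.PLUS, plus_ivs),
    )


def de(call="up", fc=4.0, p=0.001, gid="g1"):
    import math

    return DEResult(gid, math.log2(abs(fc)), fc, p, call)


class TestBuildProfile:
    def test_chemokine_style_profile(self):
        """No promoter acetylation, stimulated-only polymerase, TATA."""
        g = gene()
        s5p_plus = PeakSet(Mark.S5P, Condition.PLUS, [iv(9800, 10_300)])
        p = build_profile(
            g, cmp_result([], []), s5p_plus=s5p_plus, tata=True, de=de(fc=29.59)
        )
        assert not p.h3ac_common
        assert p.extension == "-"
        assert p.s5p_status == "+LPS"
        assert p.sp1_status == "NO"
        assert not p.cpg and p.tata
        assert p.group == "1"

    def test_tnf_style_profile(self):
        """Common acetylation widened both ways, unstimulated polymerase."""
        g = gene()
        h3 = cmp_result([iv(9000, 11_000)], [iv(8000, 12_000)])
        s5p_minus = PeakSet(Mark.S5P, Condition.MINUS, [iv(9800, 10_300)])
        p = build_profile(g, h3, s5p_minus=s5p_minus, tata=True, de=de(fc=47.23))
        assert p.h3ac_common and p.extension == "↔"
        assert p.s5p_status == "-LPS"
        assert not p.cpg and p.tata
        assert p.group == "2"

    def test_empty_tracks_all_negative(self):
        p = build_profile(gene(), cmp_result([], []))
        assert (p.h3ac_common, p.extension, p.s5p_status, p.sp1_status,
                p.cpg, p.tata, p.group) == (
            False, "-", "NO", "NO", False, False, "unassigned")

    def test_component_outside_window_ignored(self):
        h3 = cmp_result([iv(50_000, 51_000)], [iv(50_000, 52_000)])
        p = build_profile(gene(), h3, de=de())
        assert not p.h3ac_common and p.group == "1"

    def test_largest_overlap_component_wins(self, caplog):
        # two components touch the window; the bigger-overlap one (no
        # growth) dictates the extension call
        h3 = cmp_result(
            [iv(9000, 11_000), iv(7500, 8200)],
            [iv(9000, 11_000), iv(6500, 8200)],
        )
        p = build_profile(gene(), h3, de=de())
        assert p.h3ac_common and p.extension == "-"

    def test_both_conditions_status(self):
        g = gene()
        sm = PeakSet(Mark.SP1, Condition.MINUS, [iv(9900, 10_100)])
        sp = PeakSet(Mark.SP1, Condition.PLUS, [iv(9900, 10_100)])
        p = build_profile(g, cmp_result([], []), sp1_minus=sm, sp1_plus=sp)
        assert p.sp1_status == "+/-LPS"

    def test_extension_requires_component(self):
        with pytest.raises(ValueError):
            TssFeatureProfile("g", gene(), h3ac_common=False, extension="→")


class TestClassifyGroup:
    def test_tiebreak_promoter_acetylation_decides(self):
        """Class-1-looking secondary features but promoter acetylation
        present and regulated: class 2."""
        p = TssFeatureProfile(
            "IL1B-like", gene(), de=de(fc=2.12), h3ac_common=True,
            extension="←", s5p_status="NO", sp1_status="NO",
            cpg=False, tata=True,
        )
        assert classify_group(p) == "2"

    def test_no_promoter_acetylation_is_group1(self):
        p = TssFeatureProfile("x", gene(), de=de(), h3ac_common=False)
        assert classify_group(p) == "1"

    def test_unregulated_gene_unassigned(self):
        p = TssFeatureProfile("x", gene(), de=de(call="null", fc=1.1, p=0.5),
                              h3ac_common=True)
        assert classify_group(p) == "unassigned"

    def test_pure_function_of_call_and_h3ac(self):
        """Permuting secondary features never changes the class."""
        for cpg in (True, False):
            for tata in (True, False):
                for s5p in ("NO", "-LPS", "+LPS", "+/-LPS"):
                    p = TssFeatureProfile(
                        "x", gene(), de=de(), h3ac_common=True,
                        s5p_status=s5p, cpg=cpg, tata=tata,
                    )
                    assert classify_group(p) == "2"

    def test_consistency_score_range(self):
        p = TssFeatureProfile("x", gene(), de=de(), h3ac_common=True,
                              cpg=True, tata=False, sp1_status="+LPS")
        p.group = classify_group(p)
        assert consistency_score(p) == 1.0
        q = TssFeatureProfile("y", gene(), de=de(), h3ac_common=False,
                              cpg=True, tata=False, sp1_status="+LPS")
        q.group = classify_group(q)
        assert consistency_score(q) == 0.0


class TestGeneRollup:
    def test_mixed_when_tss_disagree(self):
        a = TssFeatureProfile("g", gene(), de=de(), h3ac_common=True)
        a.group = "2"
        b = TssFeatureProfile("g", gene(pos=20_000), de=de(), h3ac_common=False)
        b.group = "1"
        assert gene_rollup([a, b]) == {"g": "mixed"}

    def test_single_class(self):
        a = TssFeatureProfile("g", gene(), de=de(), h3ac_common=True)
        a.group = "2"
        assert gene_rollup([a]) == {"g": "2"}


class TestColocalization:
    def test_unique_plus_full_overlap(self):
        a = cmp_result([], [iv(0, 100)], mark=Mark.S5P)
        b = cmp_result([], [iv(90, 200)])
        out = colocalization_summary(a, b)
        assert out["unique_plus"]["frac_overlapping"] == 1.0

    def test_disjoint_tracks_zero(self):
        a = cmp_result([iv(0, 100)], [iv(0, 100)], mark=Mark.S5P)
        b = cmp_result([iv(10_000, 10_100)], [iv(10_000, 10_100)])
        out = colocalization_summary(a, b)
        for row in out.values():
            assert row["frac_overlapping"] == 0.0

    def test_fractions_in_unit_interval_random(self, rng):
        from conftest import random_intervals

        a = cmp_result(
            random_intervals(rng, 80, span=3000, max_len=50),
            random_intervals(rng, 80, span=3000, max_len=50),
            mark=Mark.S5P,
        )
        b = cmp_result(
            random_intervals(rng, 80, span=3000, max_len=50),
            random_intervals(rng, 80, span=3000, max_len=50),
        )
        out = colocalization_summary(a, b)
        for row in out.values():
            assert 0.0 <= row["frac_overlapping"] <= 1.0

    def test_agrees_with_quadratic_oracle_per_class(self, rng):
        from conftest import random_intervals

        a = cmp_result(
            random_intervals(rng, 60, span=2000, max_len=40),
            random_intervals(rng, 60, span=2000, max_len=40),
            mark=Mark.S5P,
        )
        b = cmp_result(
            random_intervals(rng, 60, span=2000, max_len=40),
            random_intervals(rng, 60, span=2000, max_len=40),
        )
        out = colocalization_summary(a, b)
        b_minus = b.all_peaks(Condition.MINUS)
        n = sum(
            1
            for p in a.all_peaks(Condition.MINUS)
            if any(overlaps_bruteforce(p, q) for q in b_minus)
        )
        assert out["all_minus"]["n_overlapping"] == n


class TestIntragenicUnique:
    def _setup(self):
        """Two genes; one with a promoter component, one without; three
        stimulated-unique intragenic peaks, one on a CpG island."""
        exonsA = [iv(10_000, 10_400), iv(18_000, 22_000)]
        gA = gene(10_000, "+", "gA", exonsA)          # open promoter
        exonsB = [iv(60_000, 60_400), iv(68_000, 72_000)]
        gB = gene(60_000, "+", "gB", exonsB)          # closed promoter
        genes = [gA, gB]
        promoters = [make_promoter_window(g, 2000, 1000) for g in genes]
        h3 = cmp_result(
            [iv(9000, 11_000)],
            [iv(9000, 11_500), iv(15_000, 15_400),   # qualifying, open gene
             iv(16_000, 16_400),                     # on CpG -> excluded
             iv(65_000, 65_400)],                    # qualifying, closed gene
        )
        islands = [iv(16_100, 16_300)]
        return h3, genes, promoters, islands

    def test_planted_counts(self):
        h3, genes, promoters, islands = self._setup()
        assert intragenic_unique_analysis(h3, genes, promoters, islands) == (2, 1)

    def test_no_unique_peaks(self):
        genes = [gene(10_000, "+", "gA", [iv(10_000, 10_400), iv(18_000, 22_000)])]
        promoters = [make_promoter_window(g, 2000, 1000) for g in genes]
        h3 = cmp_result([iv(9000, 11_000)], [iv(9000, 11_000)])
        assert intragenic_unique_analysis(h3, genes, promoters, []) == (0, 0)

    def test_synthetic_ground_truth(self, small_sim):
        from chromintegrate import format_io

        genes = format_io.read_gene_models(small_sim.files["genes"])
        promoters = [make_promoter_window(g, 2000, 1000) for g in genes]
        h3 = compare_conditions(
            format_io.read_bed(small_sim.files["h3ac_minus"], Mark.H3AC,
                               Condition.MINUS),
            format_io.read_bed(small_sim.files["h3ac_plus"], Mark.H3AC,
                               Condition.PLUS),
        )
        islands = list(format_io.read_bed(small_sim.files["cpg"]).intervals)
        n_q, n_open = intragenic_unique_analysis(h3, genes, promoters, islands)
        truth = small_sim.peaks
        planted = truth[truth.klass == "intragenic_unique_plus"]
        assert n_q == len(planted)
        open_genes = set(
            small_sim.genes[small_sim.genes.h3ac_common.astype(bool)].gene_id
        )
        assert n_open == planted.gene_id.isin(open_genes).sum()
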