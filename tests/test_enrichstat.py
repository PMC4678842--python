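import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncapeval import datasets
from ncapeval.covstat import DepthTrack
from ncapeval.enrichstat import (
    Contingency2x2,
    EnrichmentReport,
    LocusResult,
    count_on_target,
    fisher_exact,
    flanking_extension,
    report_from_counts,
    round1,
    sensitivity,
    specificity,
    summarize_experiments,
)
from ncapeval.mapper import Alignment
from ncapeval.refmodel import GenomicInterval, TargetSet

from _oracles import fisher_two_sided_exact


def _aln(rid, start, end, ref="g"):
    return Alignment(rid, ref, GenomicInterval(ref, start, end), (0, end - start), "+", end - start, end - start)


TARGETS = TargetSet([("locA", GenomicInterval("g", 1000, 2000)), ("locB", GenomicInterval("g", 5000, 5500))])


class TestCounting:
    def test_alignment_inside_locus_counts(self):
        per, on, off, exc = count_on_target([_aln("a", 1200, 1400)], TARGETS)
        assert per == {"locA": 1, "locB": 0} and (on, off, exc) == (1, 0, 0)

    def test_single_base_overlap_counts(self):
        per, on, off, exc = count_on_target([_aln("a", 999, 1001)], TARGETS)
        assert per["locA"] == 1 and on == 1
        per, on, off, exc = count_on_target([_aln("b", 990, 1000)], TARGETS)
        assert per["locA"] == 0 and off == 1

    def test_exclusion_wins_over_target(self):
        excl = [GenomicInterval("g", 1900, 2100)]
        per, on, off, exc = count_on_target([_aln("a", 1950, 1990)], TARGETS, excl)
        assert exc == 1 and on == 0 and off == 0 and per["locA"] == 0

    def test_read_spanning_two_loci_counted_once_overall(self):
        wide = TargetSet([("x", GenomicInterval("g", 100, 200)), ("y", GenomicInterval("g", 150, 300))])
        per, on, off, exc = count_on_target([_aln("a", 140, 260)], wide)
        assert per == {"x": 1, "y": 1} and on == 1

    def test_count_conservation(self):
        rng = np.random.default_rng(1)
        alns = [_aln(f"r{i}", int(s), int(s) + 100) for i, s in enumerate(rng.integers(0, 9000, 200))]
        excl = [GenomicInterval("g", 8000, 9500)]
        per, on, off, exc = count_on_target(alns, TARGETS, excl)
        assert on + off + exc == len(alns)


class TestSensitivitySpecificity:
    def _track(self, depth):
        return DepthTrack({"g": depth}, total_mapped_reads=100)

    def test_full_coverage_is_100(self):
        per, exp, covered = sensitivity(self._track(np.ones(10_000, dtype=np.int32)), TARGETS)
        assert per == {"locA": 100.0, "locB": 100.0} and exp == 100.0

    def test_zero_alignments_zero_everywhere(self):
        per, exp, covered = sensitivity(self._track(np.zeros(10_000, dtype=np.int32)), TARGETS)
        assert per == {"locA": 0.0, "locB": 0.0} and exp == 0.0

    def test_experiment_sensitivity_pools_bases(self):
        depth = np.zeros(10_000, dtype=np.int32)
        depth[1000:1500] = 2  # half of locA, none of locB
        per, exp, covered = sensitivity(self._track(depth), TARGETS)
        assert per["locA"] == 50.0
        assert exp == pytest.approx(100 * 500 / 1500)

    def test_specificity_definition_and_bounds(self):
        assert specificity(50, 50) == 100.0
        assert specificity(0, 10) == 0.0
        assert specificity(0, 0) == 0.0
        with pytest.raises(ValueError):
            specificity(11, 10)


class TestPublishedTables:
    """The evaluation layer must reproduce the published per-locus table
    and run-level percentages from the printed counts alone."""

    def test_o157_totals(self):
        loci = [LocusResult(l.name, l.reads_on_target, l.target_length_bp, l.bases_covered) for l in datasets.O157_LOCI]
        report = report_from_counts(loci, datasets.O157_TOTAL_MAPPED, name="O157")
        assert report.total_reads_on_loci == 2291
        assert report.total_target_length == 35_825
        assert round1(report.experiment_sensitivity_pct) == 100.0

    def test_k12_totals_sensitivity_and_specificity(self):
        loci = [LocusResult(l.name, l.reads_on_target, l.target_length_bp, l.bases_covered) for l in datasets.K12_LOCI]
        report = report_from_counts(loci, datasets.K12_TOTAL_MAPPED, name="K12")
        assert report.total_reads_on_loci == 251
        assert report.total_bases_covered == 35_511
        assert round1(report.experiment_sensitivity_pct) == 99.2
        assert round1(report.specificity_pct) == 94.7

    def test_lambda_specificity(self):
        assert round1(specificity(datasets.LAMBDA_READS_ON_TARGET, datasets.LAMBDA_TOTAL_MAPPED)) == 95.7

    def test_mean_sensitivity_across_three_experiments(self):
        sens = [100.0, 99.2, 100.0]
        assert round1(float(np.mean(sens))) == 99.7


class TestSummaries:
    def _report(self, on, total, covered, length, name):
        return report_from_counts([LocusResult("x", on, length, covered)], total, name=name)

    def test_single_experiment_mean_equals_pooled(self):
        r = self._report(90, 100, 900, 1000, "a")
        s = summarize_experiments([r])
        assert s["mean_specificity_pct"] == pytest.approx(s["pooled_specificity_pct"])
        assert s["mean_sensitivity_pct"] == pytest.approx(s["pooled_sensitivity_pct"])

    def test_pooled_specificity_is_ratio_of_sums(self):
        r1 = self._report(90, 100, 1000, 1000, "a")
        r2 = self._report(10, 100, 500, 1000, "b")
        s = summarize_experiments([r1, r2])
        assert s["pooled_specificity_pct"] == pytest.approx(100 * (90 + 10) / 200)
        assert s["mean_specificity_pct"] == pytest.approx((90.0 + 10.0) / 2)


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_exact(Contingency2x2(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_symmetry_under_row_and_column_swap(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b, c, d = (int(x) + 1 for x in rng.integers(0, 40, 4))
            p = fisher_exact(Contingency2x2(a, b, c, d))
            assert fisher_exact(Contingency2x2(c, d, a, b)) == pytest.approx(p, rel=1e-9)
            assert fisher_exact(Contingency2x2(b, a, d, c)) == pytest.approx(p, rel=1e-9)

    def test_agrees_with_enumeration_oracle_on_small_tables(self):
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 60:
            a, b, c, d = (int(x) for x in rng.integers(0, 9, 4))
            if min(a + b, c + d, a + c, b + d) == 0 or a + b + c + d > 30:
                continue
            got = fisher_exact(Contingency2x2(a, b, c, d))
            expected = fisher_two_sided_exact(a, b, c, d)
            assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)
            checked += 1

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            Contingency2x2(-1, 5, 5, 5)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact(Contingency2x2(0, 0, 5, 5))


class TestFlanking:
    TARGET = GenomicInterval("g", 41_053, 42_370)

    def test_alignment_inside_target_has_zero_flanks(self):
        rows, summary = flanking_extension([_aln("a", 41_100, 42_000)], self.TARGET)
        assert rows == [("a", 0, 0)]
        assert summary["max_extension_bp"] == 0.0

    def test_flank_arithmetic(self):
        rows, _ = flanking_extension([_aln("a", 40_000, 43_500)], self.TARGET)
        assert rows == [("a", 1053, 1130)]

    def test_threshold_count_and_nonoverlapping_ignored(self):
        alns = [_aln("a", 40_000, 43_500), _aln("b", 41_100, 42_000), _aln("c", 100, 200)]
        rows, summary = flanking_extension(alns, self.TARGET, threshold_bp=500)
        assert len(rows) == 2
        assert summary["n_exceeding_threshold"] == 1.0

    def test_empty_summary(self):
        _, summary = flanking_extension([], self.TARGET)
        assert summary["n_reads"] == 0.0


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(95.6980, 95.7), (18.4466, 18.4), (94.7169, 94.7), (99.2454, 99.2), (99.25, 99.3), (-1.25, -1.3)],
    )
    def test_half_away_from_zero(self, value, expected):
        assert round1(value) == expected

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(-1000, 1000))
    def test_round1_within_half_unit(self, x):
        assert abs(round1(x) - x) <= 0.05 + 1e-9


class TestInvariants:
    def test_order_invariance_and_bounds(self):
        rng = np.random.default_rng(4)
        alns = [_aln(f"r{i}", int(s), int(s) + 200) for i, s in enumerate(rng.integers(0, 8000, 100))]
        g_lens = {"g": 10_000}
        from _oracles import naive_depth

        depth = naive_depth(alns, g_lens)
        track = DepthTrack({"g": depth.pop("g").astype(np.int32)}, len(alns))
        per1, on1, off1, exc1 = count_on_target(alns, TARGETS)
        per2, on2, off2, exc2 = count_on_target(list(reversed(alns)), TARGETS)
        assert (per1, on1, off1, exc1) == (per2, on2, off2, exc2)
        _, exp, _ = sensitivity(track, TARGETS)
        assert 0.0 <= exp <= 100.0
        assert 0.0 <= specificity(on1, len(alns)) <= 100.0
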