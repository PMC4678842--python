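import numpy as np
import pytest

from ncapeval import datasets
from ncapeval.mapper import SeedIndex, map_read
from ncapeval.refmodel import GenomicInterval
from ncapeval.simlib import (
    CaptureParams,
    ControlSpec,
    ErrorParams,
    Fragment,
    SimConfig,
    build_library,
    capture,
    sequence_reads,
    shear,
)

from conftest import make_genome


def _frag(start, end, ref="lambda_syn", seq=""):
    return Fragment(GenomicInterval(ref, start, end), seq)


class TestShear:
    def test_zero_fragments(self, lambda_genome):
        cfg = SimConfig(n_fragments=0, seed=1)
        assert shear(lambda_genome, cfg, np.random.default_rng(1)) == []

    def test_degenerate_sd_gives_constant_length(self, lambda_genome):
        cfg = SimConfig(n_fragments=50, frag_mean_bp=5000, frag_sd_bp=0, seed=1)
        frags = shear(lambda_genome, cfg, np.random.default_rng(1))
        assert {f.source.length() for f in frags} == {5000}
        for f in frags:
            assert len(f.sequence) == f.source.length()

    def test_sample_mean_matches_target(self, lambda_genome):
        cfg = SimConfig(n_fragments=10_000, frag_mean_bp=5000, frag_sd_bp=500, seed=2)
        frags = shear(lambda_genome, cfg, np.random.default_rng(2))
        mean = np.mean([f.source.length() for f in frags])
        assert abs(mean - 5000) < 3 * 500 / np.sqrt(10_000)

    def test_mean_exceeding_reference_rejected(self):
        g = make_genome(2000, seed=3)
        with pytest.raises(ValueError, match="longest reference"):
            shear(g, SimConfig(n_fragments=10, frag_mean_bp=5000), np.random.default_rng(0))

    def test_deterministic_under_fixed_seed(self, lambda_genome):
        cfg = SimConfig(n_fragments=100, seed=9)
        a = shear(lambda_genome, cfg, np.random.default_rng(9))
        b = shear(lambda_genome, cfg, np.random.default_rng(9))
        assert [f.source for f in a] == [f.source for f in b]


class TestCapture:
    def test_limit_cases(self, lambda_baits_M):
        cp = CaptureParams(p_max=1.0, p_background=0.0)
        rng = np.random.default_rng(0)
        containing = [_frag(40_000, 45_000)] * 50  # fully contains a bait
        disjoint = [_frag(1000, 6000)] * 50
        assert len(capture(containing, lambda_baits_M, cp, rng)) == 50
        assert capture(disjoint, lambda_baits_M, cp, rng) == []
        assert all(f.captured for f in capture(containing, lambda_baits_M, cp, rng))

    def test_overlap_below_min_gets_background_probability(self, lambda_baits_M):
        # 99-bp overlap with the first bait: background (here 0) applies
        cp = CaptureParams(p_max=1.0, p_background=0.0, min_overlap_bp=100)
        below = _frag(41_152 - 5000, 41_152)  # overlap = 41152 - 41053 = 99
        assert capture([below] * 30, lambda_baits_M, cp, np.random.default_rng(0)) == []
        at = _frag(41_153 - 5000, 41_153)  # overlap = 100 -> on-bait rate
        assert len(capture([at] * 30, lambda_baits_M, cp, np.random.default_rng(0))) == 30

    def test_ten_kb_fragments_captured_at_half_the_5kb_rate(self, lambda_baits_M):
        """Steric-hindrance size penalty: retention halves from 5-kb to
        10-kb fragments at the default half-decay of 5 kb."""
        cp = CaptureParams()
        n = 6000
        k5 = capture([_frag(40_000, 45_000)] * n, lambda_baits_M, cp, np.random.default_rng(1))
        k10 = capture([_frag(35_000, 45_000)] * n, lambda_baits_M, cp, np.random.default_rng(2))
        ratio = len(k10) / len(k5)
        assert abs(ratio - 0.5) < 0.04  # ~5 binomial sigma

    def test_empty_input(self, lambda_baits_M):
        assert capture([], lambda_baits_M, CaptureParams(), np.random.default_rng(0)) == []

    def test_on_target_fraction_monotone_in_background_and_pmax(self, lambda_genome, lambda_baits_M, lambda_target):
        """On-target fraction of the captured pool is non-increasing in
        p_background and non-decreasing in p_max (paired seeds)."""
        cfg = SimConfig(n_fragments=3000, seed=5)
        frags = shear(lambda_genome, cfg, np.random.default_rng(5))

        def on_fraction(cp):
            kept = capture(frags, lambda_baits_M, cp, np.random.default_rng(42))
            on = sum(1 for f in kept if f.source.overlap(lambda_target) > 0)
            return on / len(kept)

        f_bg = [on_fraction(CaptureParams(p_background=p)) for p in (0.001, 0.01, 0.05)]
        assert f_bg[0] >= f_bg[1] >= f_bg[2]
        f_pm = [on_fraction(CaptureParams(p_max=p)) for p in (0.3, 0.6, 0.9)]
        assert f_pm[0] <= f_pm[1] <= f_pm[2]


class TestBuildLibrary:
    def test_single_library_gets_bar01_prefix(self):
        frags = [_frag(0, 40, seq="A" * 40) for _ in range(5)]
        cfg = SimConfig(n_fragments=5, seed=1)
        lib = build_library(frags, cfg, barcodes={"Bar01": datasets.BARCODES["Bar01"]})
        for f in lib:
            assert f.sequence.startswith("GGTGCTGAAGAAAGTTGTCGGTGTCTTTGTGTTAACCT")
            assert f.barcode_id == "Bar01"

    def test_two_libraries_partition_exactly(self):
        frags = [_frag(i, i + 10, seq="C" * 10) for i in range(10)]
        cfg = SimConfig(n_fragments=10, seed=1)
        assignment = ["Bar01"] * 5 + ["Bar02"] * 5
        lib = build_library(frags, cfg, barcodes=datasets.BARCODES, assignment=assignment)
        assert [f.barcode_id for f in lib] == assignment
        for f in lib:
            assert f.sequence.startswith(datasets.BARCODES[f.barcode_id])

    def test_missing_barcode_for_library_is_error(self):
        frags = [_frag(0, 10, seq="G" * 10)]
        cfg = SimConfig(n_fragments=1, seed=1)
        with pytest.raises(ValueError, match="no barcode"):
            build_library(frags, cfg, barcodes={"Bar01": "ACGT" * 5}, assignment=["BarX"])

    def test_zero_control_fraction_adds_nothing(self, lambda_genome):
        frags = [_frag(0, 3000, seq="T" * 3000)] * 4
        cfg = SimConfig(n_fragments=4, seed=1, control=None)
        lib = build_library(frags, cfg, control_genome=lambda_genome)
        assert len(lib) == 4 and not any(f.is_control for f in lib)

    def test_control_fraction_expected_value(self):
        control_genome = make_genome(10_000, seed=4, name="cs_dna")
        spec = ControlSpec(GenomicInterval("cs_dna", 5000, 10_000), fraction=0.2)
        frags = [_frag(0, 1000, seq="A" * 1000)] * 400
        cfg = SimConfig(n_fragments=400, seed=1, frag_mean_bp=1000, control=spec)
        lib = build_library(frags, cfg, control_genome, np.random.default_rng(1))
        n_ctrl = sum(f.is_control for f in lib)
        assert n_ctrl == 100  # 100 / (400 + 100) = 0.2 exactly in expectation
        for f in lib:
            if f.is_control:
                assert f.source.ref == "cs_dna" and f.source.start >= 5000


class TestSequenceReads:
    def test_zero_error_reads_equal_fragments(self):
        frags = [_frag(0, 30, seq="ACGTACGTACGTACGTACGTACGTACGTAC")]
        cfg = SimConfig(
            n_fragments=1, seed=1,
            error_2d=ErrorParams(0, 0, 0), error_template=ErrorParams(0, 0, 0),
        )
        reads, truth = sequence_reads(frags, cfg, np.random.default_rng(1))
        assert reads[0].sequence == frags[0].sequence
        assert truth[0].source == frags[0].source

    def test_all_2d_when_frac_is_one(self):
        frags = [_frag(i, i + 20, seq="A" * 20) for i in range(10)]
        cfg = SimConfig(n_fragments=10, seed=1, frac_2d=1.0)
        _, truth = sequence_reads(frags, cfg, np.random.default_rng(1))
        assert {t.read_class for t in truth} == {"2D"}

    def test_one_truth_record_per_read_with_unique_ids(self, lambda_genome):
        cfg = SimConfig(n_fragments=200, seed=3)
        frags = shear(lambda_genome, cfg, np.random.default_rng(3))
        reads, truth = sequence_reads(frags, cfg, np.random.default_rng(3))
        assert len(reads) == len(truth) == len(frags)
        assert len({t.read_id for t in truth}) == len(truth)
        assert [r.read_id for r in reads] == [t.read_id for t in truth]

    def test_2d_error_profile_yields_expected_identity(self, lambda_genome):
        """2-kb fragments with mismatch/insertion/deletion rates
        0.06/0.04/0.05 should land at ~0.86 median alignment identity,
        measured by the mapper's banded extension against the source."""
        rng = np.random.default_rng(7)
        cfg = SimConfig(
            n_fragments=300, frag_mean_bp=2000, frag_sd_bp=0, seed=7,
            frac_2d=1.0, error_2d=ErrorParams(0.06, 0.04, 0.05),
        )
        frags = shear(lambda_genome, cfg, rng)
        reads, truth = sequence_reads(frags, cfg, rng)
        index = SeedIndex(lambda_genome, k=11)
        idents = []
        for read in reads:
            aln = map_read(read.read_id, read.sequence, index)
            if aln is not None:
                idents.append(aln.identity)
        assert len(idents) >= 290
        assert 0.83 <= float(np.median(idents)) <= 0.88

    def test_error_rate_bounds_validated(self):
        with pytest.raises(ValueError):
            ErrorParams(0.5, 0.4, 0.2)
        with pytest.raises(ValueError):
            ErrorParams(-0.1, 0, 0)
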