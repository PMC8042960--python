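"""Repeat-length extraction, depth correction and the peak statistic."""

import math

import numpy as np
import pysam
import pytest

from msipeaks import peaks, simulate
from msipeaks.errors import InputError
from msipeaks.peaks import (
    BaselineTable,
    RepeatLengthHistogram,
    build_baseline,
    compute_peak,
    correct_histogram,
    downsample_reads,
    extract_repeat_lengths,
    profile_sample,
    read_baseline,
    read_profile,
    write_baseline,
    write_profile,
)

from conftest import make_bam

WORKED_RAW = {15: 2, 20: 10, 21: 20, 22: 40, 23: 100}
WORKED_CORRECTED = {15: 1.0, 20: 5.0, 21: 10.0, 22: 20.0, 23: 50.0}


class TestCorrection:
    def test_worked_example_halves_counts(self):
        raw = RepeatLengthHistogram("m", dict(WORKED_RAW), spanning_depth=200)
        corrected = correct_histogram(raw, BaselineTable({"m": 100.0}, 30))
        assert corrected.counts == WORKED_CORRECTED
        assert corrected.spanning_depth == 200

    def test_ratio_one_is_identity(self):
        raw = RepeatLengthHistogram("m", {20: 7, 21: 3}, spanning_depth=100)
        corrected = correct_histogram(raw, BaselineTable({"m": 100.0}, 5))
        assert corrected.counts == {20: 7, 21: 3}

    def test_under_covered_sample_not_upscaled(self):
        raw = RepeatLengthHistogram("m", {20: 10}, spanning_depth=50)
        corrected = correct_histogram(raw, BaselineTable({"m": 100.0}, 5))
        assert corrected.counts == {20: 10}

    def test_empty_histogram(self):
        raw = RepeatLengthHistogram("m", {}, spanning_depth=0)
        assert correct_histogram(raw, BaselineTable({"m": 10.0}, 2)).counts == {}

    def test_zero_baseline_warns_and_returns_raw(self):
        raw = RepeatLengthHistogram("m", {20: 4}, spanning_depth=8)
        with pytest.warns(UserWarning, match="uncorrected"):
            out = correct_histogram(raw, BaselineTable({"m": 0.0}, 3))
        assert out.counts == {20: 4} and not out.corrected

    def test_missing_baseline_entry_is_input_error(self):
        raw = RepeatLengthHistogram("m", {20: 4}, spanning_depth=8)
        with pytest.raises(InputError):
            correct_histogram(raw, BaselineTable({"other": 5.0}, 3))

    def test_mass_conserved_when_scaling_down(self):
        raw = RepeatLengthHistogram("m", {10: 13, 11: 29, 12: 7}, spanning_depth=147)
        baseline = BaselineTable({"m": 49.0}, 4)
        corrected = correct_histogram(raw, baseline)
        ratio = raw.spanning_depth / baseline["m"]
        assert math.isclose(sum(corrected.counts.values()) * ratio,
                            sum(raw.counts.values()), rel_tol=0, abs_tol=1e-9)

    def test_scale_equivariance_of_peak(self):
        # tripling counts and depth over the same baseline triples the
        # ratio, so the corrected histogram (and peak) are unchanged
        raw = RepeatLengthHistogram("m", {10: 4, 11: 40, 12: 2}, spanning_depth=46)
        baseline = BaselineTable({"m": 23.0}, 2)
        corrected = correct_histogram(raw, baseline)
        scaled = RepeatLengthHistogram(
            "m", {k: v * 3 for k, v in raw.counts.items()}, spanning_depth=46 * 3)
        corrected3 = correct_histogram(scaled, baseline)
        assert corrected3.counts == pytest.approx(corrected.counts)
        assert compute_peak(corrected3).peak == compute_peak(corrected).peak


class TestComputePeak:
    def test_worked_example_peak_is_4(self):
        hist = RepeatLengthHistogram("m", dict(WORKED_CORRECTED), spanning_depth=200)
        assert compute_peak(hist, min_support=3).peak == 4

    def test_all_supports_at_or_below_threshold(self):
        hist = RepeatLengthHistogram("m", {10: 3, 11: 2.9, 12: 0.5}, spanning_depth=7)
        assert compute_peak(hist, min_support=3).peak == 0

    def test_strict_inequality_at_boundary(self):
        hist = RepeatLengthHistogram("m", {10: 3.0, 11: 100.0}, spanning_depth=103)
        assert compute_peak(hist, min_support=3).peak == 1

    def test_non_increasing_in_min_support(self):
        rng = np.random.default_rng(0)
        counts = {int(k): float(v) for k, v in
                  zip(rng.integers(8, 30, 12), rng.uniform(0, 20, 12))}
        hist = RepeatLengthHistogram("m", counts, spanning_depth=int(sum(counts.values())))
        values = [compute_peak(hist, s).peak for s in np.linspace(0, 25, 40)]
        assert values == sorted(values, reverse=True)


class TestExtraction:
    """CIGAR-level tract length measurement on hand-built alignments."""

    def bam(self, tmp_path, reads):
        return make_bam(tmp_path / "t.bam", 100, reads)

    def hist(self, tmp_path, reads, site, flank=5):
        with pysam.AlignmentFile(self.bam(tmp_path, reads)) as aln:
            return extract_repeat_lengths(aln, site, flank=flank)

    def test_exact_match_read_reports_reference_length(self, tmp_path, homopolymer_site):
        h = self.hist(tmp_path, [("r1", 30, "30M", 30)], homopolymer_site)
        assert h.counts == {10: 1} and h.spanning_depth == 1

    def test_deletion_inside_tract_shortens_by_its_length(self, tmp_path, homopolymer_site):
        # 15M consumes ref 30..45, 2D deletes tract bases 45..47
        h = self.hist(tmp_path, [("r1", 30, "15M2D13M", 28)], homopolymer_site)
        assert h.counts == {8: 1}

    def test_insertion_inside_tract_lengthens(self, tmp_path, homopolymer_site):
        # insertion breakpoint at ref 41, strictly inside the tract
        h = self.hist(tmp_path, [("r1", 30, "11M3I16M", 30)], homopolymer_site)
        assert h.counts == {13: 1}

    def test_insertion_at_tract_start_belongs_to_flank(self, tmp_path, homopolymer_site):
        # breakpoint exactly at ref 40 == site start: not part of the tract
        h = self.hist(tmp_path, [("r1", 30, "10M3I17M", 30)], homopolymer_site)
        assert h.counts == {10: 1}

    def test_soft_clip_in_flank_excludes_read(self, tmp_path, homopolymer_site):
        # aligned portion starts at ref 36, inside the left flank window [35,40)
        h = self.hist(tmp_path, [("r1", 36, "1S29M", 30)], homopolymer_site)
        assert h.counts == {} and h.spanning_depth == 0

    def test_non_spanning_and_flagged_reads_excluded(self, tmp_path, homopolymer_site):
        reads = [
            ("short", 38, "10M", 10),          # does not reach the right flank
            ("dup", 30, "30M", 30, 1024),      # duplicate flag
            ("secondary", 30, "30M", 30, 256),  # secondary alignment
            ("good", 30, "30M", 30),
        ]
        h = self.hist(tmp_path, reads, homopolymer_site)
        assert h.spanning_depth == 1 and h.counts == {10: 1}

    def test_deletion_overlapping_flank_excludes_read(self, tmp_path, homopolymer_site):
        # deletion spans ref 38..42: the left flank is not fully aligned
        h = self.hist(tmp_path, [("r1", 30, "8M4D18M", 26)], homopolymer_site)
        assert h.spanning_depth == 0

    def test_missing_chromosome_is_input_error(self, tmp_path, homopolymer_site):
        path = make_bam(tmp_path / "t.bam", 100, [("r1", 30, "30M", 30)], chrom="other")
        with pysam.AlignmentFile(path) as aln:
            with pytest.raises(InputError, match="'c'"):
                extract_repeat_lengths(aln, homopolymer_site)


class TestDownsample:
    def test_exact_cardinality(self):
        reads = list(range(1000))
        assert len(downsample_reads(reads, 500, seed=1)) == 500

    def test_below_cap_untouched(self):
        reads = list(range(300))
        assert downsample_reads(reads, 500, seed=1) == reads

    def test_same_seed_same_subset(self):
        reads = list(range(1000))
        assert downsample_reads(reads, 500, 7) == downsample_reads(reads, 500, 7)
        assert downsample_reads(reads, 500, 7) != downsample_reads(reads, 500, 8)


class TestBaseline:
    def test_arithmetic_mean_of_depths(self, tmp_path, homopolymer_site):
        b1 = make_bam(tmp_path / "n1.bam", 100,
                      [(f"r{i}", 30, "30M", 30) for i in range(2)])
        b2 = make_bam(tmp_path / "n2.bam", 100,
                      [(f"r{i}", 30, "30M", 30) for i in range(6)])
        table = build_baseline([b1, b2], [homopolymer_site])
        assert table[homopolymer_site.site_id] == 4.0 and table.n_normals == 2

    def test_missing_chromosome_counts_depth_zero(self, tmp_path, homopolymer_site):
        b1 = make_bam(tmp_path / "n1.bam", 100,
                      [(f"r{i}", 30, "30M", 30) for i in range(4)])
        b2 = make_bam(tmp_path / "n2.bam", 100, [("r0", 30, "30M", 30)], chrom="other")
        with pytest.warns(UserWarning, match="missing"):
            table = build_baseline([b1, b2], [homopolymer_site])
        assert table[homopolymer_site.site_id] == 2.0

    def test_round_trip(self, tmp_path):
        table = BaselineTable({"s1": 101.25, "s2": 0.0}, 7)
        path = tmp_path / "baseline.tsv"
        write_baseline(table, str(path))
        back = read_baseline(str(path))
        assert back.average_depth == table.average_depth
        assert back.n_normals == 7


class TestProfileAgainstSimulator:
    def test_histograms_match_ground_truth(self, small_cohort):
        """Extraction reproduces the simulator's per-read emitted lengths."""
        sample_id = "MSIH01"
        truth = small_cohort.truth[sample_id]
        with pysam.AlignmentFile(str(small_cohort.bams[sample_id])) as aln:
            for site in small_cohort.sites:
                h = extract_repeat_lengths(aln, site)
                assert h.counts == {
                    k: float(v) for k, v in truth.emitted[site.site_id].items()
                }

    def test_profile_of_a_normal_against_itself_gives_peak_1(self, tmp_path):
        cfg = simulate.SimConfig(seed=9, n_ms_sites=6, contig_len=6_000,
                                 mean_depth=40, stutter_rate=0.0)
        ref, sites = simulate.make_reference(cfg)
        bam = tmp_path / "n.bam"
        simulate.simulate_sample(ref, sites, cfg, "NORMAL", 1, str(bam), sample_id="n")
        table = build_baseline([str(bam)], sites)
        with pysam.AlignmentFile(str(bam)) as aln:
            prof = profile_sample(aln, sites, table)
        assert (prof["peak"] == 1).all()

    def test_profile_round_trip(self, tmp_path, small_cohort_profiles):
        _, profiles = small_cohort_profiles
        prof = profiles["MSS01"]
        path = tmp_path / "p.tsv"
        write_profile(prof, str(path))
        assert read_profile(str(path)).equals(prof)
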