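"""Shared fixtures: hand-built alignments and a small simulated cohort."""

from __future__ import annotations

import pysam
import pytest

from msipeaks import peaks, simulate
from msipeaks.refscan import MicrosatelliteSite


def make_bam(path, chrom_len, reads, chrom="c"):
    """Write a sorted, indexed BAM from (name, pos, cigar, seq_len) tuples."""
    header = pysam.AlignmentHeader.from_references([chrom], [chrom_len])
    records = []
    for name, pos, cigar, seq_len, *rest in reads:
        rec = pysam.AlignedSegment(header)
        rec.query_name = name
        rec.query_sequence = "A" * seq_len
        rec.flag = rest[0] if rest else 0
        rec.reference_id = 0
        rec.reference_start = pos
        rec.mapping_quality = 60
        rec.cigarstring = cigar
        rec.query_qualities = pysam.qualitystring_to_array("I" * seq_len)
        records.append(rec)
    records.sort(key=lambda r: r.reference_start)
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for rec in records:
            bam.write(rec)
    pysam.index(str(path))
    return str(path)


@pytest.fixture
def homopolymer_site():
    """A 10-unit A tract at [40, 50) on a 100 bp contig named 'c'."""
    return MicrosatelliteSite(chrom="c", start=40, end=50, unit="A", n_units=10)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """12-locus cohort (6 MSI-H, 6 MSS, 2 normals) shared across tests.

    Big enough for the rank-sum test to reach p < 0.01 at unstable loci,
    small enough to simulate in a couple of seconds.
    """
    cfg = simulate.SimConfig(
        seed=5, n_ms_sites=12, contig_len=8_000, mean_depth=60,
        msih_site_fraction=0.25,
    )
    out = tmp_path_factory.mktemp("cohort")
    return simulate.make_cohort(cfg, n_msih=6, n_mss=6, n_normals=2, out_dir=str(out))


@pytest.fixture(scope="session")
def small_cohort_profiles(small_cohort):
    """Per-sample peak/depth profiles for every sample of the small cohort."""
    sites = small_cohort.sites
    normals = [
        str(small_cohort.bams[s])
        for s in small_cohort.labels.index
        if small_cohort.labels[s] == "NORMAL"
    ]
    baseline = peaks.build_baseline(normals, sites)
    profiles = {}
    for sample_id in small_cohort.labels.index:
        with pysam.AlignmentFile(str(small_cohort.bams[sample_id])) as aln:
            profiles[sample_id] = peaks.profile_sample(aln, sites, baseline)
    return baseline, profiles
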