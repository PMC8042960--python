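"""Repeat-length histograms, baseline depth correction and the peak feature.

For every microsatellite locus, the spanning reads of a sample yield a
histogram mapping observed repeat-tract length (bases) to supporting
read count.  A read spans a locus when its alignment covers the tract
plus ``flank`` anchored (aligned, unclipped) bases on each side; its
observed tract length is the reference tract length plus inserted minus
deleted bases within the tract, taken from the CIGAR.

Because support counts scale with coverage, raw counts are divided by
the ratio of the sample's spanning depth at the locus to the average
depth of a panel of normal samples (the baseline).  Only over-covered
samples are scaled down; a ratio below 1 leaves the histogram untouched
rather than fabricating support.  The *peak* of a locus is the number
of distinct tract lengths whose corrected support strictly exceeds
``min_support`` (default 3): a stable locus typically shows peak 1,
while an unstable locus in an MSI-H tumor shows several well-supported
lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import InputError, SiteParseError
from .refscan import MicrosatelliteSite

DEFAULT_FLANK = 5
DEFAULT_MIN_SUPPORT = 3.0

_CIGAR_MATCH = frozenset((0, 7, 8))  # M, =, X


@dataclass
class RepeatLengthHistogram:
    """Per-locus map from observed tract length to supporting reads."""

    site_id: str
    counts: dict[int, float] = field(default_factory=dict)
    spanning_depth: int = 0
    corrected: bool = False

    def __post_init__(self):
        if any(k < 0 for k in self.counts):
            raise ValueError("tract lengths must be >= 0")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("support counts must be >= 0")


@dataclass
class BaselineTable:
    """Average spanning depth per locus over a panel of normal samples."""

    average_depth: dict[str, float]
    n_normals: int

    def __post_init__(self):
        if any(d < 0 for d in self.average_depth.values()):
            raise ValueError("average depths must be >= 0")

    def __contains__(self, site_id: str) -> bool:
        return site_id in self.average_depth

    def __getitem__(self, site_id: str) -> float:
        return self.average_depth[site_id]


@dataclass(frozen=True)
class PeakValue:
    site_id: str
    peak: int


def spanning_reads(
    alignments: pysam.AlignmentFile,
    site: MicrosatelliteSite,
    flank: int = DEFAULT_FLANK,
) -> list[pysam.AlignedSegment]:
    """Primary, non-duplicate, mapped reads spanning the tract plus flanks.

    The read must carry aligned (M/=/X) bases at every reference
    position of both flank windows; soft clips, deletions or skips
    touching a flank disqualify it.
    """
    if flank < 1:
        raise InputError("flank must be >= 1")
    if site.chrom not in alignments.references:
        raise InputError(
            f"chromosome {site.chrom!r} absent from alignment header of "
            f"{alignments.filename.decode() if alignments.filename else '<stream>'}"
        )
    left_lo, right_hi = site.start - flank, site.end + flank
    out = []
    for read in alignments.fetch(site.chrom, max(0, left_lo), right_hi):
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.is_duplicate
        ):
            continue
        if read.reference_start > left_lo or read.reference_end < right_hi:
            continue
        if _flanks_aligned(read, left_lo, site.start, site.end, right_hi):
            out.append(read)
    return out


def _flanks_aligned(read, left_lo, start, end, right_hi) -> bool:
    """Every position of [left_lo,start) and [end,right_hi) is M/=/X."""
    need = (right_hi - end) + (start - left_lo)
    got = 0
    ref = read.reference_start
    for op, ln in read.cigartuples:
        if op in _CIGAR_MATCH:
            got += max(0, min(ref + ln, start) - max(ref, left_lo))
            got += max(0, min(ref + ln, right_hi) - max(ref, end))
            ref += ln
        elif op in (2, 3):  # D, N consume reference without aligned bases
            ref += ln
    return got == need


def read_tract_length(read: pysam.AlignedSegment, site: MicrosatelliteSite) -> int:
    """Observed tract length: reference span + insertions - deletions.

    An insertion counts toward the tract when its breakpoint lies
    strictly between the first and last tract base; one placed exactly
    at either tract boundary belongs to the flanking sequence.
    """
    ins = dele = 0
    ref = read.reference_start
    for op, ln in read.cigartuples:
        if op in _CIGAR_MATCH:
            ref += ln
        elif op == 1:  # I: breakpoint before reference position `ref`
            if site.start < ref < site.end:
                ins += ln
        elif op in (2, 3):  # D, N
            dele += max(0, min(ref + ln, site.end) - max(ref, site.start))
            ref += ln
    return site.ref_tract_len + ins - dele


def downsample_reads(
    reads: Sequence[pysam.AlignedSegment], max_reads: int, seed: int
) -> list:
    """Uniform random subset of exactly ``max_reads`` reads (seeded).

    Fewer reads than the cap are returned unchanged.
    """
    if max_reads < 1:
        raise InputError("max_reads must be >= 1")
    if len(reads) <= max_reads:
        return list(reads)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=max_reads, replace=False)
    idx.sort()
    return [reads[i] for i in idx]


def extract_repeat_lengths(
    alignments: pysam.AlignmentFile,
    site: MicrosatelliteSite,
    flank: int = DEFAULT_FLANK,
    max_reads: int | None = None,
    seed: int = 0,
) -> RepeatLengthHistogram:
    """Raw repeat-length histogram of one sample at one locus."""
    reads = spanning_reads(alignments, site, flank)
    if max_reads is not None:
        reads = downsample_reads(reads, max_reads, seed)
    counts: dict[int, float] = {}
    for read in reads:
        length = read_tract_length(read, site)
        counts[length] = counts.get(length, 0) + 1
    return RepeatLengthHistogram(
        site_id=site.site_id, counts=counts, spanning_depth=len(reads)
    )


def correct_histogram(
    raw: RepeatLengthHistogram, baseline: BaselineTable
) -> RepeatLengthHistogram:
    """Divide raw support by the depth ratio sample/baseline.

    ratio = spanning_depth / baseline average depth at the locus.  A
    ratio <= 1 returns the histogram unchanged (no up-scaling of
    under-covered samples); a zero baseline leaves the locus
    uncorrectable and the raw histogram is returned with a warning.
    """
    if raw.site_id not in baseline:
        raise InputError(f"no baseline entry for site {raw.site_id!r}")
    avg = baseline[raw.site_id]
    if avg == 0:
        warnings.warn(
            f"site {raw.site_id}: baseline depth 0, histogram left uncorrected",
            stacklevel=2,
        )
        return RepeatLengthHistogram(
            raw.site_id, dict(raw.counts), raw.spanning_depth, corrected=False
        )
    ratio = raw.spanning_depth / avg
    if ratio <= 1:
        counts = dict(raw.counts)
    else:
        counts = {length: c / ratio for length, c in raw.counts.items()}
    return RepeatLengthHistogram(raw.site_id, counts, raw.spanning_depth, corrected=True)


def compute_peak(
    corrected: RepeatLengthHistogram, min_support: float = DEFAULT_MIN_SUPPORT
) -> PeakValue:
    """Number of distinct tract lengths with support strictly > min_support."""
    if min_support < 0:
        raise InputError("min_support must be >= 0")
    peak = sum(1 for c in corrected.counts.values() if c > min_support)
    return PeakValue(site_id=corrected.site_id, peak=peak)


def build_baseline(
    normal_paths: Sequence[str],
    sites: Sequence[MicrosatelliteSite],
    flank: int = DEFAULT_FLANK,
) -> BaselineTable:
    """Mean spanning depth per locus over a panel of normal samples."""
    if not normal_paths:
        raise InputError("at least one normal sample is required")
    totals = {s.site_id: 0.0 for s in sites}
    for path in normal_paths:
        with pysam.AlignmentFile(str(path)) as aln:
            present = set(aln.references)
            for site in sites:
                if site.chrom not in present:
                    warnings.warn(
                        f"normal {path}: chromosome {site.chrom} missing, "
                        f"depth 0 at {site.site_id}",
                        stacklevel=2,
                    )
                    continue
                totals[site.site_id] += len(spanning_reads(aln, site, flank))
    n = len(normal_paths)
    return BaselineTable(
        average_depth={sid: t / n for sid, t in totals.items()}, n_normals=n
    )


def profile_sample(
    alignments: pysam.AlignmentFile,
    sites: Sequence[MicrosatelliteSite],
    baseline: BaselineTable,
    flank: int = DEFAULT_FLANK,
    min_support: float = DEFAULT_MIN_SUPPORT,
    max_reads: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-locus spanning depth and peak for one sample.

    Composition of extract -> correct -> compute_peak at every locus;
    loci without spanning reads get depth 0 and peak 0.
    """
    if not sites:
        raise InputError("site list is empty")
    rows = []
    for site in sites:
        raw = extract_repeat_lengths(alignments, site, flank, max_reads, seed)
        corr = correct_histogram(raw, baseline)
        peak = compute_peak(corr, min_support)
        rows.append((site.site_id, raw.spanning_depth, peak.peak))
    return pd.DataFrame(rows, columns=["site_id", "spanning_depth", "peak"])


def sample_peak_vector(
    alignments, sites, baseline, flank=DEFAULT_FLANK,
    min_support=DEFAULT_MIN_SUPPORT, max_reads=None, seed=0,
) -> dict[str, int]:
    """Map site_id -> peak for one sample (see :func:`profile_sample`)."""
    prof = profile_sample(alignments, sites, baseline, flank, min_support, max_reads, seed)
    return dict(zip(prof["site_id"], prof["peak"]))


# ---------------------------------------------------------------------------
# TSV I/O

def write_baseline(baseline: BaselineTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\taverage_depth\tn_normals\n")
        for sid, depth in baseline.average_depth.items():
            fh.write(f"{sid}\t{depth!r}\t{baseline.n_normals}\n")


def read_baseline(path: str) -> BaselineTable:
    depths: dict[str, float] = {}
    n_normals = 0
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith("site_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise SiteParseError(path, i, "expected 3 columns")
            try:
                depths[fields[0]] = float(fields[1])
                n_normals = int(fields[2])
            except ValueError as exc:
                raise SiteParseError(path, i, str(exc)) from exc
    return BaselineTable(average_depth=depths, n_normals=n_normals)


def write_profile(profile: pd.DataFrame, path: str) -> None:
    profile.to_csv(path, sep="\t", index=False)


def read_profile(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"site_id", "spanning_depth", "peak"} - set(df.columns)
    if missing:
        raise SiteParseError(path, 1, f"missing columns {sorted(missing)}")
    return df
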