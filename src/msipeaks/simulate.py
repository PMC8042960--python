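"""Synthetic panel-sequencing world: reference, cohorts, reads, truth.

The generator emulates the data this pipeline consumes in production:
a reference genome carrying microsatellite loci, a capture panel, and
coordinate-sorted aligned reads per sample.

* Background sequence is run-suppressed (homopolymers capped below the
  scan threshold, multi-base repeats below four copies), so the planted
  loci are the complete truth set for the scanner.
* MSS and NORMAL samples carry a single allele per locus equal to the
  reference tract; MSI-H samples replace a fixed fraction of loci with
  several shorter alleles (deletion-biased instability), spread over a
  configurable number of repeat units.
* Every read is subject to PCR stutter: with probability
  ``stutter_rate`` its tract shifts by a geometric number of whole
  units in a random direction, the classic +/-1-unit-dominated stutter
  ladder.
* Reads are emitted pre-aligned with explicit tract indels in their
  CIGARs, mimicking the output of an upstream aligner; alignment
  itself is out of scope.

Ground truth records the alleles per locus, the label per sample and
the emitted tract length per read, so extraction can be checked
read-for-read.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .errors import ConfigError
from .markers import MSI_H, MSS, NORMAL
from .refscan import MicrosatelliteSite, scan_reference, write_sites

_BASES = "ACGT"


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic world.

    Defaults are sized for a small capture panel: 50 loci over two
    contigs, 100x mean spanning depth, 100 bp reads, reference tracts
    of 10-34 bases, 2% per-read stutter, and MSI-H instability at 20%
    of loci with 3-5 alleles spread over up to 8 repeat units.
    """

    seed: int = 0
    n_contigs: int = 2
    contig_len: int = 12_000
    n_ms_sites: int = 50
    unit_weights: dict = field(
        default_factory=lambda: {"A": 0.45, "T": 0.45, "TG": 0.10}
    )
    tract_len_range: tuple[int, int] = (10, 34)
    read_len: int = 100
    mean_depth: float = 100.0
    stutter_rate: float = 0.02
    stutter_geom_p: float = 0.7
    msih_allele_count: tuple[int, int] = (3, 5)
    msih_allele_spread: int = 8
    msih_site_fraction: float = 0.2
    flank_margin: int = 10

    def __post_init__(self):
        for name in ("stutter_rate", "msih_site_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if not 0 < self.stutter_geom_p <= 1:
            raise ConfigError("stutter_geom_p must be in (0,1]")
        lo, hi = self.tract_len_range
        if not 2 <= lo <= hi:
            raise ConfigError(f"bad tract_len_range {self.tract_len_range}")
        if self.read_len < hi + 2 * self.flank_margin + 4:
            raise ConfigError(
                f"read_len {self.read_len} too short to span tracts up to {hi} "
                f"bases with {self.flank_margin}-base anchored flanks"
            )
        k_lo, k_hi = self.msih_allele_count
        if not 1 <= k_lo <= k_hi:
            raise ConfigError(f"bad msih_allele_count {self.msih_allele_count}")
        if self.msih_allele_spread < k_hi - 1:
            raise ConfigError("msih_allele_spread too small for msih_allele_count")

    @property
    def max_tract_len(self) -> int:
        # stutter may lengthen a tract; cap it at what a read can span
        return self.read_len - 2 * self.flank_margin


@dataclass
class SampleTruth:
    """Per-sample ground truth emitted alongside the reads."""

    sample_id: str
    label: str
    alleles: dict            # site_id -> list of [tract_len_bases, weight]
    read_lengths: dict       # read_name -> emitted tract length
    emitted: dict            # site_id -> {tract_len: read count}


def _run_suppressed_background(rng: np.random.Generator, length: int) -> list[str]:
    """Random sequence avoiding homopolymers > 6 and >= 4 copies of any 2-6mer."""
    seq: list[str] = []
    for _ in range(length):
        excluded = set()
        if len(seq) >= 6 and len(set(seq[-6:])) == 1:
            excluded.add(seq[-1])
        for p in range(2, 7):
            w = 4 * p - 1
            if len(seq) >= w:
                tail = seq[-w:]
                if all(tail[x] == tail[x - p] for x in range(p, w)):
                    excluded.add(tail[-p])
        choices = [b for b in _BASES if b not in excluded] or list(_BASES)
        seq.append(choices[rng.integers(len(choices))])
    return seq


def make_reference(
    config: SimConfig,
) -> tuple[dict[str, str], list[MicrosatelliteSite]]:
    """Random reference with planted, scanner-discoverable microsatellites.

    Planted runs are maximal (boundary bases are forced off-unit) and
    the background is scrubbed until the scanner finds exactly the
    planted list.
    """
    rng = np.random.default_rng(config.seed)
    per_contig = [config.n_ms_sites // config.n_contigs] * config.n_contigs
    for i in range(config.n_ms_sites % config.n_contigs):
        per_contig[i] += 1
    units = list(config.unit_weights)
    weights = np.array([config.unit_weights[u] for u in units], dtype=float)
    weights /= weights.sum()
    lo, hi = config.tract_len_range

    reference: dict[str, str] = {}
    planted: list[MicrosatelliteSite] = []
    for ci in range(config.n_contigs):
        chrom = f"chr{ci + 1}"
        n_here = per_contig[ci]
        seq = _run_suppressed_background(rng, config.contig_len)
        if n_here:
            spacing = config.contig_len // (n_here + 1)
            if spacing < config.read_len + hi + 20:
                raise ConfigError(
                    f"{n_here} sites do not fit in a {config.contig_len}-bp contig "
                    f"with {config.read_len}-bp reads: sites too dense"
                )
            for k in range(n_here):
                unit = units[rng.choice(len(units), p=weights)]
                p = len(unit)
                n_units = int(rng.integers((lo + p - 1) // p, hi // p + 1))
                tract = unit * n_units
                pos = (k + 1) * spacing + int(rng.integers(-spacing // 8, spacing // 8 + 1))
                seq[pos : pos + len(tract)] = list(tract)
                # break the run at both ends so the planted tract is maximal
                for edge, off_unit in ((pos - 1, unit[-1]), (pos + len(tract), unit[0])):
                    cands = [b for b in "CG" if b != off_unit] or ["C"]
                    seq[edge] = cands[int(rng.integers(len(cands)))]
                planted.append(
                    MicrosatelliteSite(
                        chrom=chrom, start=pos, end=pos + len(tract),
                        unit=unit, n_units=n_units,
                    )
                )
        reference[chrom] = "".join(seq)

    planted.sort(key=lambda s: (s.chrom, s.start))
    _scrub_background(reference, planted, rng)
    return reference, planted


def _scrub_background(reference, planted, rng, max_rounds: int = 20) -> None:
    """Mutate away any scanner hit that is not a planted locus."""
    planted_keys = {(s.chrom, s.start, s.end, s.unit) for s in planted}
    spans = {}
    for s in planted:
        spans.setdefault(s.chrom, []).append((s.start, s.end))
    for _ in range(max_rounds):
        found = scan_reference(reference)
        stray = [
            s for s in found if (s.chrom, s.start, s.end, s.unit) not in planted_keys
        ]
        if not stray:
            missing = planted_keys - {
                (s.chrom, s.start, s.end, s.unit) for s in found
            }
            if missing:
                raise ConfigError(f"planted loci destroyed during scrub: {missing}")
            return
        for s in stray:
            pos = (s.start + s.end) // 2
            if any(a <= pos < b for a, b in spans.get(s.chrom, ())):
                continue  # never touch a planted tract
            seq = reference[s.chrom]
            near = {seq[pos - 1], seq[pos], seq[pos + 1]}
            choices = [b for b in _BASES if b not in near]
            reference[s.chrom] = (
                seq[:pos] + choices[int(rng.integers(len(choices)))] + seq[pos + 1 :]
            )
    raise ConfigError("background scrub did not converge")


def make_panel(
    sites: list[MicrosatelliteSite], pad: int = 50
) -> list[tuple[str, int, int]]:
    """Merged capture intervals covering each locus plus ``pad`` bases."""
    raw = sorted((s.chrom, max(0, s.start - pad), s.end + pad) for s in sites)
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in raw:
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            merged[-1] = (chrom, merged[-1][1], max(end, merged[-1][2]))
        else:
            merged.append((chrom, start, end))
    return merged


def draw_alleles(
    site: MicrosatelliteSite, config: SimConfig, rng: np.random.Generator
) -> list[tuple[int, float]]:
    """MSI-H allele set at an unstable locus: reference plus shorter tracts."""
    p = len(site.unit)
    k_lo, k_hi = config.msih_allele_count
    k = int(rng.integers(k_lo, k_hi + 1))
    max_delta = min(config.msih_allele_spread, site.n_units - 2)
    if max_delta < k - 1:
        k = max_delta + 1
    deltas = rng.choice(np.arange(1, max_delta + 1), size=k - 1, replace=False)
    lengths = [site.ref_tract_len] + [
        (site.n_units - int(d)) * p for d in sorted(deltas)
    ]
    w = 1.0 / len(lengths)
    return [(length, w) for length in lengths]


def _stuttered_length(
    tract_len: int, unit_len: int, config: SimConfig, rng: np.random.Generator
) -> int:
    if rng.random() >= config.stutter_rate:
        return tract_len
    step = int(rng.geometric(config.stutter_geom_p)) * unit_len
    if rng.random() < 0.5:
        step = -step
    out = tract_len + step
    out = max(2 * unit_len, min(out, (config.max_tract_len // unit_len) * unit_len))
    return out


def simulate_sample(
    reference: dict[str, str],
    sites: list[MicrosatelliteSite],
    config: SimConfig,
    label: str,
    seed: int,
    out_bam: str,
    unstable_site_ids: set[str] | frozenset[str] = frozenset(),
    sample_id: str = "sample",
) -> SampleTruth:
    """Emit one sample's sorted, indexed BAM plus its ground truth."""
    if label not in (MSI_H, MSS, NORMAL):
        raise ConfigError(f"unknown label {label!r}")
    rng = np.random.default_rng(seed)
    chroms = list(reference)
    header = pysam.AlignmentHeader.from_references(
        chroms, [len(reference[c]) for c in chroms]
    )
    tid = {c: i for i, c in enumerate(chroms)}

    alleles: dict[str, list[tuple[int, float]]] = {}
    for site in sites:
        if label == MSI_H and site.site_id in unstable_site_ids:
            alleles[site.site_id] = draw_alleles(site, config, rng)
        else:
            alleles[site.site_id] = [(site.ref_tract_len, 1.0)]

    records = []
    read_lengths: dict[str, int] = {}
    emitted: dict[str, dict[int, int]] = {s.site_id: {} for s in sites}
    for site in sites:
        seq = reference[site.chrom]
        site_alleles = alleles[site.site_id]
        probs = np.array([w for _, w in site_alleles])
        n_reads = int(rng.poisson(config.mean_depth))
        for ri in range(n_reads):
            base_len = site_alleles[int(rng.choice(len(site_alleles), p=probs))][0]
            tract_len = _stuttered_length(base_len, len(site.unit), config, rng)
            rec = _make_read(
                seq, site, tract_len, config, rng,
                name=f"{sample_id}:{site.site_id}:{ri}", header=header,
                tid=tid[site.chrom],
            )
            if rec is None:
                continue
            records.append(rec)
            read_lengths[rec.query_name] = tract_len
            emitted[site.site_id][tract_len] = emitted[site.site_id].get(tract_len, 0) + 1

    records.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name))
    with pysam.AlignmentFile(out_bam, "wb", header=header) as bam:
        for rec in records:
            bam.write(rec)
    pysam.index(out_bam)
    return SampleTruth(
        sample_id=sample_id, label=label,
        alleles={k: [list(a) for a in v] for k, v in alleles.items()},
        read_lengths=read_lengths, emitted=emitted,
    )


def _make_read(seq, site, tract_len, config, rng, name, header, tid):
    """Build one aligned read spanning the locus with the requested tract.

    The read is reference sequence left of the tract, whole unit copies
    to ``tract_len`` bases, then reference sequence right of it; length
    changes are encoded as a single insertion just after the first
    tract base or a deletion at the tract's right end.
    """
    p = len(site.unit)
    margin = config.flank_margin
    lo_a = margin
    hi_a = config.read_len - tract_len - margin
    if hi_a < lo_a:
        return None
    a = int(rng.integers(lo_a, hi_a + 1))
    rs = site.start - a
    right_len = config.read_len - a - tract_len
    ref_end_needed = site.end + right_len
    if rs < 0 or ref_end_needed > len(seq):
        return None
    unit_run = (site.unit * (tract_len // p + 1))[:tract_len]
    read_seq = seq[rs : site.start] + unit_run + seq[site.end : ref_end_needed]
    d = tract_len - site.ref_tract_len
    if d == 0:
        cigar = [(0, config.read_len)]
    elif d > 0:
        cigar = [(0, a + 1), (1, d), (0, config.read_len - a - 1 - d)]
    else:
        cigar = [(0, a + tract_len), (2, -d), (0, right_len)]
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.query_sequence = read_seq
    rec.flag = 0
    rec.reference_id = tid
    rec.reference_start = rs
    rec.mapping_quality = 60
    rec.cigartuples = cigar
    rec.query_qualities = pysam.qualitystring_to_array("I" * len(read_seq))
    return rec


def choose_unstable_sites(
    sites: list[MicrosatelliteSite], config: SimConfig
) -> list[str]:
    """Cohort-level unstable locus set (shared by all MSI-H samples)."""
    rng = np.random.default_rng(config.seed + 1_000_000_007 % (2**31))
    n_unstable = int(round(config.msih_site_fraction * len(sites)))
    idx = sorted(rng.choice(len(sites), size=n_unstable, replace=False))
    return [sites[i].site_id for i in idx]


@dataclass
class Cohort:
    """Paths and truth for a complete simulated study."""

    out_dir: Path
    reference_fasta: Path
    panel_bed: Path
    sites_tsv: Path
    labels_tsv: Path
    truth_json: Path
    bams: dict[str, Path]
    labels: pd.Series
    sites: list[MicrosatelliteSite]
    unstable_site_ids: list[str]
    truth: dict[str, SampleTruth]


def write_reference(reference: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    pysam.faidx(str(path))


def _sample_seed(base_seed: int, index: int) -> int:
    return (base_seed * 1_000_003 + 7919 * index + 1) % (2**31 - 1)


def make_cohort(
    config: SimConfig,
    n_msih: int,
    n_mss: int,
    n_normals: int,
    out_dir: str,
) -> Cohort:
    """End-to-end fixture: reference, panel, labelled BAMs, ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference, sites = make_reference(config)
    fasta = out / "reference.fa"
    write_reference(reference, str(fasta))
    panel = make_panel(sites)
    bed = out / "panel.bed"
    with open(bed, "w") as fh:
        for chrom, start, end in panel:
            fh.write(f"{chrom}\t{start}\t{end}\n")
    sites_tsv = out / "sites.tsv"
    write_sites(sites, str(sites_tsv))

    unstable = choose_unstable_sites(sites, config)
    plan = (
        [(f"NORM{i+1:02d}", NORMAL) for i in range(n_normals)]
        + [(f"MSS{i+1:02d}", MSS) for i in range(n_mss)]
        + [(f"MSIH{i+1:02d}", MSI_H) for i in range(n_msih)]
    )
    bams: dict[str, Path] = {}
    truth: dict[str, SampleTruth] = {}
    for idx, (sample_id, label) in enumerate(plan):
        bam = out / f"{sample_id}.bam"
        truth[sample_id] = simulate_sample(
            reference, sites, config, label,
            seed=_sample_seed(config.seed, idx), out_bam=str(bam),
            unstable_site_ids=frozenset(unstable), sample_id=sample_id,
        )
        bams[sample_id] = bam

    labels = pd.Series({sid: lab for sid, lab in plan}, name="label")
    labels_tsv = out / "labels.tsv"
    labels.rename_axis("sample_id").to_frame().to_csv(labels_tsv, sep="\t")
    truth_json = out / "truth.json"
    with open(truth_json, "w") as fh:
        json.dump(
            {
                "unstable_site_ids": unstable,
                "samples": {sid: asdict(t) for sid, t in truth.items()},
            },
            fh,
        )
    return Cohort(
        out_dir=out, reference_fasta=fasta, panel_bed=bed, sites_tsv=sites_tsv,
        labels_tsv=labels_tsv, truth_json=truth_json, bams=bams, labels=labels,
        sites=sites, unstable_site_ids=unstable, truth=truth,
    )
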