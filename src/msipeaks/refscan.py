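"""Microsatellite discovery in a reference genome.

A microsatellite site is a maximal run of a short tandem-repeat unit
(1-6 bp) in the reference sequence.  Runs are reported once, under their
canonical unit: the shortest period, phased at the leftmost position of
the periodic region.  Whole unit copies only; a trailing partial copy is
not part of the site but does not break maximality (no *whole* extra
unit fits on either side).

Homopolymers are kept when the tract reaches ``min_homopolymer_len``
bases (default 10); multi-base units when the copy number strictly
exceeds ``min_units_multibase`` (default 3).  N (or any non-ACGT base)
terminates a run; soft-masked lowercase bases are uppercased first,
because capture panels routinely cover repeat-masked sequence.

Coordinates are 0-based half-open everywhere, including the sites TSV,
so they can be intersected with BED intervals without conversion.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

from pyfaidx import Fasta, FastaIndexingError

from .errors import InputError, SiteParseError

_ACGT = frozenset("ACGT")

SITES_COLUMNS = ("site_id", "chrom", "start", "end", "unit", "n_units")


def _is_primitive(unit: str) -> bool:
    """True if *unit* is not a whole-number power of a shorter string."""
    p = len(unit)
    for q in range(1, p):
        if p % q == 0 and unit == unit[:q] * (p // q):
            return False
    return True


@dataclass(frozen=True, order=True)
class MicrosatelliteSite:
    """One reference microsatellite locus (0-based half-open)."""

    chrom: str
    start: int
    end: int
    unit: str
    n_units: int
    site_id: str = ""

    def __post_init__(self):
        if self.end - self.start != self.n_units * len(self.unit):
            raise ValueError(
                f"{self.site_id or self.locus}: span {self.end - self.start} "
                f"!= {self.n_units} x {len(self.unit)}-bp unit"
            )
        if not self.unit or not set(self.unit) <= _ACGT:
            raise ValueError(f"invalid repeat unit {self.unit!r}")
        if not _is_primitive(self.unit):
            raise ValueError(f"unit {self.unit!r} is itself periodic")
        if not self.site_id:
            object.__setattr__(self, "site_id", self.locus)

    @property
    def locus(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.unit}"

    @property
    def ref_tract_len(self) -> int:
        return self.end - self.start


def scan_sequence(
    chrom: str,
    seq: str,
    min_homopolymer_len: int = 10,
    min_units_multibase: int = 3,
    max_unit_len: int = 6,
) -> list[MicrosatelliteSite]:
    """Scan one sequence for maximal microsatellite runs.

    For each period ``p`` the sequence is swept for maximal stretches
    satisfying ``seq[x] == seq[x - p]``; the stretch is truncated to
    whole unit copies from its leftmost position and kept only when the
    leading unit is primitive (otherwise the same run is reported at its
    shorter period).
    """
    if min_homopolymer_len < 2:
        raise InputError("min_homopolymer_len must be >= 2")
    if not 1 <= max_unit_len <= 6:
        raise InputError("max_unit_len must be in 1..6")
    seq = seq.upper()
    n = len(seq)
    sites: list[MicrosatelliteSite] = []
    for p in range(1, max_unit_len + 1):
        x = p
        while x < n:
            if seq[x] == seq[x - p] and seq[x] in _ACGT:
                a = x - p  # leftmost position of the periodic stretch
                while x < n and seq[x] == seq[x - p] and seq[x] in _ACGT:
                    x += 1
                unit = seq[a : a + p]
                if set(unit) <= _ACGT and _is_primitive(unit):
                    n_units = (x - a) // p
                    tract = n_units * p
                    keep = (
                        tract >= min_homopolymer_len
                        if p == 1
                        else n_units > min_units_multibase
                    )
                    if keep:
                        sites.append(
                            MicrosatelliteSite(
                                chrom=chrom, start=a, end=a + tract,
                                unit=unit, n_units=n_units,
                            )
                        )
                x += 1  # a fresh stretch cannot resume inside x-p..x
            else:
                x += 1
    sites.sort(key=lambda s: (s.chrom, s.start, len(s.unit)))
    return sites


def scan_reference(
    reference: "Mapping[str, str] | str",
    min_homopolymer_len: int = 10,
    min_units_multibase: int = 3,
    max_unit_len: int = 6,
) -> list[MicrosatelliteSite]:
    """Scan a whole reference (FASTA path or mapping chrom -> sequence)."""
    if isinstance(reference, (str, bytes)):
        try:
            fasta = Fasta(str(reference), as_raw=True, sequence_always_upper=True)
        except (OSError, FastaIndexingError, ValueError) as exc:
            raise InputError(f"cannot read FASTA {reference}: {exc}") from exc
        items = ((name, str(fasta[name][:])) for name in fasta.keys())
    else:
        items = reference.items()
    sites: list[MicrosatelliteSite] = []
    for chrom, seq in items:
        if not seq:
            raise InputError(f"reference sequence {chrom!r} is empty")
        sites.extend(
            scan_sequence(
                chrom, seq, min_homopolymer_len, min_units_multibase, max_unit_len
            )
        )
    sites.sort(key=lambda s: (s.chrom, s.start, len(s.unit)))
    return sites


def read_panel_bed(path: str) -> list[tuple[str, int, int]]:
    """Read a BED3 file into sorted half-open intervals."""
    intervals = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SiteParseError(path, i, "BED line has fewer than 3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise SiteParseError(path, i, f"bad BED coordinates: {exc}") from exc
            if start < 0 or end <= start:
                raise SiteParseError(path, i, f"bad interval [{start},{end})")
            intervals.append((chrom, start, end))
    intervals.sort()
    return intervals


def intersect_panel(
    sites: Sequence[MicrosatelliteSite],
    panel: Sequence[tuple[str, int, int]],
) -> list[MicrosatelliteSite]:
    """Keep sites overlapping any panel interval by >= 1 base (half-open)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in panel:
        by_chrom.setdefault(chrom, []).append((start, end))
    kept = []
    for site in sites:
        for start, end in by_chrom.get(site.chrom, ()):
            if site.start < end and start < site.end:
                kept.append(site)
                break
    return kept


def write_sites(sites: Iterable[MicrosatelliteSite], path_or_handle) -> None:
    """Write sites as TSV (0-based half-open) with a header line."""
    own = isinstance(path_or_handle, (str, bytes))
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        fh.write("\t".join(SITES_COLUMNS) + "\n")
        for s in sites:
            fh.write(
                f"{s.site_id}\t{s.chrom}\t{s.start}\t{s.end}\t{s.unit}\t{s.n_units}\n"
            )
    finally:
        if own:
            fh.close()


def read_sites(path: str) -> list[MicrosatelliteSite]:
    """Read a sites TSV written by :func:`write_sites`."""
    sites = []
    with open(path) as fh:
        header_seen = False
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                if tuple(line.split("\t")) != SITES_COLUMNS:
                    raise SiteParseError(
                        path, i, f"expected header {'	'.join(SITES_COLUMNS)!r}"
                    )
                header_seen = True
                continue
            fields = line.split("\t")
            if len(fields) != len(SITES_COLUMNS):
                raise SiteParseError(
                    path, i, f"expected {len(SITES_COLUMNS)} columns, got {len(fields)}"
                )
            site_id, chrom, start, end, unit, n_units = fields
            try:
                site = MicrosatelliteSite(
                    chrom=chrom, start=int(start), end=int(end),
                    unit=unit, n_units=int(n_units), site_id=site_id,
                )
            except ValueError as exc:
                raise SiteParseError(path, i, str(exc)) from exc
            sites.append(site)
    return sites


def load_builtin_marker_sites() -> list[MicrosatelliteSite]:
    """The published 54-locus hg19 MSI marker panel shipped with msipeaks.

    These loci (site ids ``MS95`` .. ``MS1398``) are mononucleotide and
    TG-dinucleotide repeats selected on an 808-gene capture panel; the
    set includes the NCI consensus markers BAT-25, BAT-26, NR-21, NR-22
    and NR-24.  Coordinates were converted from the published 1-based
    inclusive table to this package's 0-based half-open convention.
    """
    ref = resources.files("msipeaks.data").joinpath("hg19_msi_54_loci.tsv")
    with resources.as_file(ref) as path:
        return read_sites(str(path))
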