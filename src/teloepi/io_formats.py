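"""Readers/writers for the formats the pipeline touches.

All genomic intervals are handled internally as 0-based half-open
``[start, end)``, the native convention of BED and bedMethyl.  Human-readable
report tables use 1-based inclusive coordinates; :func:`to_report_coords` and
:func:`from_report_coords` convert between the two and are inverses of each
other.

bedMethyl means the tab-separated per-site pileup dialect emitted by
``modkit pileup``: nine BED9 columns followed by valid coverage and percent
modified, optionally followed by seven raw count columns (18 columns total).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO

from .util import reverse_complement  # noqa: F401  (re-exported convenience)

logger = logging.getLogger(__name__)

VALID_MOD_CODES = {"m", "h", "a"}  # 5mC, 5hmC, 6mA
_ALLOWED_BASES = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class Contig:
    """A named assembly sequence; the coordinate frame for all intervals."""

    name: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AlignedRead:
    """One aligned read.

    ``sequence`` and ``qualities`` are in read (molecule) orientation, i.e.
    the bases as the sequencer emitted them; for minus-strand alignments this
    is the reverse complement of the SEQ field stored in the SAM record.
    ``ref_start``/``ref_end`` delimit the half-open reference interval the
    alignment covers.
    """

    name: str
    ref: str
    strand: str
    ref_start: int
    ref_end: int
    sequence: str
    qualities: list[int]
    is_mapped: bool = True

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.name}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )


@dataclass(frozen=True)
class BedMethylRecord:
    """One per-site modification pileup row (one strand, one base)."""

    chrom: str
    start: int
    end: int
    mod_code: str
    strand: str
    valid_cov: int
    frac_mod: float
    n_mod: int
    n_canonical: int

    @property
    def pos(self) -> int:
        return self.start


@dataclass(frozen=True)
class RegionInterval:
    """A labelled half-open genomic interval."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and start < self.end and end > self.start


# ---------------------------------------------------------------------------
# coordinate conventions
# ---------------------------------------------------------------------------

def to_report_coords(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (report convention)."""
    return start + 1, end


def from_report_coords(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start1 - 1, end1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_assembly(path: str | Path) -> dict[str, Contig]:
    """Read a FASTA assembly into an ordered ``{name: Contig}`` mapping.

    Sequences are uppercased.  Duplicate record names and characters outside
    A/C/G/T/N are rejected with a :class:`FormatError` naming the offending
    record (and line, for bad characters).
    """
    path = Path(path)
    contigs: dict[str, Contig] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise FormatError(f"{path}: duplicate sequence name {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - _ALLOWED_BASES
        if bad:
            raise FormatError(
                f"{path}: record {record.id!r} contains non-DNA character(s) "
                f"{sorted(bad)} near line {_find_bad_line(path, bad)}"
            )
        contigs[record.id] = Contig(name=record.id, sequence=seq)
    if not contigs:
        logger.warning("%s: no FASTA records found", path)
    logger.info("%s: read %d contig(s)", path, len(contigs))
    return contigs


def _find_bad_line(path: Path, bad_chars: set[str]) -> int:
    bad_upper = {c.upper() for c in bad_chars}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad_upper:
                return lineno
    return -1


def write_assembly(contigs: Iterable[Contig], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for contig in contigs:
            fh.write(f">{contig.name}\n")
            for i in range(0, contig.length, width):
                fh.write(contig.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# bedMethyl
# ---------------------------------------------------------------------------

def parse_bedmethyl(path: str | Path) -> list[BedMethylRecord]:
    """Parse a modkit-pileup bedMethyl file (11- or 18-column dialect).

    Percent-modified (0-100) is converted to ``frac_mod`` in [0, 1].  When
    the raw count columns are absent, ``n_mod`` is derived as
    ``round(frac_mod * valid_cov)``.  Unknown modification codes are kept
    verbatim and flagged with a warning.
    """
    path = Path(path)
    records: list[BedMethylRecord] = []
    unknown_codes: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise FormatError(
                    f"{path}:{lineno}: expected >=11 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                start = int(fields[1])
                end = int(fields[2])
                valid_cov = int(fields[9])
                percent = float(fields[10])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field: {exc}") from None
            mod_code = fields[3]
            if mod_code not in VALID_MOD_CODES:
                unknown_codes.add(mod_code)
            frac_mod = percent / 100.0
            if len(fields) >= 13:
                n_mod = int(fields[11])
                n_canonical = int(fields[12])
            else:
                n_mod = int(round(frac_mod * valid_cov))
                n_canonical = valid_cov - n_mod
            records.append(
                BedMethylRecord(
                    chrom=fields[0],
                    start=start,
                    end=end,
                    mod_code=mod_code,
                    strand=fields[5],
                    valid_cov=valid_cov,
                    frac_mod=frac_mod,
                    n_mod=n_mod,
                    n_canonical=n_canonical,
                )
            )
    if unknown_codes:
        logger.warning(
            "%s: unknown modification code(s) retained verbatim: %s",
            path,
            sorted(unknown_codes),
        )
    logger.info("%s: parsed %d bedMethyl record(s)", path, len(records))
    return records


def write_bedmethyl(records: Iterable[BedMethylRecord], path: str | Path) -> None:
    """Write records in the 18-column modkit pileup dialect."""
    with open(path, "w") as fh:
        for r in records:
            percent = r.frac_mod * 100.0
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.chrom,
                        r.start,
                        r.end,
                        r.mod_code,
                        r.valid_cov,
                        r.strand,
                        r.start,
                        r.end,
                        "255,0,0",
                        r.valid_cov,
                        f"{percent:.2f}",
                        r.n_mod,
                        r.n_canonical,
                        0,
                        0,
                        0,
                        0,
                        0,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[RegionInterval]:
    """Read BED3+ (column 4, when present, becomes the label)."""
    path = Path(path)
    regions: list[RegionInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >=3 columns")
            label = fields[3] if len(fields) > 3 else ""
            try:
                regions.append(
                    RegionInterval(fields[0], int(fields[1]), int(fields[2]), label)
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    logger.info("%s: read %d region(s)", path, len(regions))
    return regions


def write_bed(regions: Iterable[RegionInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")


# ---------------------------------------------------------------------------
# SAM/BAM
# ---------------------------------------------------------------------------

def load_alignments(
    path: str | Path,
    region: RegionInterval | None = None,
) -> list[AlignedRead]:
    """Load mapped reads from a SAM/BAM file, optionally restricted to reads
    whose alignment interval overlaps ``region``.

    Sequences and qualities are returned in read (molecule) orientation.
    Reads without base qualities are rejected: every downstream step needs
    them.  The file is scanned linearly, so no index is required.
    """
    path = Path(path)
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=True) as fh:
        if region is not None and region.chrom not in fh.references:
            raise ValueError(
                f"region chromosome {region.chrom!r} absent from {path} header"
            )
        for rec in fh:
            if rec.is_unmapped:
                continue
            ref_start = rec.reference_start
            ref_end = rec.reference_end
            if region is not None and not region.overlaps(
                rec.reference_name, ref_start, ref_end
            ):
                continue
            seq = rec.get_forward_sequence()
            quals = rec.get_forward_qualities()
            if seq is None or quals is None:
                raise FormatError(
                    f"{path}: read {rec.query_name} lacks sequence or base "
                    "qualities, which are required downstream"
                )
            reads.append(
                AlignedRead(
                    name=rec.query_name,
                    ref=rec.reference_name,
                    strand="-" if rec.is_reverse else "+",
                    ref_start=ref_start,
                    ref_end=ref_end,
                    sequence=seq.upper(),
                    qualities=list(quals),
                )
            )
    logger.info("%s: loaded %d mapped read(s)", path, len(reads))
    return reads
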