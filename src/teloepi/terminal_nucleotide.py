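"""Quantification of non-templated nucleotides at telomeric read ends.

Telomerase can append a single non-telomeric dT beyond the templated repeat.
On sequencing data this shows up as an excess of reads whose final
(3'-terminal) base is T among reads aligned to a chromosome-end region; the
complementary-strand signal is read ends in A.  The procedure:

1. keep reads whose overall quality passes a strict per-read filter
   (>80% of bases at or above Q35 by default);
2. conservatively trim each read end, removing terminal runs of bases below
   Q30 so the retained terminal base is confidently called;
3. isolate the last 200 bp of the trimmed read and (by default) require it
   to contain the telomeric repeat, confirming the read end is telomeric;
4. tally reads ending in T and in A, with integer half-up percentages.

All sequence handling is in read (molecule) orientation: the last base of a
read is the base the sequencer reached last, i.e. the molecule's 3' end.
A- and T-ending reads are tallied separately, without re-orientation, so the
direct and complementary-strand signals stay in separate columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io_formats import AlignedRead, RegionInterval, load_alignments, to_report_coords
from .util import percent_int, reverse_complement

logger = logging.getLogger(__name__)


@dataclass
class TrimmedRead:
    name: str
    sequence: str
    qualities: list[int]
    n_trimmed_5p: int
    n_trimmed_3p: int

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TerminalCountRow:
    """Per-region tally of read terminal bases.

    Percentages are integer, rounded half-up; ``None`` when no read passed.
    """

    region: str
    A_end: int
    T_end: int
    perc_A: int | None
    perc_T: int | None
    N_total_reads: int


def quality_filter_reads(
    reads: list[AlignedRead], q: int = 35, min_frac: float = 0.8
) -> list[AlignedRead]:
    """Keep reads with strictly more than ``min_frac`` of bases at >= ``q``."""
    kept = []
    for read in reads:
        if len(read.qualities) == 0:
            logger.warning("read %s is empty; excluded", read.name)
            continue
        frac = sum(1 for x in read.qualities if x >= q) / len(read.qualities)
        if frac > min_frac:
            kept.append(read)
    logger.info("quality filter Q%d>%.0f%%: kept %d/%d reads", q, 100 * min_frac,
                len(kept), len(reads))
    return kept


def trim_read_q30(read: AlignedRead, qmin: int = 30) -> TrimmedRead:
    """Remove terminal runs of bases with quality < ``qmin`` from both ends.

    Interior bases are never touched; a read that is low-quality throughout
    trims to an empty sequence (excluded downstream).
    """
    quals = read.qualities
    lo, hi = 0, len(quals)
    while lo < hi and quals[lo] < qmin:
        lo += 1
    while hi > lo and quals[hi - 1] < qmin:
        hi -= 1
    return TrimmedRead(
        name=read.name,
        sequence=read.sequence[lo:hi],
        qualities=list(quals[lo:hi]),
        n_trimmed_5p=lo,
        n_trimmed_3p=len(quals) - hi,
    )


def terminal_window(read: TrimmedRead, window: int = 200) -> str:
    """The final ``min(window, len)`` bases of the trimmed read."""
    if len(read) == 0:
        raise ValueError(f"read {read.name} trimmed to empty sequence")
    return read.sequence[-window:]


def count_terminal_bases(
    reads: list[AlignedRead],
    region: RegionInterval,
    qmin: int = 30,
    window: int = 200,
    require_motif: bool = True,
    motif: str = "GGTGGCGG",
) -> TerminalCountRow:
    """Trim, optionally confirm telomeric context, and tally terminal bases.

    A read contributes to ``N_total_reads`` when it survives trimming with a
    non-empty sequence and — if ``require_motif`` — its terminal window
    contains the telomeric repeat or its reverse complement.
    """
    start1, end1 = to_report_coords(region.start, region.end)
    label = f"{region.chrom}:{start1}-{end1}"
    motif_rc = reverse_complement(motif)
    n_total = a_end = t_end = 0
    for read in reads:
        trimmed = trim_read_q30(read, qmin=qmin)
        if len(trimmed) == 0:
            continue
        suffix = terminal_window(trimmed, window=window)
        if require_motif and motif not in suffix and motif_rc not in suffix:
            continue
        n_total += 1
        last = trimmed.sequence[-1]
        if last == "A":
            a_end += 1
        elif last == "T":
            t_end += 1
    if n_total == 0:
        return TerminalCountRow(label, 0, 0, None, None, 0)
    return TerminalCountRow(
        region=label,
        A_end=a_end,
        T_end=t_end,
        perc_A=percent_int(a_end, n_total),
        perc_T=percent_int(t_end, n_total),
        N_total_reads=n_total,
    )


def terminal_table(
    alignment_path,
    regions: list[RegionInterval],
    q_filter: int = 35,
    min_frac: float = 0.8,
    qmin: int = 30,
    window: int = 200,
    require_motif: bool = True,
    motif: str = "GGTGGCGG",
) -> list[TerminalCountRow]:
    """One :class:`TerminalCountRow` per region, in input order.

    The per-read Q35 filter is applied before trimming, mirroring a
    filter-then-analyse workflow.
    """
    rows = []
    for region in regions:
        reads = load_alignments(alignment_path, region=region)
        reads = quality_filter_reads(reads, q=q_filter, min_frac=min_frac)
        rows.append(
            count_terminal_bases(
                reads, region, qmin=qmin, window=window,
                require_motif=require_motif, motif=motif,
            )
        )
    return rows


def terminal_frame(rows: list[TerminalCountRow]) -> pd.DataFrame:
    """Tabulate rows with NA percentages where no read qualified."""
    return pd.DataFrame(
        [
            {
                "Region": r.region,
                "A_end": r.A_end,
                "T_end": r.T_end,
                "perc_A": "NA" if r.perc_A is None else r.perc_A,
                "perc_T": "NA" if r.perc_T is None else r.perc_T,
                "N_total_reads": r.N_total_reads,
            }
            for r in rows
        ],
        columns=["Region", "A_end", "T_end", "perc_A", "perc_T", "N_total_reads"],
    )
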