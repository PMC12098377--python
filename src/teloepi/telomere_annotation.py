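"""Detection of tandem telomeric repeat arrays at contig ends.

The detector scans a fixed window at each contig end for exact copies of the
repeat unit — the 3' arm with the motif as given, the 5' arm with its
reverse complement — merges motif-covered positions into runs tolerating
short gaps (degenerate copies), and reports at most one terminal array per
arm.  Exact matching with a gap allowance keeps the operator deterministic;
no fuzzy matching is attempted.

Report coordinates are 1-based inclusive, so ``length == end - start + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import Contig, RegionInterval, to_report_coords
from .util import is_strict_dna, reverse_complement


@dataclass(frozen=True)
class TelomereAnnotation:
    """One telomeric array call; ``start``/``end`` are 1-based inclusive."""

    chrom: str
    arm: str  # "5_prime" | "3_prime"
    start: int
    end: int
    motif: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def as_interval(self) -> RegionInterval:
        return RegionInterval(self.chrom, self.start - 1, self.end, f"Telomere_{self.arm}")


def _match_positions(window: str, motif: str) -> list[tuple[int, int]]:
    """Half-open intervals of every exact motif occurrence in ``window``."""
    hits = []
    i = window.find(motif)
    while i != -1:
        hits.append((i, i + len(motif)))
        i = window.find(motif, i + 1)
    return hits


def _merge_runs(hits: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    """Merge overlapping/nearby match intervals into runs (gap <= max_gap)."""
    runs: list[list[int]] = []
    for s, e in hits:
        if runs and s - runs[-1][1] <= max_gap:
            runs[-1][1] = max(runs[-1][1], e)
        else:
            runs.append([s, e])
    return [(s, e) for s, e in runs]


def annotate_telomeres(
    contig: Contig,
    motif: str = "GGTGGCGG",
    max_search: int = 2000,
    max_gap: int = 8,
    min_copies: int = 3,
    motif_5p: str | None = None,
) -> list[TelomereAnnotation]:
    """Find the telomeric array, if any, at each end of ``contig``.

    A run of exact motif matches (allowing internal gaps of at most
    ``max_gap`` bp) is reported when it covers at least ``min_copies *
    len(motif)`` bp and begins within ``max_gap`` bp of the contig terminus.
    The 5' arm is searched with ``reverse_complement(motif)`` unless an
    explicit 5' unit ``motif_5p`` is supplied (the two published end motifs
    of a genome need not be exact reverse complements).  Ties between runs
    equally close to the terminus go to the longer run, then the smaller
    start.
    """
    if len(motif) < 4:
        raise ValueError("motif must be at least 4 bp")
    if not is_strict_dna(motif) or (motif_5p is not None and not is_strict_dna(motif_5p)):
        raise ValueError("motif must contain only A/C/G/T")
    max_search = min(max_search, contig.length)
    min_len = min_copies * len(motif)
    out: list[TelomereAnnotation] = []

    # 5' arm: leftmost window, run must begin near position 0
    five_unit = motif_5p if motif_5p is not None else reverse_complement(motif)
    window = contig.sequence[:max_search]
    runs = [
        (s, e)
        for s, e in _merge_runs(_match_positions(window, five_unit), max_gap)
        if e - s >= min_len and s <= max_gap
    ]
    if runs:
        s, e = min(runs, key=lambda r: (r[0], -(r[1] - r[0])))
        r_start, r_end = to_report_coords(s, e)
        out.append(TelomereAnnotation(contig.name, "5_prime", r_start, r_end, five_unit))

    # 3' arm: rightmost window, run must end near the contig terminus
    offset = contig.length - max_search
    window = contig.sequence[offset:]
    runs = [
        (s, e)
        for s, e in _merge_runs(_match_positions(window, motif), max_gap)
        if e - s >= min_len and max_search - e <= max_gap
    ]
    if runs:
        s, e = min(runs, key=lambda r: (max_search - r[1], -(r[1] - r[0]), r[0]))
        r_start, r_end = to_report_coords(offset + s, offset + e)
        out.append(TelomereAnnotation(contig.name, "3_prime", r_start, r_end, motif))
    return out


def annotate_assembly(
    contigs: dict[str, Contig], motif: str = "GGTGGCGG", **kwargs
) -> list[TelomereAnnotation]:
    """Annotate every contig of an assembly."""
    out: list[TelomereAnnotation] = []
    for contig in contigs.values():
        out.extend(annotate_telomeres(contig, motif, **kwargs))
    return out


def telomere_report(annotations: list[TelomereAnnotation]) -> pd.DataFrame:
    """Tabulate annotations: Name, Start, End, Length, Motif, Feature."""
    rows = [
        {
            "Name": a.chrom,
            "Start": a.start,
            "End": a.end,
            "Length": a.length,
            "Motif": a.motif,
            "Feature": f"Telomere_{a.arm}",
        }
        for a in sorted(annotations, key=lambda a: (a.chrom, a.arm))
    ]
    return pd.DataFrame(rows, columns=["Name", "Start", "End", "Length", "Motif", "Feature"])
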