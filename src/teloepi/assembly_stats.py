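"""Small assembly/read-set comparison statistics."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import Contig
from .util import round_half_up


@dataclass(frozen=True)
class LengthDeltaRow:
    name: str
    long_len: int
    short_len: int
    delta_pct: float


def length_delta_percent(long_len: int, short_len: int) -> float:
    """Relative length difference ``100*(long-short)/short`` in percent,
    rounded half-up to 3 decimals.  Negative when the first assembly is
    shorter."""
    if short_len == 0:
        raise ValueError("short assembly length must be positive")
    return round_half_up(100.0 * (long_len - short_len) / short_len, 3)


def length_delta_table(
    long_contigs: dict[str, Contig], short_contigs: dict[str, Contig]
) -> pd.DataFrame:
    """Per-contig length comparison of two assemblies sharing contig names."""
    rows = []
    for name, contig in long_contigs.items():
        if name not in short_contigs:
            continue
        rows.append(
            {
                "Contig_Name": name,
                "Long_len": contig.length,
                "Short_len": short_contigs[name].length,
                "Delta_pct": length_delta_percent(contig.length, short_contigs[name].length),
            }
        )
    return pd.DataFrame(rows, columns=["Contig_Name", "Long_len", "Short_len", "Delta_pct"])


def n50(lengths: list[int]) -> int:
    """Largest L such that sequences of length >= L hold at least half of
    the total bases."""
    if not lengths:
        raise ValueError("empty length list")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2.0
    acc = 0
    for x in ordered:
        acc += x
        if acc >= half:
            return x
    raise AssertionError("unreachable")


def read_length_stats(lengths: list[int]) -> dict[str, float]:
    """N50, read count and total gigabases of a read set."""
    total = sum(lengths)
    return {
        "n50": n50(lengths),
        "n_reads": len(lengths),
        "total_gb": total / 1e9,
        "mean_length": total / len(lengths),
    }
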