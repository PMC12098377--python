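"""Thresholding, density profiles and motif context of DNA modifications.

Works from per-site bedMethyl pileup records (5mC ``m``, 5hmC ``h``, 6mA
``a``).  A site counts as modified when its modified fraction exceeds 0.5
and its valid coverage exceeds 10 reads (both strict).  Downstream
summaries:

* per-modification totals against the genomic base composition (the
  fraction of all adenines, or cytosines, that are modified; both strands);
* per-chromosome density, in two interpretations (see
  :func:`density_table`), and 1-kb binned counts for plotting;
* interval intersections (e.g. "is there any 5mC in the rDNA locus?");
* +/-10 bp sequence windows around modified sites, the input for motif
  discovery, plus a light-weight k-mer enrichment scorer with a
  dinucleotide-preserving shuffle null.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import BedMethylRecord, Contig, RegionInterval
from .util import reverse_complement, round_half_up

logger = logging.getLogger(__name__)


@dataclass
class ModSiteSet:
    """Modification sites that passed the frequency/coverage threshold."""

    sites: list[BedMethylRecord]
    min_frac: float
    min_cov: int

    def by_code(self, mod_code: str) -> list[BedMethylRecord]:
        return [s for s in self.sites if s.mod_code == mod_code]

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class ModificationSummary:
    """Total thresholded sites per modification and their share of the
    genomic A (for 6mA) or C (for 5mC/5hmC) content, both strands."""

    n_sites: dict[str, int]
    pct_of_base: dict[str, float]
    base_counts: dict[str, int]


@dataclass
class DensityRow:
    chrom: str
    n_mod: int
    density_per_bp: float
    density_per_kbp: float
    density_per_bp_raw: float
    density_per_kbp_raw: float


@dataclass
class MotifWindow:
    """A +/-flank window around one modified base, reference orientation."""

    chrom: str
    win_start: int
    win_end: int
    center: int
    sequence: str
    clamped: bool = False
    strand: str = "+"


# ---------------------------------------------------------------------------
# thresholding and summaries
# ---------------------------------------------------------------------------

def threshold_sites(
    records: list[BedMethylRecord], min_frac: float = 0.5, min_cov: int = 10
) -> ModSiteSet:
    """Keep records with ``frac_mod > min_frac`` and ``valid_cov > min_cov``
    (both strictly greater)."""
    sites = [r for r in records if r.frac_mod > min_frac and r.valid_cov > min_cov]
    counts = Counter(s.mod_code for s in sites)
    logger.info(
        "threshold frac>%s cov>%s: kept %d/%d sites (%s)",
        min_frac, min_cov, len(sites), len(records), dict(counts),
    )
    return ModSiteSet(sites=sites, min_frac=min_frac, min_cov=min_cov)


def _base_census(contigs: dict[str, Contig]) -> dict[str, int]:
    total: Counter = Counter()
    for contig in contigs.values():
        total.update(contig.sequence)
    return dict(total)


def modification_summary(
    siteset: ModSiteSet, contigs: dict[str, Contig]
) -> ModificationSummary:
    """Count thresholded sites per modification against base composition.

    The denominator for 6mA is the number of adenines on both strands
    (#A + #T of the top strand); for 5mC/5hmC the number of cytosines on
    both strands (#C + #G).  N bases never enter a denominator.
    """
    if not contigs:
        raise ValueError("empty assembly")
    census = _base_census(contigs)
    denominators = {
        "a": census.get("A", 0) + census.get("T", 0),
        "m": census.get("C", 0) + census.get("G", 0),
        "h": census.get("C", 0) + census.get("G", 0),
    }
    n_sites = {code: len(siteset.by_code(code)) for code in ("m", "h", "a")}
    pct = {}
    for code, n in n_sites.items():
        denom = denominators[code]
        if denom == 0 and n > 0:
            raise ValueError(f"no target base in assembly for modification {code!r}")
        pct[code] = 100.0 * n / denom if denom else 0.0
    return ModificationSummary(n_sites=n_sites, pct_of_base=pct, base_counts=denominators)


def density_table(
    siteset: ModSiteSet,
    contigs: dict[str, Contig],
    mode: str = "inferred",
    mod_code: str | None = "a",
) -> list[DensityRow]:
    """Per-chromosome modification density, one row per contig.

    ``inferred`` (default): per-base density = sites / contig length, and
    per-kbp density = sites / 1000 (i.e. mean sites per kilobase assuming a
    megabase-scale chromosome is ~1000 kb — the count in units of thousands).
    ``literal``: the modified-read fraction summed over sites,
    ``sum(n_mod) / (sum(n_mod) + sum(n_canonical))``, divided by the contig
    length or by 1000.  Both interpretations are logged side by side; values
    are reported raw and rounded half-up to 4 decimals.
    """
    if mode not in ("inferred", "literal"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for contig in contigs.values():
        if contig.length == 0:
            raise ValueError(f"contig {contig.name} has zero length")
        sites = [
            s
            for s in siteset.sites
            if s.chrom == contig.name and (mod_code is None or s.mod_code == mod_code)
        ]
        n = len(sites)
        total_mod = sum(s.n_mod for s in sites)
        total_can = sum(s.n_canonical for s in sites)
        frac = total_mod / (total_mod + total_can) if (total_mod + total_can) else 0.0
        inferred = (n / contig.length, n / 1000.0)
        literal = (frac / contig.length, frac / 1000.0)
        logger.info(
            "%s: n=%d inferred per-bp/per-kbp = %.6g/%.6g, literal = %.6g/%.6g",
            contig.name, n, *inferred, *literal,
        )
        per_bp, per_kbp = inferred if mode == "inferred" else literal
        rows.append(
            DensityRow(
                chrom=contig.name,
                n_mod=n,
                density_per_bp=round_half_up(per_bp, 4),
                density_per_kbp=round_half_up(per_kbp, 4),
                density_per_bp_raw=per_bp,
                density_per_kbp_raw=per_kbp,
            )
        )
    return rows


def binned_density(
    siteset: ModSiteSet,
    contigs: dict[str, Contig],
    binsize: int = 1000,
    mod_code: str | None = "a",
) -> dict[str, list[tuple[int, int]]]:
    """Site counts in half-open ``[k*binsize, (k+1)*binsize)`` bins per
    contig; the last bin is truncated at the contig end.  Bin counts always
    sum to the number of sites on the contig."""
    if binsize < 1:
        raise ValueError("binsize must be >= 1")
    out: dict[str, list[tuple[int, int]]] = {}
    for contig in contigs.values():
        n_bins = max(1, math.ceil(contig.length / binsize))
        positions = [
            s.start
            for s in siteset.sites
            if s.chrom == contig.name and (mod_code is None or s.mod_code == mod_code)
        ]
        counts = np.bincount(
            np.asarray(positions, dtype=int) // binsize, minlength=n_bins
        )
        out[contig.name] = [(i * binsize, int(c)) for i, c in enumerate(counts)]
    return out


def region_site_count(
    siteset: ModSiteSet, region: RegionInterval, mod_code: str | None = None
) -> int:
    """Thresholded sites of ``mod_code`` whose position falls in the
    half-open region."""
    return sum(
        1
        for s in siteset.sites
        if s.chrom == region.chrom
        and region.start <= s.start < region.end
        and (mod_code is None or s.mod_code == mod_code)
    )


# ---------------------------------------------------------------------------
# windows around modified sites
# ---------------------------------------------------------------------------

def extract_windows(
    siteset: ModSiteSet,
    contigs: dict[str, Contig],
    flank: int = 10,
    bed_path: str | Path | None = None,
    fasta_path: str | Path | None = None,
    stranded: bool = False,
) -> list[MotifWindow]:
    """Extract ``[pos-flank, pos+flank+1)`` sequence windows around each
    thresholded site (21 bp for the default flank of 10).

    Windows that would overhang a contig are clamped to the contig bounds
    and flagged, not dropped, so the number of windows equals the number of
    usable sites.  Sequences are emitted in reference orientation unless
    ``stranded``, in which case minus-strand sites are reverse-complemented.
    Sites on unknown contigs or beyond the contig end are skipped with a
    warning.
    """
    windows: list[MotifWindow] = []
    for site in siteset.sites:
        contig = contigs.get(site.chrom)
        if contig is None:
            logger.warning("site %s:%d on unknown contig; skipped", site.chrom, site.start)
            continue
        if site.start >= contig.length:
            logger.warning(
                "site %s:%d beyond contig end (%d); skipped",
                site.chrom, site.start, contig.length,
            )
            continue
        start = max(0, site.start - flank)
        end = min(contig.length, site.start + flank + 1)
        seq = contig.sequence[start:end]
        strand = site.strand if site.strand in "+-" else "+"
        if stranded and strand == "-":
            seq = reverse_complement(seq)
        windows.append(
            MotifWindow(
                chrom=site.chrom,
                win_start=start,
                win_end=end,
                center=site.start,
                sequence=seq,
                clamped=(end - start) < 2 * flank + 1,
                strand=strand,
            )
        )
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for w in windows:
                fh.write(f"{w.chrom}\t{w.win_start}\t{w.win_end}\t{w.center}\t0\t{w.strand}\n")
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for w in windows:
                fh.write(f">{w.chrom}:{w.win_start}-{w.win_end}({w.center})\n{w.sequence}\n")
    return windows


# ---------------------------------------------------------------------------
# k-mer enrichment against a dinucleotide-preserving null
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle ``seq`` preserving its exact dinucleotide counts
    (random Eulerian-path reshuffle of the dinucleotide multigraph)."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    inner = [v for v in edges if v != last]
    # designate one exit edge per non-terminal vertex so that following the
    # designated exits always reaches the terminal vertex, then randomise
    # the order of the remaining exits
    while True:
        exit_edge = {v: edges[v][int(rng.integers(len(edges[v])))] for v in inner}
        ok = True
        for v in inner:
            u, seen = v, set()
            while u != last and u in exit_edge and u not in seen:
                seen.add(u)
                u = exit_edge[u]
            if u != last:
                ok = False
                break
        if ok:
            break
    order: dict[str, list[str]] = {}
    for v, outs in edges.items():
        pool = list(outs)
        if v in exit_edge:
            pool.remove(exit_edge[v])
        rng.shuffle(pool)
        order[v] = pool + ([exit_edge[v]] if v in exit_edge else [])
    ptr = {v: 0 for v in order}
    out = [seq[0]]
    u = seq[0]
    for _ in range(len(seq) - 1):
        nxt = order[u][ptr[u]]
        ptr[u] += 1
        out.append(nxt)
        u = nxt
    return "".join(out)


def _count_kmers(seqs: list[str], k: int) -> Counter:
    counts: Counter = Counter()
    for s in seqs:
        for i in range(len(s) - k + 1):
            counts[s[i : i + k]] += 1
    return counts


def kmer_enrichment(
    windows: list[MotifWindow] | list[str],
    k: int = 7,
    n_shuffles: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every observed k-mer against a per-window
    dinucleotide-preserving shuffle null.

    For each k-mer: ``score = (observed - mean_null) / sd_null`` where the
    null distribution comes from ``n_shuffles`` rounds of shuffling every
    window independently.  When the null sd is 0 (the k-mer never appeared
    in any shuffle) the z-score is undefined; such a k-mer is almost always
    a sampling zero — a low-count k-mer the finite null simply missed — so
    it falls back to the excess count ``observed - mean_null`` rather than
    infinity, which would let every singleton outrank genuinely recurrent
    motifs.  The result is ranked by descending score, ties broken
    lexicographically.  This is a deliberately simple enrichment screen, not
    a motif-discovery EM; it reports z-like scores, not E-values.
    """
    seqs = [w.sequence if isinstance(w, MotifWindow) else w for w in windows]
    if len(seqs) < 10:
        raise ValueError("need at least 10 windows for enrichment scoring")
    if k > min(len(s) for s in seqs):
        raise ValueError("k exceeds the shortest window length")
    rng = np.random.default_rng(seed)
    observed = _count_kmers(seqs, k)
    null_counts: dict[str, np.ndarray] = {
        kmer: np.zeros(n_shuffles) for kmer in observed
    }
    for r in range(n_shuffles):
        shuffled = [dinucleotide_shuffle(s, rng) for s in seqs]
        round_counts = _count_kmers(shuffled, k)
        for kmer in null_counts:
            null_counts[kmer][r] = round_counts.get(kmer, 0)
    rows = []
    for kmer, obs in observed.items():
        null = null_counts[kmer]
        mean, sd = float(null.mean()), float(null.std())
        score = (obs - mean) / sd if sd > 0.0 else float(obs - mean)
        rows.append(
            {"kmer": kmer, "observed": obs, "null_mean": mean, "null_sd": sd, "score": score}
        )
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["score", "kmer"], ascending=[False, True], ignore_index=True
    )
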