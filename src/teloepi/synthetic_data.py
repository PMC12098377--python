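"""Synthetic genomes, long reads and modification pileups with ground truth.

The generator emulates the data layout the downstream analyses assume:

* chromosomes carrying tandem telomeric arrays at both ends — the published
  3' repeat unit ``GGTGGCGG`` on the top strand at the right (3') end and its
  reverse complement at the left (5') end;
* long reads sampled across each chromosome; a read whose alignment runs off
  a chromosome end such that the *molecule's own 3' terminus* coincides with
  the chromosome terminus may carry one extra non-templated thymidine, the
  signature of telomerase-mediated dT addition.  For a plus-strand read this
  is the right end of the chromosome (T appended to the molecule, stored
  soft-clipped at the alignment's right edge); for a minus-strand read it is
  the left end (the molecule ends in T; the SAM record, stored in reference
  orientation, shows a soft-clipped A prepended at the alignment's left
  edge);
* a per-site modification pileup in bedMethyl form: every planted 6mA site
  sits 1-4 bp upstream of a planted ``TCCACCA`` motif and is emitted with
  high modified fraction and coverage, while cytosines pick up sporadic
  5mC/5hmC false-positive records that always fail the frequency/coverage
  threshold.

Every random decision is recorded in a :class:`TruthTable` so each pipeline
stage can be checked against exact ground truth.  A single global seed
drives everything; per-contig and per-stage substreams are derived from it,
so identical configurations produce byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .io_formats import Contig, RegionInterval, write_assembly, write_bed, write_bedmethyl, BedMethylRecord
from .util import is_strict_dna, reverse_complement

_BASES = np.array(list("ACGT"))

# fixed offsets that separate the rng substreams of the three stages
_STREAM_GENOME = 0
_STREAM_READS = 1
_STREAM_PILEUP = 2


@dataclass
class SimulationConfig:
    """Knobs of the generator.  Defaults describe a small diploid-free yeast
    chromosome-end scenario: 8-bp telomere unit, ~70% of end-spanning
    molecules carrying the non-templated dT, Phred ~40 read bodies with
    termini dipping to the Q30 floor, and 6mA planted 1-4 bp upstream of a
    TCCACCA motif at 90% modified fraction and 30x coverage."""

    seed: int = 42
    n_contigs: int = 2
    contig_length: int = 50_000
    telomere_motif: str = "GGTGGCGG"
    telomere_copies: int = 20
    p_terminal_T: float = 0.7
    read_length_mean: int = 5_000
    min_read_length: int = 500
    read_depth: float = 25.0
    q_high: int = 40
    q_low: int = 30
    motif_6mA: str = "TCCACCA"
    motif_offset_range: tuple[int, int] = (1, 4)
    n_motif_sites: int = 40
    per_site_frac_6mA: float = 0.9
    per_site_cov: int = 30
    fp_rate_5mC: float = 0.002
    fp_rate_5hmC: float = 0.001

    def validate(self) -> None:
        for name in ("p_terminal_T", "per_site_frac_6mA", "fp_rate_5mC", "fp_rate_5hmC"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("telomere_motif", "motif_6mA"):
            if not is_strict_dna(getattr(self, name)):
                raise ValueError(f"{name} must contain only A/C/G/T")
        if self.telomere_copies * len(self.telomere_motif) >= self.contig_length / 4:
            raise ValueError("telomeric arrays would occupy too much of the contig")
        lo, hi = self.motif_offset_range
        if not (1 <= lo <= hi):
            raise ValueError("motif_offset_range must be a positive interval")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")
        if not (2 <= self.q_low <= self.q_high <= 60):
            raise ValueError("need 2 <= q_low <= q_high <= 60")


@dataclass
class ReadTruth:
    """Ground-truth placement of one simulated read."""

    name: str
    ref: str
    start: int
    end: int
    strand: str
    has_addition: bool


@dataclass
class TruthTable:
    """Everything the generator decided, for verification downstream."""

    terminal_T_reads: set[str] = field(default_factory=set)
    planted_6mA_sites: list[tuple[str, int]] = field(default_factory=list)
    planted_motif_sites: list[tuple[str, int]] = field(default_factory=list)
    telomere_intervals: list[RegionInterval] = field(default_factory=list)
    reads: list[ReadTruth] = field(default_factory=list)

    def three_prime_intervals(self) -> list[RegionInterval]:
        return [r for r in self.telomere_intervals if r.label.endswith("3_prime")]

    def reads_overlapping(self, region: RegionInterval) -> list[ReadTruth]:
        return [r for r in self.reads if region.overlaps(r.ref, r.start, r.end)]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "terminal_T_reads": sorted(self.terminal_T_reads),
            "planted_6mA_sites": [list(t) for t in self.planted_6mA_sites],
            "planted_motif_sites": [list(t) for t in self.planted_motif_sites],
            "telomere_intervals": [asdict(r) for r in self.telomere_intervals],
            "reads": [asdict(r) for r in self.reads],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        return cls(
            terminal_T_reads=set(payload["terminal_T_reads"]),
            planted_6mA_sites=[tuple(t) for t in payload["planted_6mA_sites"]],
            planted_motif_sites=[tuple(t) for t in payload["planted_motif_sites"]],
            telomere_intervals=[RegionInterval(**d) for d in payload["telomere_intervals"]],
            reads=[ReadTruth(**d) for d in payload["reads"]],
        )


def _rng(config: SimulationConfig, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream, index])


def _pick_junction_base(left: str, right: str, unit: str) -> str:
    """Pick a base for the position between ``left`` and ``right`` such that
    no occurrence of ``unit`` spans that position."""
    for cand in "ACGT":
        window = left + cand + right
        pos = len(left)
        if not any(
            window[s : s + len(unit)] == unit
            for s in range(max(0, pos - len(unit) + 1), pos + 1)
        ):
            return cand
    raise ValueError(f"cannot break tandem continuation of unit {unit!r}")


def _scrub_unit(body: np.ndarray, unit: str, at_start: bool, span: int) -> None:
    """Destroy chance occurrences of ``unit`` in the first/last ``span``
    bases of the body, so a detector merging runs across small gaps cannot
    extend a telomeric array into the body."""
    k = len(unit)
    while True:
        segment = "".join(body[:span] if at_start else body[-span:])
        i = segment.find(unit)
        if i == -1:
            return
        offset = 0 if at_start else len(body) - span
        mid = offset + i + k // 2
        left = "".join(body[max(0, mid - k + 1) : mid])
        right = "".join(body[mid + 1 : mid + k])
        body[mid] = _pick_junction_base(left, right, unit)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> tuple[dict[str, Contig], TruthTable]:
    """Build contigs with telomeric arrays and planted 6mA/motif sites.

    Layout per contig: ``revcomp(motif) * copies`` + random body + ``motif *
    copies``.  Within the body, ``n_motif_sites`` non-overlapping TCCACCA
    occurrences are planted; for each, one adenine is forced 1-4 bp upstream
    of the motif start and recorded as the modified base.
    """
    config.validate()
    truth = TruthTable()
    contigs: dict[str, Contig] = {}
    arm_len = config.telomere_copies * len(config.telomere_motif)
    motif = config.motif_6mA
    off_lo, off_hi = config.motif_offset_range
    for ci in range(config.n_contigs):
        rng = _rng(config, _STREAM_GENOME, ci)
        name = f"chr{ci + 1}"
        body_len = config.contig_length - 2 * arm_len
        body = rng.choice(_BASES, size=body_len)

        # non-overlapping motif slots: one uniform draw inside each of
        # n_motif_sites equal chunks, with margins for the upstream adenine
        # and the +/-10 bp windows extracted later
        margin = 40
        slot = (body_len - 2 * margin) // config.n_motif_sites
        if slot < len(motif) + off_hi + margin:
            raise ValueError("body too short for the requested number of motif sites")
        for si in range(config.n_motif_sites):
            lo = margin + si * slot + off_hi
            start = int(rng.integers(lo, lo + slot - len(motif) - margin))
            body[start : start + len(motif)] = list(motif)
            offset = int(rng.integers(off_lo, off_hi + 1))
            body[start - offset] = "A"
            contig_start = arm_len + start
            truth.planted_motif_sites.append((name, contig_start))
            truth.planted_6mA_sites.append((name, contig_start - offset))

        # the body base adjacent to each array must not extend the tandem
        # pattern, otherwise the true array interval would be ambiguous
        unit5 = reverse_complement(config.telomere_motif)
        k = len(config.telomere_motif)
        body[0] = _pick_junction_base(
            unit5[-(k - 1):], "".join(body[1:k]), unit5
        )
        body[-1] = _pick_junction_base(
            "".join(body[-k:-1]), config.telomere_motif[: k - 1],
            config.telomere_motif,
        )
        _scrub_unit(body, unit5, at_start=True, span=3 * k)
        _scrub_unit(body, config.telomere_motif, at_start=False, span=3 * k)
        seq = (
            unit5 * config.telomere_copies
            + "".join(body)
            + config.telomere_motif * config.telomere_copies
        )
        contigs[name] = Contig(name=name, sequence=seq)
        truth.telomere_intervals.append(
            RegionInterval(name, 0, arm_len, "Telomere_5_prime")
        )
        truth.telomere_intervals.append(
            RegionInterval(
                name, config.contig_length - arm_len, config.contig_length,
                "Telomere_3_prime",
            )
        )
    return contigs, truth


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(
    contigs: dict[str, Contig],
    truth: TruthTable,
    config: SimulationConfig,
    fastq_path: str | Path,
    sam_path: str | Path,
) -> TruthTable:
    """Sample error-free long reads, write FASTQ + SAM, update the truth.

    Molecule placement is uniform on an extended axis and clipped to the
    contig, so both chromosome ends accumulate reads that terminate exactly
    at the terminus — as real telomeric reads do.  Read lengths are
    geometric around ``read_length_mean``.  Base qualities are ``q_high``
    in the body; the three bases at each molecule end are drawn uniformly
    from ``[q_low, q_high]`` to imitate noisier termini.
    """
    config.validate()
    header = pysam.AlignmentHeader.from_references(
        [c.name for c in contigs.values()], [c.length for c in contigs.values()]
    )
    with open(fastq_path, "w") as fq, pysam.AlignmentFile(
        str(sam_path), "wh", header=header
    ) as sam:
        for ci, contig in enumerate(contigs.values()):
            rng = _rng(config, _STREAM_READS, ci)
            _simulate_contig_reads(contig, ci, truth, config, rng, fq, sam)
    return truth


def _simulate_contig_reads(contig, ref_id, truth, config, rng, fq, sam) -> None:
    L = contig.length
    n_reads = int(round(config.read_depth * L / config.read_length_mean))
    made = 0
    while made < n_reads:
        length = int(rng.geometric(1.0 / config.read_length_mean))
        s = int(rng.integers(-config.read_length_mean, L))
        start, end = max(0, s), min(s + length, L)
        if end - start < config.min_read_length:
            continue
        strand = "-" if rng.random() < 0.5 else "+"
        # the molecule's 3' terminus sits at a chromosome end?
        at_3prime_terminus = (strand == "+" and end == L) or (strand == "-" and start == 0)
        add_T = at_3prime_terminus and rng.random() < config.p_terminal_T
        name = f"{contig.name}_read{made:06d}"

        aligned = contig.sequence[start:end]
        if strand == "+":
            molecule = aligned + ("T" if add_T else "")
            stored = molecule
            cigar = f"{end - start}M" + ("1S" if add_T else "")
            flag = 0
        else:
            molecule = reverse_complement(aligned) + ("T" if add_T else "")
            stored = ("A" if add_T else "") + aligned
            cigar = ("1S" if add_T else "") + f"{end - start}M"
            flag = 16

        quals = np.full(len(molecule), config.q_high, dtype=np.int64)
        k = min(3, len(molecule))
        quals[:k] = rng.integers(config.q_low, config.q_high + 1, size=k)
        quals[-k:] = rng.integers(config.q_low, config.q_high + 1, size=k)

        fq.write(
            f"@{name}\n{molecule}\n+\n"
            + "".join(chr(q + 33) for q in quals)
            + "\n"
        )
        rec = pysam.AlignedSegment(header=sam.header)
        rec.query_name = name
        rec.flag = flag
        rec.reference_id = ref_id
        rec.reference_start = start
        rec.mapping_quality = 60
        rec.cigarstring = cigar
        rec.query_sequence = stored
        # SAM stores minus-strand reads in reference orientation
        rec.query_qualities = list(quals[::-1] if strand == "-" else quals)
        sam.write(rec)

        if add_T:
            truth.terminal_T_reads.add(name)
        truth.reads.append(
            ReadTruth(name=name, ref=contig.name, start=start, end=end,
                      strand=strand, has_addition=add_T)
        )
        made += 1


# ---------------------------------------------------------------------------
# modification pileup
# ---------------------------------------------------------------------------

def simulate_bedmethyl(
    contigs: dict[str, Contig],
    truth: TruthTable,
    config: SimulationConfig,
    path: str | Path,
) -> list[BedMethylRecord]:
    """Emit a bedMethyl pileup: confident 6mA at every planted site plus
    always-sub-threshold 5mC/5hmC noise on cytosines of either strand.

    A false-positive record fails the frequency>0.5 / coverage>10 threshold
    by construction: half of them get a low modified fraction at full
    coverage, the other half a high fraction at coverage <= 10.
    """
    config.validate()
    records: list[BedMethylRecord] = []
    cov = config.per_site_cov
    n_mod = int(round(config.per_site_frac_6mA * cov))
    for chrom, pos in truth.planted_6mA_sites:
        records.append(
            BedMethylRecord(
                chrom=chrom, start=pos, end=pos + 1, mod_code="a", strand="+",
                valid_cov=cov, frac_mod=config.per_site_frac_6mA,
                n_mod=n_mod, n_canonical=cov - n_mod,
            )
        )
    for ci, contig in enumerate(contigs.values()):
        rng = _rng(config, _STREAM_PILEUP, ci)
        arr = np.frombuffer(contig.sequence.encode(), dtype="S1")
        for code, rate in (("m", config.fp_rate_5mC), ("h", config.fp_rate_5hmC)):
            if rate <= 0:
                continue
            for strand, base in (("+", b"C"), ("-", b"G")):
                positions = np.flatnonzero(arr == base)
                hits = positions[rng.random(positions.size) < rate]
                for pos in hits:
                    if rng.random() < 0.5:
                        fp_cov = cov
                        fp_mod = int(round(rng.uniform(0.05, 0.45) * fp_cov))
                        fp_mod = min(fp_mod, fp_cov // 2)  # keep fraction <= 0.5
                    else:
                        fp_cov = int(rng.integers(3, 11))
                        fp_mod = int(round(rng.uniform(0.55, 0.95) * fp_cov))
                    # the emitted fraction is what a pileup caller would
                    # compute from the counts
                    frac = fp_mod / fp_cov
                    records.append(
                        BedMethylRecord(
                            chrom=contig.name, start=int(pos), end=int(pos) + 1,
                            mod_code=code, strand=strand, valid_cov=fp_cov,
                            frac_mod=frac, n_mod=fp_mod,
                            n_canonical=fp_cov - fp_mod,
                        )
                    )
    records.sort(key=lambda r: (r.chrom, r.start, r.mod_code, r.strand))
    write_bedmethyl(records, path)
    return records


# ---------------------------------------------------------------------------
# one-call driver
# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig, outdir: str | Path) -> TruthTable:
    """Run the three stages and write the full fixture set into ``outdir``:
    genome.fasta, reads.fastq, reads.sam, pileup.bedmethyl, regions.bed,
    truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs, truth = simulate_genome(config)
    write_assembly(contigs.values(), outdir / "genome.fasta")
    simulate_reads(contigs, truth, config, outdir / "reads.fastq", outdir / "reads.sam")
    simulate_bedmethyl(contigs, truth, config, outdir / "pileup.bedmethyl")
    write_bed(truth.telomere_intervals, outdir / "regions.bed")
    truth.to_json(outdir / "truth.json")
    return truth
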