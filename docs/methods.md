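# Methods note

This note records the model behind each analysis, the parameter choices
and their rationale, the numerical conventions, and the limitations of
the synthetic generator.

## Coordinate and rounding conventions

* Internally every interval is **0-based, half-open** (`[start, end)`),
  the native convention of BED and bedMethyl. Reports convert to
  **1-based inclusive** coordinates, so a reported feature has
  `length = end − start + 1`. `to_report_coords` / `from_report_coords`
  are exact inverses (property-tested).
* All rounding of reported numbers is **half-up** (0.5 → 1), via
  `decimal.Decimal` on the shortest repr of the float, never Python's
  built-in banker's rounding: published-style tables (integer terminal
  percentages, 3-decimal length deltas, 4-decimal densities) are only
  reproducible under half-up.

## Telomere annotation

Exact (mismatch-free) matching of the repeat unit within the terminal
`max_search = 2000` bp of each contig: the 3′ motif `GGTGGCGG` at the
3′ end, its reverse complement (or an explicitly supplied 5′ unit, e.g.
`CCACCCCG`) at the 5′ end. Matches are merged into runs when separated
by ≤ `max_gap = 8` bp; a run qualifies when it contains ≥
`min_copies = 3` copies **and** reaches within `max_gap` of the contig
terminus — interstitial arrays are deliberately not called telomeres.
If several runs qualify, the terminal-most (then longest, then
leftmost) wins. Shrinking `max_gap` can only shorten or remove an
annotation (monotonicity, property-tested).

## Terminal-nucleotide pipeline

Order matters and is fixed:

1. **Read filter**: keep reads with strictly more than 80 % of bases at
   Q ≥ 35. Strictness at the boundary is intentional and tested.
2. **Terminal trim**: remove maximal terminal runs of bases below Q30
   from both ends. Interior low-quality bases are never touched — the
   goal is to distrust read *ends*, where the non-templated-T signal
   lives, not to fragment reads.
3. **Telomere context**: the trimmed read's last 200 bp must contain
   the telomere motif or its reverse complement (`require_motif=True`),
   restricting the tally to reads that actually end in telomeric
   sequence.
4. **Tally**: count final-base A and T; report integer half-up
   percentages of the qualifying read count, `NA` for empty regions.

Reads are handled in **molecule orientation** (the basecalled strand):
for a minus-strand alignment the stored SAM sequence is
reverse-complemented back, so "the read ends in T" always refers to the
molecule's 3′ terminus. A non-templated T on a minus-strand molecule
appears in the SAM file as a soft-clipped `A` at the *left* edge of the
alignment; the loader undoes this so both strands are analysed
identically.

## Modification profile

* **Thresholding**: a site is called modified when `frac_mod > 0.5`
  **and** `valid_cov > 10`, both strict — matching the usual
  "frequency > 0.5 at > 10× valid coverage" rule. Monotone in both
  thresholds by construction.
* **Genome-wide percentages**: the denominator for 6mA is the number of
  A **plus** T bases in the assembly (both strands carry callable
  adenines); for 5mC/5hmC it is C + G. `N` bases are excluded.
* **Densities** (per contig): the default *inferred* mode reports
  `n_sites / length` (per bp) and `n_sites / 1000` (per kbp), both to 4
  decimals half-up — the interpretation under which a mitochondrion
  with 17 called sites over 41,721 bp yields 0.0004 per bp. A *literal*
  mode is also provided that averages read-level modification
  fractions, `Σn_mod / (Σn_mod + Σn_canonical)`, divided by length or
  1000; it answers a different question (average per-read modification
  level) and does not reproduce the per-base table.
* **Binned density**: half-open 1-kb bins; bin counts always sum to the
  total site count (property-tested).
* **Windows**: ±10 bp around each called site (21 bp). Windows running
  off a contig edge are clamped and flagged, not discarded; sites
  beyond the contig end (stale pileup vs. assembly) are skipped with a
  warning.
* **k-mer enrichment**: observed k-mer counts over all windows versus a
  null of per-window **dinucleotide-preserving shuffles**
  (Altschul–Erikson), which keeps local composition and therefore
  controls for the biased base content of modification neighbourhoods.
  Score = `(observed − null_mean) / null_sd`. When `null_sd = 0` (a
  k-mer never produced by any shuffle) the score falls back to the
  finite excess `observed − null_mean` instead of infinity: with a
  finite number of shuffles, dozens of chance singleton k-mers have
  empty nulls, and an infinite score would rank every one of them above
  a genuinely recurrent motif, inverting the ranking the statistic
  exists to produce. Requires ≥ 10 windows.

## Synthetic generator

Each contig is: 5′ array (reverse-complement units) + random body +
3′ array (`telomere_copies` exact units each). The body is sampled
uniformly over ACGT, then hardened so no repeat-unit occurrence
straddles or abuts an array/body junction — otherwise chance hits would
extend an array and truth-equality would fail stochastically.
`TCCACCA` motifs are planted in disjoint slots of the body interior,
each with a templated `A` forced 1–4 bp upstream (the recorded 6mA
site).

Reads: placement uniform along the contig (allowing overhang at the 5′
placement edge so terminal coverage is not starved), geometric length
with mean `read_length_mean`, strand fair, minimum length
`min_read_length = 500`. A read is *end-spanning* when its molecule 3′
terminus coincides with a contig 3′ terminus (plus strand reaching the
right end, minus strand reaching the left end); such reads receive one
non-templated `T` with probability `p_terminal_T`, emitted as a 1-bp
soft clip in the SAM record. Qualities: `q_high = 40` everywhere except
the 3 outermost bases at each end, uniform in `[q_low, q_high]`.

The bedMethyl pileup contains every planted 6mA site at
`per_site_frac_6mA = 0.9`, `per_site_cov = 30` (comfortably above both
thresholds) plus sub-threshold 5mC/5hmC false positives at rates
`fp_rate_5mC` / `fp_rate_5hmC`: half with low fraction at full
coverage, half with low coverage (≤ 10), fractions always derived from
integer counts as a real pileup would. Sub-threshold by construction —
the generator's contract is that strict thresholding recovers the 6mA
truth exactly.

Determinism: all randomness flows from
`numpy.random.default_rng([seed, stream, index])` with separate streams
for genome, reads and pileup; the six output files are byte-identical
across runs (tested).

### Parameter rationale

* `q_low = 30` (not lower): terminal bases below Q30 would be removed
  by the very trimming step the pipeline mandates, silently destroying
  the planted terminal-T signal. The trimming logic itself is exercised
  by dedicated unit and property tests with sub-Q30 qualities.
* `min_read_length = 500`: fragments shorter than this can live
  entirely inside a telomeric array; their suffix matches the motif, so
  they pass the context filter while ending at an arbitrary repeat
  base, diluting the terminal-T fraction with reads that never reached
  the terminus.
* Deep-recovery configuration (`n_contigs = 4`, `contig_length =
  30 000`, `read_depth = 450`, `read_length_mean = 20 000`): chosen so
  ≥ 500 reads span a 3′ terminus and mean read length far exceeds the
  array length, so end-spanning reads span the *whole* array; reads
  terminating mid-array are the main residual dilution of `perc_T`.

### What the generator does not model

Sequencing errors (substitutions/indels), chimeras, adapter sequence,
heterogeneous telomere lengths, subtelomeric repeat structure, mapping
ambiguity (all reads are emitted with MAPQ 60 at their true position),
and modification-call noise *above* threshold. It validates pipeline
logic and statistics, not basecaller or aligner robustness.

## Data-quality note

Among the seven published 3′ telomere rows, six satisfy
`length = end − start + 1` exactly; the chr4 row prints 166 where its
own coordinates give 167. The convention is fixed by the six consistent
rows (and by the companion read-count table reusing the same
coordinates), so the package treats the printed 166 as a typographical
error; the acceptance test asserts the six exact matches and the known
1-bp deviation explicitly.
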