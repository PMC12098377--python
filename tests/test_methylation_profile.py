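"""Thresholding, densities, window extraction and k-mer enrichment."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from teloepi import (
    BedMethylRecord,
    RegionInterval,
    binned_density,
    density_table,
    dinucleotide_shuffle,
    extract_windows,
    kmer_enrichment,
    modification_summary,
    parse_bedmethyl,
    region_site_count,
    threshold_sites,
)
from teloepi.io_formats import Contig


def rec(chrom="chr1", pos=0, code="a", frac=0.9, cov=30, strand="+"):
    n_mod = round(frac * cov)
    return BedMethylRecord(chrom, pos, pos + 1, code, strand, cov, frac,
                           n_mod, cov - n_mod)


class TestThreshold:
    def test_passing_site_kept(self):
        assert len(threshold_sites([rec(frac=0.6, cov=12)])) == 1

    @pytest.mark.parametrize("frac,cov", [(0.5, 12), (0.9, 10), (0.5, 10)])
    def test_boundaries_are_strict(self, frac, cov):
        assert len(threshold_sites([rec(frac=frac, cov=cov)])) == 0

    def test_generator_truth_recovered(self, small_dataset):
        """Thresholding the synthetic pileup returns exactly the planted
        6mA sites and no 5mC/5hmC survivors."""
        _, truth, outdir = small_dataset
        siteset = threshold_sites(parse_bedmethyl(outdir / "pileup.bedmethyl"))
        got = sorted((s.chrom, s.start) for s in siteset.sites)
        assert got == sorted(truth.planted_6mA_sites)
        assert not siteset.by_code("m") and not siteset.by_code("h")

    def test_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(41)
        records = [
            rec(pos=i, code=rng.choice(["m", "h", "a"]),
                frac=float(rng.uniform(0, 1)), cov=int(rng.integers(1, 40)))
            for i in range(300)
        ]
        for _ in range(100):
            f1, f2 = sorted(rng.uniform(0, 1, size=2))
            c1, c2 = sorted(rng.integers(0, 40, size=2))
            assert len(threshold_sites(records, f2, c1)) <= len(
                threshold_sites(records, f1, c1)
            )
            assert len(threshold_sites(records, f1, c2)) <= len(
                threshold_sites(records, f1, c1)
            )


class TestSummary:
    def test_zero_sites(self):
        contigs = {"c": Contig("c", "ACGT" * 10)}
        s = modification_summary(threshold_sites([]), contigs)
        assert s.n_sites == {"m": 0, "h": 0, "a": 0}
        assert s.pct_of_base == {"m": 0.0, "h": 0.0, "a": 0.0}

    def test_both_strand_denominator_arithmetic(self):
        # 500 A + 500 T = 1000 adenines over both strands; 10 sites -> 1.0%
        contigs = {"c": Contig("c", "A" * 500 + "T" * 500 + "C" * 100)}
        siteset = threshold_sites([rec(chrom="c", pos=i) for i in range(10)])
        s = modification_summary(siteset, contigs)
        assert s.pct_of_base["a"] == pytest.approx(1.0)
        assert s.base_counts["m"] == 100

    def test_n_bases_excluded_from_denominator(self):
        contigs = {"c": Contig("c", "AANN")}
        s = modification_summary(threshold_sites([]), contigs)
        assert s.base_counts["a"] == 2

    def test_empty_assembly_rejected(self):
        with pytest.raises(ValueError):
            modification_summary(threshold_sites([]), {})

    def test_oracle_recount_on_synthetic_genome(self, small_dataset, small_contigs):
        _, truth, outdir = small_dataset
        siteset = threshold_sites(parse_bedmethyl(outdir / "pileup.bedmethyl"))
        s = modification_summary(siteset, small_contigs)
        census = Counter()
        for c in small_contigs.values():
            census.update(c.sequence)
        expected = 100 * len(truth.planted_6mA_sites) / (census["A"] + census["T"])
        assert s.pct_of_base["a"] == pytest.approx(expected)


class TestDensity:
    def test_inferred_mode_row(self):
        contigs = {"mt": Contig("mt", "A" * 41_721)}
        siteset = threshold_sites([rec(chrom="mt", pos=i) for i in range(17)])
        (row,) = density_table(siteset, contigs, mode="inferred")
        assert row.n_mod == 17
        assert row.density_per_bp == 0.0004
        assert row.density_per_kbp == 0.0170

    def test_zero_sites_zero_density(self):
        contigs = {"c": Contig("c", "A" * 1000)}
        (row,) = density_table(threshold_sites([]), contigs)
        assert row.density_per_bp == 0.0 and row.density_per_kbp == 0.0

    def test_algebraic_identity_before_rounding(self):
        rng = np.random.default_rng(43)
        for _ in range(50):
            length = int(rng.integers(50, 3_000))
            n = int(rng.integers(0, min(length, 400)))
            contigs = {"c": Contig("c", "A" * length)}
            siteset = threshold_sites([rec(chrom="c", pos=p) for p in range(n)])
            (row,) = density_table(siteset, contigs)
            assert row.n_mod == n
            assert row.density_per_bp_raw * length == pytest.approx(n)
            assert row.density_per_kbp_raw * 1000 == pytest.approx(n)

    def test_literal_mode_uses_read_fractions(self):
        contigs = {"c": Contig("c", "A" * 1000)}
        siteset = threshold_sites([rec(chrom="c", pos=0, frac=0.8, cov=20),
                                   rec(chrom="c", pos=5, frac=0.6, cov=20)])
        (row,) = density_table(siteset, contigs, mode="literal")
        frac = (16 + 12) / 40
        assert row.density_per_bp_raw == pytest.approx(frac / 1000)
        assert row.density_per_kbp_raw == pytest.approx(frac / 1000)

    def test_zero_length_contig_rejected(self):
        with pytest.raises(ValueError):
            density_table(threshold_sites([]), {"c": Contig("c", "")})


class TestBins:
    CONTIGS = {"c": Contig("c", "A" * 2500)}

    def test_half_open_bin_edges(self):
        siteset = threshold_sites(
            [rec(chrom="c", pos=p) for p in (10, 999, 1000)]
        )
        bins = dict(binned_density(siteset, self.CONTIGS, binsize=1000)["c"])
        assert bins[0] == 2 and bins[1000] == 1 and bins[2000] == 0

    def test_empty_siteset_all_zero(self):
        bins = binned_density(threshold_sites([]), self.CONTIGS)["c"]
        assert all(c == 0 for _, c in bins)

    def test_conservation_over_random_configurations(self):
        rng = np.random.default_rng(44)
        for _ in range(100):
            length = int(rng.integers(1, 5000))
            contigs = {"c": Contig("c", "A" * length)}
            n = int(rng.integers(0, 50))
            positions = rng.integers(0, length, size=n)
            siteset = threshold_sites([rec(chrom="c", pos=int(p)) for p in positions])
            binsize = int(rng.integers(1, 1200))
            bins = binned_density(siteset, contigs, binsize=binsize)["c"]
            assert sum(c for _, c in bins) == n
            assert bins[-1][0] < length or length <= binsize


class TestRegionCount:
    def test_empty_siteset(self):
        assert region_site_count(threshold_sites([]), RegionInterval("c", 0, 10)) == 0

    def test_end_exclusive(self):
        siteset = threshold_sites([rec(chrom="c", pos=10)])
        assert region_site_count(siteset, RegionInterval("c", 0, 10)) == 0
        assert region_site_count(siteset, RegionInterval("c", 0, 11)) == 1

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(45)
        records = [
            rec(chrom=f"c{rng.integers(3)}", pos=int(rng.integers(0, 1000)),
                code=str(rng.choice(["m", "h", "a"])))
            for _ in range(400)
        ]
        siteset = threshold_sites(records)
        for _ in range(100):
            chrom = f"c{rng.integers(3)}"
            a, b = sorted(rng.integers(0, 1001, size=2))
            if a == b:
                continue
            region = RegionInterval(chrom, int(a), int(b))
            code = str(rng.choice(["m", "h", "a"]))
            expected = sum(
                1 for s in siteset.sites
                if s.chrom == chrom and a <= s.start < b and s.mod_code == code
            )
            assert region_site_count(siteset, region, code) == expected


class TestWindows:
    CONTIGS = {"c": Contig("c", "ACGT" * 60)}

    def test_full_window_is_21bp(self):
        siteset = threshold_sites([rec(chrom="c", pos=100)])
        (w,) = extract_windows(siteset, self.CONTIGS)
        assert (w.win_start, w.win_end) == (90, 111)
        assert len(w.sequence) == 21 and not w.clamped
        assert w.sequence == self.CONTIGS["c"].sequence[90:111]

    def test_edge_window_clamped_and_flagged(self):
        siteset = threshold_sites([rec(chrom="c", pos=5)])
        (w,) = extract_windows(siteset, self.CONTIGS)
        assert (w.win_start, w.win_end) == (0, 16)
        assert len(w.sequence) == 16 and w.clamped

    def test_site_beyond_contig_skipped_with_warning(self, caplog):
        siteset = threshold_sites([rec(chrom="c", pos=10_000)])
        with caplog.at_level("WARNING"):
            assert extract_windows(siteset, self.CONTIGS) == []
        assert "beyond contig end" in caplog.text

    def test_files_written(self, tmp_path):
        siteset = threshold_sites([rec(chrom="c", pos=50)])
        extract_windows(siteset, self.CONTIGS, bed_path=tmp_path / "w.bed",
                        fasta_path=tmp_path / "w.fasta")
        assert (tmp_path / "w.bed").read_text().startswith("c\t40\t61\t50")
        assert (tmp_path / "w.fasta").read_text().startswith(">c:40-61(50)\n")

    def test_generator_windows_contain_motif_downstream_of_center(
        self, small_dataset, small_contigs
    ):
        """Every window around a planted 6mA holds TCCACCA starting 1-4 bp
        downstream of the modified adenine, on the reference strand."""
        cfg, truth, outdir = small_dataset
        siteset = threshold_sites(parse_bedmethyl(outdir / "pileup.bedmethyl"))
        windows = extract_windows(siteset, small_contigs)
        assert len(windows) == len(truth.planted_6mA_sites)
        for w in windows:
            rel = w.center - w.win_start
            hit = w.sequence.find(cfg.motif_6mA, rel)
            assert hit != -1
            assert 1 <= hit - rel <= 4


DNA = st.text(alphabet="ACGT", min_size=3, max_size=40)


@given(seq=DNA, seed=st.integers(0, 2**31 - 1))
@settings(max_examples=200, deadline=None)
def test_dinucleotide_shuffle_preserves_doublets(seq, seed):
    rng = np.random.default_rng(seed)
    shuffled = dinucleotide_shuffle(seq, rng)
    assert len(shuffled) == len(seq)
    assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]
    assert Counter(zip(seq, seq[1:])) == Counter(zip(shuffled, shuffled[1:]))


class TestKmerEnrichment:
    def test_identical_windows_rank_their_kmers_first(self):
        windows = ["TTTTCCACCATTTTGGGGCCC"] * 20
        frame = kmer_enrichment(windows, k=7, n_shuffles=50, seed=3)
        top = set(frame.head(5)["kmer"])
        in_window = {windows[0][i:i + 7] for i in range(len(windows[0]) - 6)}
        assert top <= in_window

    def test_uniform_windows_lack_systematic_enrichment(self):
        """Random windows can produce high scores for chance singletons
        (small null variance), but no k-mer recurs across many windows the
        way a planted motif does."""
        rng = np.random.default_rng(46)
        windows = ["".join(rng.choice(list("ACGT"), size=21)) for _ in range(100)]
        frame = kmer_enrichment(windows, k=7, n_shuffles=100, seed=5)
        assert frame.iloc[0]["observed"] <= 5

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="10 windows"):
            kmer_enrichment(["ACGTACGTACGT"] * 5)

    def test_k_longer_than_window_rejected(self):
        with pytest.raises(ValueError, match="shortest window"):
            kmer_enrichment(["ACGTA"] * 12, k=7)

    def test_planted_motif_recovered_first(self, small_dataset, small_contigs):
        cfg, _, outdir = small_dataset
        siteset = threshold_sites(parse_bedmethyl(outdir / "pileup.bedmethyl"))
        windows = extract_windows(siteset, small_contigs)
        frame = kmer_enrichment(windows, k=7, n_shuffles=100, seed=9)
        assert frame.iloc[0]["kmer"] == cfg.motif_6mA
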