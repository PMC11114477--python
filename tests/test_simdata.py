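"""Simulator geometry, determinism and output contracts."""

import numpy as np
import pandas as pd
import pytest

from sncsig.simdata import (
    SimConfig, revcomp, simulate_background, simulate_genome, simulate_library,
    simulate_mirna_reads, simulate_pingpong_pairs, simulate_sirna_duplexes,
    write_genome_fasta, write_library, write_simulation,
)
from sncsig.sncrna_io import Locus, read_alignments
from sncsig.overlap_signature import pair_overlap


def _pairs_from_truth(reads, truth):
    by_id = {r.read_id: r for r in reads}
    out = []
    for pair_id, grp in truth[truth.pair_id != ""].groupby("pair_id"):
        members = [by_id[i] for i in grp.read_id]
        plus = next(r for r in members if r.strand == "+")
        minus = next(r for r in members if r.strand == "-")
        out.append((plus, minus))
    return out


class TestConfig:
    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(genome_length=0)

    @pytest.mark.parametrize("kwargs", [
        {"sirna_overhang": 21},
        {"pirna_len_range": (30, 24)},
        {"star_fraction": 1.5},
        {"n_chromosomes": 0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestGenome:
    def test_determinism_byte_identical_fasta(self, tmp_path):
        for name in ("a", "b"):
            genome, _ = simulate_genome(SimConfig(seed=9))
            write_genome_fasta(genome, tmp_path / f"{name}.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_loci_are_non_overlapping_with_gaps(self):
        cfg = SimConfig(genome_length=100_000, n_sirna_loci=3,
                        n_pirna_clusters=2, n_mirna_loci=5)
        _, loci = simulate_genome(cfg)
        assert len(loci) == 10
        by_chrom = {}
        for l in loci:
            by_chrom.setdefault(l.chrom, []).append((l.start, l.end))
        for intervals in by_chrom.values():
            intervals.sort()
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                assert e1 + 50 <= s2

    def test_unplaceable_loci_raise_with_class_name(self):
        cfg = SimConfig(genome_length=600, n_mirna_loci=0, n_sirna_loci=0,
                        n_pirna_clusters=5, pirna_cluster_len=500)
        with pytest.raises(RuntimeError, match="pirna"):
            simulate_genome(cfg)

    def test_mirna_loci_form_hairpins(self):
        genome, loci = simulate_genome(SimConfig(seed=4))
        for l in loci:
            if l.label != "mirna":
                continue
            seq = genome[l.chrom][l.start:l.end]
            assert seq[-22:] == revcomp(seq[:22])


class TestSirnaDuplexes:
    locus = Locus(chrom="chr1", start=1000, end=1400, name="sirna:1", label="sirna")

    def _genome(self, seed=0):
        rng = np.random.default_rng(seed)
        return {"chr1": "".join(rng.choice(list("ACGT"), size=2000))}

    def test_single_duplex_overlaps_by_19(self):
        reads, truth = simulate_sirna_duplexes(self.locus, self._genome(), 1,
                                               rng=np.random.default_rng(1))
        ((plus, minus),) = _pairs_from_truth(reads, truth)
        assert pair_overlap(plus, minus) == 19

    def test_zero_duplexes_give_empty_outputs(self):
        reads, truth = simulate_sirna_duplexes(self.locus, self._genome(), 0)
        assert reads == [] and truth.empty

    def test_every_pair_has_exact_overlap_geometry(self):
        reads, truth = simulate_sirna_duplexes(self.locus, self._genome(), 100,
                                               rng=np.random.default_rng(2))
        pairs = _pairs_from_truth(reads, truth)
        assert len(pairs) == 100
        assert all(pair_overlap(p, m) == 19 for p, m in pairs)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            simulate_sirna_duplexes(self.locus, self._genome(), -1)

    def test_short_locus_rejected(self):
        small = Locus(chrom="chr1", start=0, end=20, name="sirna:1")
        with pytest.raises(ValueError):
            simulate_sirna_duplexes(small, self._genome(), 1)

    def test_phased_mode_tiles_starts(self):
        reads, truth = simulate_sirna_duplexes(self.locus, self._genome(), 5,
                                               rng=np.random.default_rng(3), phased=True)
        starts = sorted(r.start for r in reads if r.strand == "+")
        assert starts == [starts[0] + 21 * i for i in range(5)]


class TestPingpong:
    cluster = Locus(chrom="chr1", start=500, end=1500, name="pirna:1", label="pirna")

    def _genome(self):
        rng = np.random.default_rng(0)
        return {"chr1": "".join(rng.choice(list("ACGT"), size=2000))}

    def test_single_pair_overlaps_by_10(self):
        reads, truth = simulate_pingpong_pairs(self.cluster, self._genome(), 1,
                                               rng=np.random.default_rng(1))
        ((plus, minus),) = _pairs_from_truth(reads, truth)
        assert pair_overlap(plus, minus) == 10

    def test_zero_pairs_empty(self):
        reads, truth = simulate_pingpong_pairs(self.cluster, self._genome(), 0)
        assert reads == [] and truth.empty

    def test_two_hundred_pairs_all_overlap_10(self):
        reads, truth = simulate_pingpong_pairs(self.cluster, self._genome(), 200,
                                               rng=np.random.default_rng(2))
        pairs = _pairs_from_truth(reads, truth)
        assert len(pairs) == 200
        assert all(pair_overlap(p, m) == 10 for p, m in pairs)

    def test_lengths_within_range(self):
        reads, _ = simulate_pingpong_pairs(self.cluster, self._genome(), 100,
                                           (24, 30), rng=np.random.default_rng(3))
        assert all(24 <= r.length <= 30 for r in reads)

    def test_incompatible_length_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_pingpong_pairs(self.cluster, self._genome(), 1, (5, 9))


class TestMirnaReads:
    def _setup(self):
        genome, loci = simulate_genome(SimConfig(seed=6))
        locus = next(l for l in loci if l.label == "mirna")
        return genome, locus

    def test_star_fraction_within_binomial_bound(self):
        genome, locus = self._setup()
        n, frac = 1000, 0.1
        _, _, record = simulate_mirna_reads(locus, genome, n, frac,
                                            np.random.default_rng(7))
        sd = (n * frac * (1 - frac)) ** 0.5
        assert abs(record.star_count - n * frac) <= 3 * sd

    def test_lengths_inside_mature_window(self):
        genome, locus = self._setup()
        reads, _, _ = simulate_mirna_reads(locus, genome, 500, 0.1,
                                           np.random.default_rng(8))
        assert all(20 <= r.length <= 25 for r in reads)

    def test_zero_star_fraction_gives_no_star_reads(self):
        genome, locus = self._setup()
        _, _, record = simulate_mirna_reads(locus, genome, 200, 0.0,
                                            np.random.default_rng(9))
        assert record.star_count == 0

    def test_truth_record_sequences_are_consistent(self):
        genome, locus = self._setup()
        _, _, record = simulate_mirna_reads(locus, genome, 10, 0.1,
                                            np.random.default_rng(10))
        assert record.mature in record.precursor
        assert record.star in record.precursor
        assert record.seed == record.mature[1:8]


class TestBackground:
    _small = dict(n_mirna_loci=0, n_sirna_loci=0, n_pirna_clusters=0)

    def test_zero_reads_empty(self):
        genome, _ = simulate_genome(SimConfig(seed=1, genome_length=5000, **self._small))
        reads, truth = simulate_background(genome, 0)
        assert reads == [] and truth.empty

    def test_strand_balance_within_binomial_bound(self):
        genome, _ = simulate_genome(SimConfig(seed=1, genome_length=20000, **self._small))
        reads, _ = simulate_background(genome, 10_000, rng=np.random.default_rng(2))
        plus_frac = sum(r.strand == "+" for r in reads) / len(reads)
        assert abs(plus_frac - 0.5) <= 3 * (0.25 / len(reads)) ** 0.5

    def test_reads_stay_within_chromosome_bounds(self):
        genome, _ = simulate_genome(SimConfig(seed=1, genome_length=3000, **self._small))
        reads, _ = simulate_background(genome, 2000, rng=np.random.default_rng(3))
        assert all(0 <= r.start < r.end <= len(genome[r.chrom]) for r in reads)

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            simulate_background({}, 10)


class TestLibraryLevel:
    def test_read_sequences_match_genome(self, default_simulation):
        sim = default_simulation
        for r in sim.library.reads:
            ref = sim.genome[r.chrom][r.start:r.end]
            expected = ref if r.strand == "+" else revcomp(ref)
            assert r.seq == expected

    def test_truth_covers_every_read_exactly_once(self, default_simulation):
        sim = default_simulation
        assert sorted(sim.truth.read_id) == sorted(r.read_id for r in sim.library.reads)
        assert sim.truth.read_id.is_unique

    def test_paired_classes_reference_existing_partners(self, default_simulation):
        truth = default_simulation.truth
        paired = truth[truth.pair_id != ""]
        sizes = paired.groupby("pair_id").size()
        assert (sizes == 2).all()

    def test_class_length_ranges_respected(self, default_simulation):
        sim = default_simulation
        lengths = {r.read_id: r.length for r in sim.library.reads}
        windows = {"sirna": (21, 21), "pirna": (24, 30),
                   "mirna": (20, 25), "background": (18, 35)}
        for read_id, cls in zip(sim.truth.read_id, sim.truth["class"]):
            lo, hi = windows[cls]
            assert lo <= lengths[read_id] <= hi

    def test_multimap_flag_marks_sirna_reads(self):
        sim = simulate_library(SimConfig(seed=5, multimap_sirna=True,
                                         n_background_reads=100, n_mirna_reads=50,
                                         n_sirna_duplexes=20, n_pingpong_pairs=20))
        sirna_ids = set(sim.truth[sim.truth["class"] == "sirna"].read_id)
        for r in sim.library.reads:
            assert r.n_hits == (2 if r.read_id in sirna_ids else 1)

    def test_full_simulation_is_deterministic(self, tmp_path):
        cfg = SimConfig(seed=13, n_background_reads=500, n_mirna_reads=100,
                        n_sirna_duplexes=50, n_pingpong_pairs=50)
        for name in ("a", "b"):
            write_simulation(simulate_library(cfg), tmp_path / name)
        for fname in ("genome.fa", "loci.bed", "library.sam", "library.fastq",
                      "truth.tsv", "mirna_genes.tsv"):
            assert (tmp_path / "a" / fname).read_bytes() == \
                   (tmp_path / "b" / fname).read_bytes(), fname


class TestWriteLibrary:
    def test_sam_round_trip_preserves_read_multiset(self, tmp_path, default_simulation):
        sim = default_simulation
        reads = sim.library.reads[:50]
        sam = tmp_path / "lib.sam"
        write_library(reads, sim.truth.head(0), sim.genome, sam)
        back = read_alignments(sam, "sam").reads
        key = lambda r: (r.chrom, r.start, r.end, r.strand, r.copies, r.n_hits)
        assert sorted(map(key, back)) == sorted(map(key, reads))

    def test_empty_library_writes_valid_headers_only_sam(self, tmp_path, default_simulation):
        sam = tmp_path / "empty.sam"
        write_library([], pd.DataFrame(columns=["read_id", "class", "locus_id", "pair_id"]),
                      default_simulation.genome, sam)
        assert len(read_alignments(sam, "sam")) == 0

    def test_truth_tsv_rows_match_distinct_read_ids(self, tmp_path, default_simulation):
        sim = default_simulation
        truth_path = tmp_path / "truth.tsv"
        write_library(sim.library.reads, sim.truth, sim.genome,
                      tmp_path / "x.sam", truth_path=truth_path)
        written = pd.read_csv(truth_path, sep="\t")
        assert len(written) == sim.truth.read_id.nunique()
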