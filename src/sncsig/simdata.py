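"""Synthetic genomes and small-RNA libraries with known ground truth.

The simulator emulates the read-level structure the signature analysis
assumes, without any sequencing-error or adapter model:

* miRNA hairpin loci: a 5' arm, a short loop and a 3' arm that is the reverse
  complement of the 5' arm; mature-arm and star-arm reads of 20-25 nt with
  +/-1 nt end jitter and a configurable mature/star ratio.
* dsRNA (endo-siRNA) loci: Dicer-2 style duplexes of two ``read_len``-nt reads
  on opposite strands offset by a 2-nt 3' overhang, so each pair's 5'-5'
  overlap is exactly ``read_len - overhang`` (19 for canonical 21-mers).
* piRNA clusters: ping-pong pairs - a plus read with 5' end at x and a minus
  read with 5' end at x + 9 - whose 5'-5' overlap is exactly 10 nt, with
  member lengths drawn independently from 24-30 nt.
* uniform background reads over both strands, 18-35 nt.

Every read's sequence equals the genome subsequence at its coordinates
(reverse-complemented on the minus strand, whose 5' end is ``end - 1`` in the
0-based half-open convention used throughout). A truth table records each
read's class, source locus and duplex/ping-pong partner. All randomness flows
through one seeded NumPy generator, so identical configurations produce
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .sncrna_io import AlignedRead, Library, Locus

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MIRNA_ARM_LEN = 22
MIRNA_LOOP_LEN = 15
LOCUS_GAP = 50


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimConfig:
    """Parameters of one simulated genome + library.

    Defaults encode the biology the signature analysis targets: 21-nt siRNAs
    with a 2-nt overhang, 24-30 nt piRNAs, 20-25 nt miRNAs, and an 18-35 nt
    uniform background.
    """

    genome_length: int = 100_000
    n_chromosomes: int = 1
    seed: int = 0
    # loci
    n_mirna_loci: int = 5
    n_sirna_loci: int = 3
    n_pirna_clusters: int = 2
    sirna_locus_len: int = 400
    pirna_cluster_len: int = 1000
    # reads
    n_mirna_reads: int = 1000
    n_sirna_duplexes: int = 500
    n_pingpong_pairs: int = 500
    n_background_reads: int = 5000
    star_fraction: float = 0.1
    # geometry
    sirna_read_len: int = 21
    sirna_overhang: int = 2
    pirna_len_range: tuple[int, int] = (24, 30)
    mirna_mature_len_range: tuple[int, int] = (20, 25)
    background_len_range: tuple[int, int] = (18, 35)
    phased_sirna: bool = False
    pingpong_nt_bias: bool = False
    multimap_sirna: bool = False

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be > 0")
        if self.n_chromosomes <= 0:
            raise ValueError("n_chromosomes must be > 0")
        for name in ("pirna_len_range", "mirna_mature_len_range", "background_len_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or lo > hi:
                raise ValueError(f"{name} must satisfy 0 < min <= max")
        if self.sirna_read_len <= 0:
            raise ValueError("sirna_read_len must be > 0")
        if not 0 <= self.sirna_overhang < self.sirna_read_len:
            raise ValueError("sirna_overhang must be in [0, sirna_read_len)")
        if not 0.0 <= self.star_fraction <= 1.0:
            raise ValueError("star_fraction must be in [0, 1]")


@dataclass
class MirnaLocusTruth:
    """Ground-truth record for one simulated miRNA hairpin."""

    locus_id: str
    chrom: str
    precursor_start: int
    precursor_end: int
    precursor: str
    mature: str
    star: str
    seed: str
    mature_count: int = 0
    star_count: int = 0


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> tuple[dict[str, str], list[Locus]]:
    """Uniform-random genome with non-overlapping, class-labelled loci.

    Loci (miRNA hairpins, siRNA dsRNA regions, piRNA clusters) are placed by
    rejection sampling with at least ``LOCUS_GAP`` nt between any two; miRNA
    3' arms are overwritten with the reverse complement of the 5' arm so the
    precursor forms a hairpin. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    per_chrom = config.genome_length // config.n_chromosomes
    if per_chrom <= 0:
        raise ValueError("genome_length must be >= n_chromosomes")
    chrom_arrays = {
        f"chr{i + 1}": rng.choice(_BASES, size=per_chrom)
        for i in range(config.n_chromosomes)
    }
    chrom_names = list(chrom_arrays)

    mirna_len = 2 * MIRNA_ARM_LEN + MIRNA_LOOP_LEN
    wanted: list[tuple[str, int]] = (
        [("mirna", mirna_len)] * config.n_mirna_loci
        + [("sirna", config.sirna_locus_len)] * config.n_sirna_loci
        + [("pirna", config.pirna_cluster_len)] * config.n_pirna_clusters
    )

    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    loci: list[Locus] = []
    counters = {"mirna": 0, "sirna": 0, "pirna": 0}
    for label, length in wanted:
        ok = False
        for _ in range(1000):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            if per_chrom < length:
                continue
            start = int(rng.integers(0, per_chrom - length + 1))
            end = start + length
            if all(end + LOCUS_GAP <= s or e + LOCUS_GAP <= start
                   for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                counters[label] += 1
                loci.append(Locus(chrom=chrom, start=start, end=end,
                                  name=f"{label}:{counters[label]}",
                                  strand="+", label=label))
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place a {label} locus of {length} nt without overlap; "
                "reduce locus counts or enlarge the genome")

    # hairpin structure: 3' arm = revcomp(5' arm)
    for locus in loci:
        if locus.label != "mirna":
            continue
        arr = chrom_arrays[locus.chrom]
        arm5 = "".join(arr[locus.start:locus.start + MIRNA_ARM_LEN])
        arm3 = np.array(list(revcomp(arm5)))
        arr[locus.end - MIRNA_ARM_LEN:locus.end] = arm3

    genome = {c: "".join(a) for c, a in chrom_arrays.items()}
    return genome, loci


def _read_seq(genome: dict[str, str], chrom: str, start: int, end: int, strand: str) -> str:
    s = genome[chrom][start:end]
    return s if strand == "+" else revcomp(s)


# ---------------------------------------------------------------------------
# read simulators
# ---------------------------------------------------------------------------

def simulate_sirna_duplexes(locus: Locus, genome: dict[str, str], n_duplexes: int,
                            read_len: int = 21, overhang: int = 2,
                            rng: np.random.Generator | None = None, *,
                            phased: bool = False,
                            id_prefix: str = "sirna") -> tuple[list[AlignedRead], pd.DataFrame]:
    """Dicer-2 duplexes from one dsRNA locus.

    Each duplex is a plus read [x, x + read_len) and a minus read
    [x - overhang, x - overhang + read_len): the two 3' ends protrude by
    ``overhang`` nt, so the 5'-5' overlap is ``read_len - overhang``. Starts
    are uniform within the locus, or tiled every ``read_len`` when phased.
    """
    if n_duplexes < 0:
        raise ValueError("n_duplexes must be >= 0")
    if locus.end - locus.start < read_len + overhang:
        raise ValueError("locus shorter than read_len + overhang")
    rng = np.random.default_rng(0) if rng is None else rng

    lo = locus.start + overhang           # minus read must stay inside the locus
    hi = locus.end - read_len             # inclusive upper bound for x
    if phased:
        starts = [lo + (i * read_len) % (hi - lo + 1) for i in range(n_duplexes)]
    else:
        starts = [int(rng.integers(lo, hi + 1)) for _ in range(n_duplexes)]

    reads: list[AlignedRead] = []
    truth_rows = []
    for i, x in enumerate(starts):
        pid = f"{id_prefix}:{locus.name}:d{i}"
        plus = AlignedRead(read_id=f"{pid}:p", chrom=locus.chrom, start=x,
                           end=x + read_len, strand="+",
                           seq=_read_seq(genome, locus.chrom, x, x + read_len, "+"))
        ms = x - overhang
        minus = AlignedRead(read_id=f"{pid}:m", chrom=locus.chrom, start=ms,
                            end=ms + read_len, strand="-",
                            seq=_read_seq(genome, locus.chrom, ms, ms + read_len, "-"))
        reads += [plus, minus]
        truth_rows += [
            (plus.read_id, "sirna", locus.name, pid),
            (minus.read_id, "sirna", locus.name, pid),
        ]
    truth = pd.DataFrame(truth_rows, columns=["read_id", "class", "locus_id", "pair_id"])
    return reads, truth


def simulate_pingpong_pairs(cluster: Locus, genome: dict[str, str], n_pairs: int,
                            len_range: tuple[int, int] = (24, 30),
                            rng: np.random.Generator | None = None, *,
                            nt_bias: bool = False,
                            id_prefix: str = "pirna") -> tuple[list[AlignedRead], pd.DataFrame]:
    """Ping-pong piRNA pairs from one cluster.

    Each pair is a plus read with 5' end at x and a minus read with 5' end at
    x + 9, so the 5'-5' overlap is exactly 10 nt; member lengths are drawn
    independently from ``len_range``. With ``nt_bias`` the plus 5' base is
    biased toward U (rejection sampling over start positions, keeping read
    sequences faithful to the genome).
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    lo_len, hi_len = len_range
    if hi_len < 11:
        raise ValueError("ping-pong geometry requires a length range reaching >= 11 nt")
    if cluster.end - cluster.start < hi_len + 10:
        raise ValueError("cluster shorter than max read length + 10")
    rng = np.random.default_rng(0) if rng is None else rng

    reads: list[AlignedRead] = []
    truth_rows = []
    for i in range(n_pairs):
        len_p = int(rng.integers(lo_len, hi_len + 1))
        len_m = int(rng.integers(max(lo_len, 11), hi_len + 1))
        x_lo = cluster.start + max(0, len_m - 10)
        x_hi = cluster.end - max(len_p, 10)   # inclusive
        x = int(rng.integers(x_lo, x_hi + 1))
        if nt_bias:
            for _ in range(50):
                if genome[cluster.chrom][x] == "T":
                    break
                x = int(rng.integers(x_lo, x_hi + 1))
        pid = f"{id_prefix}:{cluster.name}:pp{i}"
        plus = AlignedRead(read_id=f"{pid}:p", chrom=cluster.chrom, start=x,
                           end=x + len_p, strand="+",
                           seq=_read_seq(genome, cluster.chrom, x, x + len_p, "+"))
        # minus 5' end at x+9  =>  interval [x + 10 - len_m, x + 10)
        ms, me = x + 10 - len_m, x + 10
        minus = AlignedRead(read_id=f"{pid}:m", chrom=cluster.chrom, start=ms,
                            end=me, strand="-",
                            seq=_read_seq(genome, cluster.chrom, ms, me, "-"))
        reads += [plus, minus]
        truth_rows += [
            (plus.read_id, "pirna", cluster.name, pid),
            (minus.read_id, "pirna", cluster.name, pid),
        ]
    truth = pd.DataFrame(truth_rows, columns=["read_id", "class", "locus_id", "pair_id"])
    return reads, truth


def simulate_mirna_reads(locus: Locus, genome: dict[str, str], n_reads: int,
                         star_fraction: float = 0.1,
                         rng: np.random.Generator | None = None, *,
                         id_prefix: str = "mirna"
                         ) -> tuple[list[AlignedRead], pd.DataFrame, MirnaLocusTruth]:
    """Mature/star reads from one hairpin locus.

    Reads come from the mature (5') arm with probability 1 - star_fraction and
    the star (3') arm otherwise, with independent +/-1 nt jitter on both ends,
    giving lengths of 20-24 nt around the 22-nt arms. The truth record carries
    the precursor, mature, star and seed sequences plus realised arm counts.
    """
    if not 0.0 <= star_fraction <= 1.0:
        raise ValueError("star_fraction must be in [0, 1]")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    rng = np.random.default_rng(0) if rng is None else rng

    chrom = locus.chrom
    mature_iv = (locus.start, locus.start + MIRNA_ARM_LEN)
    star_iv = (locus.end - MIRNA_ARM_LEN, locus.end)
    precursor = genome[chrom][locus.start:locus.end]
    mature = genome[chrom][mature_iv[0]:mature_iv[1]]
    star = genome[chrom][star_iv[0]:star_iv[1]]

    reads: list[AlignedRead] = []
    truth_rows = []
    n_star = 0
    for i in range(n_reads):
        is_star = bool(rng.random() < star_fraction)
        n_star += is_star
        arm = star_iv if is_star else mature_iv
        start = arm[0] + int(rng.integers(-1, 2))
        end = arm[1] + int(rng.integers(-1, 2))
        rid = f"{id_prefix}:{locus.name}:{'s' if is_star else 'm'}{i}"
        reads.append(AlignedRead(read_id=rid, chrom=chrom, start=start, end=end,
                                 strand="+", seq=_read_seq(genome, chrom, start, end, "+")))
        truth_rows.append((rid, "mirna", locus.name, ""))

    truth = pd.DataFrame(truth_rows, columns=["read_id", "class", "locus_id", "pair_id"])
    record = MirnaLocusTruth(
        locus_id=locus.name, chrom=chrom,
        precursor_start=locus.start, precursor_end=locus.end,
        precursor=precursor, mature=mature, star=star, seed=mature[1:8],
        mature_count=n_reads - n_star, star_count=n_star,
    )
    return reads, truth, record


def simulate_background(genome: dict[str, str], n_reads: int,
                        len_range: tuple[int, int] = (18, 35),
                        rng: np.random.Generator | None = None, *,
                        id_prefix: str = "bg") -> tuple[list[AlignedRead], pd.DataFrame]:
    """Uniform background reads over positions, strands and ``len_range``."""
    if not genome:
        raise ValueError("genome must be non-empty")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    rng = np.random.default_rng(0) if rng is None else rng
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    reads: list[AlignedRead] = []
    truth_rows = []
    for i in range(n_reads):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        start = int(rng.integers(0, len(genome[chrom]) - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        rid = f"{id_prefix}:{i}"
        reads.append(AlignedRead(read_id=rid, chrom=chrom, start=start,
                                 end=start + length, strand=strand,
                                 seq=_read_seq(genome, chrom, start, start + length, strand)))
        truth_rows.append((rid, "background", "", ""))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "class", "locus_id", "pair_id"])
    return reads, truth


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class Simulation:
    """One complete simulated dataset."""

    config: SimConfig
    genome: dict[str, str]
    loci: list[Locus]
    library: Library
    truth: pd.DataFrame
    mirna_genes: list[MirnaLocusTruth] = field(default_factory=list)


def simulate_library(config: SimConfig) -> Simulation:
    """Genome + loci + all four read classes under one seed.

    A single generator (seeded from the config) is threaded through genome
    construction and then, in order, siRNA, ping-pong, miRNA and background
    draws, so the whole dataset is a deterministic function of the config.
    """
    genome, loci = simulate_genome(config)
    rng = np.random.default_rng(config.seed + 1)

    reads: list[AlignedRead] = []
    truths: list[pd.DataFrame] = []
    genes: list[MirnaLocusTruth] = []

    sirna_loci = [l for l in loci if l.label == "sirna"]
    for locus in sirna_loci:
        n = _split(config.n_sirna_duplexes, len(sirna_loci), locus)
        r, t = simulate_sirna_duplexes(locus, genome, n, config.sirna_read_len,
                                       config.sirna_overhang, rng,
                                       phased=config.phased_sirna)
        if config.multimap_sirna:
            r = [replace(x, n_hits=2) for x in r]
        reads += r
        truths.append(t)

    pirna_loci = [l for l in loci if l.label == "pirna"]
    for locus in pirna_loci:
        n = _split(config.n_pingpong_pairs, len(pirna_loci), locus)
        r, t = simulate_pingpong_pairs(locus, genome, n, config.pirna_len_range,
                                       rng, nt_bias=config.pingpong_nt_bias)
        reads += r
        truths.append(t)

    mirna_loci = [l for l in loci if l.label == "mirna"]
    for locus in mirna_loci:
        n = _split(config.n_mirna_reads, len(mirna_loci), locus)
        r, t, g = simulate_mirna_reads(locus, genome, n, config.star_fraction, rng)
        reads += r
        truths.append(t)
        genes.append(g)

    r, t = simulate_background(genome, config.n_background_reads,
                               config.background_len_range, rng)
    reads += r
    truths.append(t)

    truth = (pd.concat(truths, ignore_index=True) if truths
             else pd.DataFrame(columns=["read_id", "class", "locus_id", "pair_id"]))
    library = Library(reads=reads, total_mapped=sum(x.copies for x in reads))
    return Simulation(config=config, genome=genome, loci=loci,
                      library=library, truth=truth, mirna_genes=genes)


def _split(total: int, n_groups: int, locus: Locus) -> int:
    """Even split of a read budget over loci (remainder to the first loci)."""
    if n_groups == 0:
        return 0
    idx = int(locus.name.split(":")[1]) - 1
    return total // n_groups + (1 if idx < total % n_groups else 0)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_genome_fasta(genome: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_loci_bed(loci: Sequence[Locus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.name}\t0\t{l.strand}\n")


def write_library(reads: Sequence[AlignedRead], truth: pd.DataFrame,
                  genome: dict[str, str], sam_path: str | Path,
                  fastq_path: str | Path | None = None,
                  truth_path: str | Path | None = None) -> None:
    """Write reads as SAM (+ optional FASTQ and truth TSV).

    The SAM carries the NH tag for alignment multiplicity; FASTQ qualities are
    a constant 'I'. Round-tripping the SAM through
    :func:`sncsig.sncrna_io.read_alignments` reproduces coordinates, strand,
    length and copies exactly.
    """
    chroms = sorted(genome)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(genome[c])} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for r in reads:
            seq = r.seq or _read_seq(genome, r.chrom, r.start, r.end, r.strand)
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.reference_id = tid[r.chrom]
            a.reference_start = r.start
            a.cigarstring = f"{r.length}M"
            a.flag = 16 if r.strand == "-" else 0
            a.mapping_quality = 255
            # SAM stores the forward-strand sequence
            a.query_sequence = revcomp(seq) if r.strand == "-" else seq
            a.set_tag("NH", r.n_hits)
            out.write(a)

    if fastq_path is not None:
        with open(fastq_path, "w") as fq:
            for r in reads:
                seq = r.seq or _read_seq(genome, r.chrom, r.start, r.end, r.strand)
                fq.write(f"@{r.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")

    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)


def write_simulation(sim: Simulation, outdir: str | Path) -> dict[str, Path]:
    """Write genome, loci, SAM/FASTQ library, truth table and gene table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "loci": outdir / "loci.bed",
        "sam": outdir / "library.sam",
        "fastq": outdir / "library.fastq",
        "truth": outdir / "truth.tsv",
        "genes": outdir / "mirna_genes.tsv",
    }
    write_genome_fasta(sim.genome, paths["genome"])
    write_loci_bed(sim.loci, paths["loci"])
    write_library(sim.library.reads, sim.truth, sim.genome,
                  paths["sam"], paths["fastq"], paths["truth"])
    pd.DataFrame(
        [(g.locus_id, g.precursor, g.mature, g.star, g.mature_count, g.star_count)
         for g in sim.mirna_genes],
        columns=["gene_id", "precursor", "mature", "star", "mature_count", "star_count"],
    ).to_csv(paths["genes"], sep="\t", index=False)
    return paths
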