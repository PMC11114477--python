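"""miRNA gene filtering, family assignment and novel-family clustering.

Candidate miRNA genes (precursor + mature + star sequences with read counts,
as produced by an upstream discovery tool or by the simulator) are processed
in three steps:

1. star filter - novel candidates whose star (passenger-strand) read support
   is below 5 reads are discarded; star support is the classic evidence that
   a hairpin is genuinely Dicer-processed.
2. known-family assignment - each precursor is locally aligned against a
   reference pre-miRNA database (MirGeneDB-style, headers carrying a family
   label and the mature sequence); the best hit's family is assigned only if
   the two genes share an identical 7-nt seed (mature positions 2-8).
3. novel-family clustering - unassigned genes are joined by an edge when
   their precursors produce a reciprocal local-alignment hit AND their seeds
   differ by at most one substitution; families are the connected components
   (single linkage), named after the lexicographically smallest member.

A conservation check aligns each precursor against a second genome (both
strands) and flags the gene as shared when the hit passes identity/coverage
thresholds and covers the seed region without mismatches.

Local alignment uses a simple scoring (match +1, mismatch -2, gap -3) with
identity and coverage thresholds in place of E-values, which would depend on
an arbitrary database size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner

SEED_START = 1   # 0-based: mature positions 2-8, 1-based inclusive
SEED_END = 8
MIN_STAR_DEFAULT = 5

_U2T = str.maketrans("Uu", "Tt")


def _norm(seq: str) -> str:
    return seq.translate(_U2T).upper()


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def extract_seed(mature: str) -> str:
    """The 7-nt seed: mature positions 2-8 (1-based inclusive), U -> T."""
    mature = _norm(mature)
    if len(mature) < 8:
        raise ValueError(f"mature sequence shorter than 8 nt: {mature!r}")
    return mature[SEED_START:SEED_END]


@dataclass
class MirnaGene:
    """A candidate miRNA gene: hairpin precursor with mature/star arms."""

    gene_id: str
    precursor: str
    mature: str
    star: str
    mature_count: int = 0
    star_count: int = 0
    family: str | None = None
    novel: bool = True

    def __post_init__(self) -> None:
        self.precursor = _norm(self.precursor)
        self.mature = _norm(self.mature)
        self.star = _norm(self.star)
        if self.mature not in self.precursor:
            raise ValueError(f"{self.gene_id}: mature is not a substring of the precursor")
        if self.star and self.star not in self.precursor:
            raise ValueError(f"{self.gene_id}: star is not a substring of the precursor")
        if self.star_count < 0 or self.mature_count < 0:
            raise ValueError(f"{self.gene_id}: read counts must be >= 0")

    @property
    def seed(self) -> str:
        return extract_seed(self.mature)


@dataclass(frozen=True)
class ReferenceEntry:
    """One reference pre-miRNA with its family label and mature sequence."""

    ref_id: str
    family: str
    precursor: str
    mature: str

    @property
    def seed(self) -> str:
        return extract_seed(self.mature)


@dataclass
class MirnaFamily:
    family_id: str
    members: list[str]
    seed_set: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# alignment machinery
# ---------------------------------------------------------------------------

def _aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    al.match_score = 1
    al.mismatch_score = -2
    al.open_gap_score = -3
    al.extend_gap_score = -3
    return al


@dataclass(frozen=True)
class LocalHit:
    score: float
    identity: float          # matches / aligned columns
    coverage_frac: float     # aligned target span / len(shorter sequence)
    target_blocks: tuple[tuple[int, int], ...]
    query_blocks: tuple[tuple[int, int], ...]


def best_local_hit(target: str, query: str) -> LocalHit | None:
    """Best-scoring local alignment of two sequences, or None if score <= 0."""
    target, query = _norm(target), _norm(query)
    al = _aligner()
    score = al.score(target, query)
    if score <= 0:
        return None
    aln = al.align(target, query)[0]
    t_blocks, q_blocks = aln.aligned
    matches = 0
    columns = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for i in range(te - ts):
            columns += 1
            if target[ts + i] == query[qs + i]:
                matches += 1
    # count gap columns between consecutive aligned blocks
    for i in range(1, len(t_blocks)):
        columns += (t_blocks[i][0] - t_blocks[i - 1][1]) + (q_blocks[i][0] - q_blocks[i - 1][1])
    if columns == 0:
        return None
    shorter = min(len(target), len(query))
    t_span = sum(te - ts for ts, te in t_blocks)
    q_span = sum(qe - qs for qs, qe in q_blocks)
    coverage = min(t_span, q_span) / shorter
    return LocalHit(score=float(score), identity=matches / columns,
                    coverage_frac=coverage,
                    target_blocks=tuple(map(tuple, t_blocks)),
                    query_blocks=tuple(map(tuple, q_blocks)))


def _hit_passes(hit: LocalHit | None, min_identity: float, min_coverage_frac: float) -> bool:
    return (hit is not None and hit.identity >= min_identity
            and hit.coverage_frac >= min_coverage_frac)


def seed_distance(seed_a: str, seed_b: str) -> int:
    """Hamming distance between two 7-nt seeds."""
    if len(seed_a) != len(seed_b):
        raise ValueError("seeds must have equal length")
    return sum(a != b for a, b in zip(seed_a, seed_b))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def star_filter(genes: Iterable[MirnaGene], min_star: int = MIN_STAR_DEFAULT) -> list[MirnaGene]:
    """Drop novel candidates with star read coverage strictly below min_star.

    Genes already matching a known family (``novel=False``) pass through
    regardless; the bound is strict, so star_count == min_star is kept.
    """
    if min_star < 0:
        raise ValueError("min_star must be >= 0")
    return [g for g in genes if not g.novel or g.star_count >= min_star]


def assign_known_family(gene: MirnaGene, reference: Sequence[ReferenceEntry],
                        min_identity: float = 0.6,
                        min_coverage_frac: float = 0.5) -> str | None:
    """Best-hit family assignment gated on an identical seed.

    The precursor is aligned locally against every reference precursor; the
    best hit is the highest-scoring alignment with identity >= min_identity
    over >= min_coverage_frac of the shorter sequence (ties broken by
    identity, then reference id). The family is assigned only when the
    gene's seed is identical to the best hit's seed; otherwise None.
    """
    best: tuple[float, float, str, ReferenceEntry] | None = None
    for entry in sorted(reference, key=lambda e: e.ref_id):
        hit = best_local_hit(gene.precursor, entry.precursor)
        if not _hit_passes(hit, min_identity, min_coverage_frac):
            continue
        key = (hit.score, hit.identity, entry.ref_id)
        if best is None or (key[0], key[1]) > (best[0], best[1]):
            best = (hit.score, hit.identity, entry.ref_id, entry)
    if best is None:
        return None
    entry = best[3]
    return entry.family if gene.seed == entry.seed else None


def cluster_novel_families(genes: Sequence[MirnaGene],
                           min_identity: float = 0.6,
                           min_coverage_frac: float = 0.5) -> list[MirnaFamily]:
    """Single-linkage clustering of unassigned genes into novel families.

    Two genes are linked when their precursors yield a local-alignment hit
    passing the thresholds and their seeds differ by at most one nucleotide;
    families are the connected components. Because linkage is transitive,
    a family may contain seed pairs at distance 2 joined through a chain.
    Family ids are the lexicographically smallest member id, so the result
    is independent of input order.
    """
    graph = nx.Graph()
    ordered = sorted(genes, key=lambda g: g.gene_id)
    graph.add_nodes_from(g.gene_id for g in ordered)
    seeds = {g.gene_id: g.seed for g in ordered}
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            if seed_distance(a.seed, b.seed) > 1:
                continue
            hit = best_local_hit(a.precursor, b.precursor)
            if _hit_passes(hit, min_identity, min_coverage_frac):
                graph.add_edge(a.gene_id, b.gene_id)
    families = []
    for component in nx.connected_components(graph):
        members = sorted(component)
        families.append(MirnaFamily(family_id=members[0], members=members,
                                    seed_set={seeds[m] for m in members}))
    families.sort(key=lambda f: f.family_id)
    return families


def conservation_check(genes: Sequence[MirnaGene], second_genome: dict[str, str],
                       min_identity: float = 0.8,
                       min_coverage_frac: float = 0.8) -> pd.DataFrame:
    """Flag genes whose precursor aligns to a second genome with a conserved seed.

    Each precursor is aligned locally against every chromosome on both
    strands; the gene is 'shared' when some hit passes the identity/coverage
    thresholds and the aligned region covers the seed positions gap-free
    with zero mismatches. Returns one row per gene plus the shared count.
    """
    if not second_genome:
        raise ValueError("second_genome must be non-empty")
    rows = []
    for gene in genes:
        seed_lo = gene.precursor.index(gene.mature) + SEED_START
        seed_hi = seed_lo + (SEED_END - SEED_START)
        shared = False
        for chrom_seq in second_genome.values():
            for target in (chrom_seq, revcomp(chrom_seq)):
                hit = best_local_hit(_norm(target), gene.precursor)
                if not _hit_passes(hit, min_identity, min_coverage_frac):
                    continue
                if _seed_conserved(hit, _norm(target), gene.precursor, seed_lo, seed_hi):
                    shared = True
                    break
            if shared:
                break
        rows.append((gene.gene_id, shared))
    return pd.DataFrame(rows, columns=["gene_id", "shared"])


def _seed_conserved(hit: LocalHit, target: str, precursor: str,
                    seed_lo: int, seed_hi: int) -> bool:
    """True when precursor positions [seed_lo, seed_hi) align match-only."""
    covered = 0
    for (ts, te), (qs, qe) in zip(hit.target_blocks, hit.query_blocks):
        for i in range(te - ts):
            q = qs + i
            if seed_lo <= q < seed_hi:
                if target[ts + i] != precursor[q]:
                    return False
                covered += 1
    return covered == seed_hi - seed_lo


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_gene_table(path: str | Path) -> list[MirnaGene]:
    """Candidate gene TSV: gene_id, precursor, mature, star, mature_count, star_count."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return [MirnaGene(gene_id=row.gene_id, precursor=row.precursor,
                      mature=row.mature, star=row.star if isinstance(row.star, str) else "",
                      mature_count=int(row.mature_count), star_count=int(row.star_count))
            for row in df.itertuples()]


def read_reference_fasta(path: str | Path) -> list[ReferenceEntry]:
    """Reference pre-miRNA FASTA with '>id family=NAME mature=SEQ' headers."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        attrs = dict(kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv)
        if "family" not in attrs or "mature" not in attrs:
            raise ValueError(f"reference entry {rec.id}: header must carry family= and mature=")
        entries.append(ReferenceEntry(ref_id=rec.id, family=attrs["family"],
                                      precursor=_norm(str(rec.seq)),
                                      mature=_norm(attrs["mature"])))
    return entries


def annotate_genes(genes: Sequence[MirnaGene], reference: Sequence[ReferenceEntry],
                   min_star: int = MIN_STAR_DEFAULT, min_identity: float = 0.6,
                   min_coverage_frac: float = 0.5
                   ) -> tuple[list[MirnaGene], list[MirnaFamily]]:
    """Full annotation: known-family assignment, star filter, novel clustering.

    Genes matching a known family keep it (novel=False, exempt from the star
    filter, mirroring the rule that the star-support cutoff applies to novel
    predictions only); the remaining candidates are star-filtered and
    clustered into novel families.
    """
    for gene in genes:
        fam = assign_known_family(gene, reference, min_identity, min_coverage_frac)
        gene.family = fam
        gene.novel = fam is None
    kept = star_filter(genes, min_star)
    novel = [g for g in kept if g.novel]
    families = cluster_novel_families(novel, min_identity, min_coverage_frac)
    by_gene = {m: f.family_id for f in families for m in f.members}
    for g in novel:
        g.family = f"novel:{by_gene[g.gene_id]}"
    return kept, families


def genes_to_frame(genes: Sequence[MirnaGene]) -> pd.DataFrame:
    return pd.DataFrame(
        [(g.gene_id, g.family or "", g.novel, g.seed, g.mature_count, g.star_count)
         for g in genes],
        columns=["gene_id", "family", "novel", "seed", "mature_count", "star_count"],
    )
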