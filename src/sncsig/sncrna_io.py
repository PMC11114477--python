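"""Reading, writing and normalising aligned small-RNA reads.

Small-RNA libraries are usually collapsed (identical sequences merged with a
copy count) and mapped allowing many alignments per read. This module defines
the in-memory read/library containers used throughout the package and the
standard operations on them: parsing SAM or BED6 alignments, collapsing
duplicates, length/multimap filtering, annotation interval parsing and
reads-per-million (RPM) normalisation.

Coordinates are 0-based, half-open everywhere in memory; the 1-based SAM and
GFF3 conventions are converted at the file boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
import pysam

logger = logging.getLogger("sncsig")

# suffix convention of FASTA/FASTQ collapsers: read ids like "r17_x42"
_COPIES_SUFFIX = re.compile(r"_x(\d+)$")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedRead:
    """One mapped small-RNA read.

    ``start``/``end`` are 0-based half-open genome coordinates. ``copies`` is
    the number of identical collapsed reads this record stands for and
    ``n_hits`` the number of genomic alignments of the read (SAM ``NH`` tag).
    """

    read_id: str
    chrom: str
    start: int
    end: int
    strand: Literal["+", "-"]
    copies: int = 1
    n_hits: int = 1
    seq: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"read {self.read_id}: end ({self.end}) must exceed start ({self.start})")
        if self.copies < 1:
            raise ValueError(f"read {self.read_id}: copies must be >= 1")
        if self.n_hits < 1:
            raise ValueError(f"read {self.read_id}: n_hits must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.read_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """0-based position of the biological 5' end (``end - 1`` on minus)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class Library:
    """A collection of mapped reads plus the pre-filter sequencing depth.

    ``total_mapped`` is fixed when the library is read (sum of copies before
    any filtering) so that RPM values stay comparable across filter settings.
    """

    reads: list[AlignedRead]
    total_mapped: int
    tissue: str = "unspecified"

    def __post_init__(self) -> None:
        retained = sum(r.copies for r in self.reads)
        if self.total_mapped < retained:
            raise ValueError("total_mapped cannot be smaller than the retained copy sum")

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class Locus:
    """A labelled annotation interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."
    label: str = "."


# ---------------------------------------------------------------------------
# alignment parsing
# ---------------------------------------------------------------------------

def _copies_from_id(read_id: str) -> int:
    m = _COPIES_SUFFIX.search(read_id)
    return int(m.group(1)) if m else 1


def read_alignments(path: str | Path, format: Literal["sam", "bed6"] = "sam",
                    tissue: str = "unspecified") -> Library:
    """Parse a SAM or BED6 file into a :class:`Library`.

    SAM: the ``NH`` tag populates ``n_hits`` (default 1), a ``_xN`` id suffix
    populates ``copies`` (collapsed-read convention), and unmapped records are
    dropped with a logged count. BED6: the score column is the copy count.
    """
    path = Path(path)
    if format == "sam":
        reads = _read_sam(path)
    elif format == "bed6":
        reads = _read_bed6_reads(path)
    else:
        raise ValueError(f"unknown alignment format: {format!r}")
    total = sum(r.copies for r in reads)
    return Library(reads=reads, total_mapped=total, tissue=tissue)


def _read_sam(path: Path) -> list[AlignedRead]:
    reads: list[AlignedRead] = []
    dropped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.reference_name is None or rec.reference_start is None:
                dropped += 1
                continue
            n_hits = rec.get_tag("NH") if rec.has_tag("NH") else 1
            reads.append(AlignedRead(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                copies=_copies_from_id(rec.query_name),
                n_hits=int(n_hits),
                seq=rec.query_sequence,
            ))
    if dropped:
        logger.info("dropped %d unmapped/coordinate-less records from %s", dropped, path)
    return reads


def _read_bed6_reads(path: Path) -> list[AlignedRead]:
    reads: list[AlignedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 requires 6 columns, got {len(fields)}")
            try:
                chrom, start, end, name, score, strand = fields[:6]
                reads.append(AlignedRead(
                    read_id=name, chrom=chrom, start=int(start), end=int(end),
                    strand=strand, copies=max(1, int(float(score))),
                ))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED6 record: {exc}") from exc
    return reads


# ---------------------------------------------------------------------------
# collapsing and filtering
# ---------------------------------------------------------------------------

def collapse_reads(library: Library) -> Library:
    """Merge reads identical in (chrom, start, end, strand), summing copies.

    Idempotent; conserves total copies. Identical positions must agree on
    ``n_hits`` (they are the same sequence mapped the same way), else an error
    is raised.
    """
    merged: dict[tuple[str, int, int, str], AlignedRead] = {}
    for r in library.reads:
        key = (r.chrom, r.start, r.end, r.strand)
        prev = merged.get(key)
        if prev is None:
            merged[key] = r
        else:
            if prev.n_hits != r.n_hits:
                raise ValueError(
                    f"conflicting n_hits at {key}: {prev.n_hits} vs {r.n_hits}")
            merged[key] = replace(prev, copies=prev.copies + r.copies)
    return Library(reads=list(merged.values()),
                   total_mapped=library.total_mapped, tissue=library.tissue)


def filter_reads(library: Library, min_len: int = 18, max_len: int = 35,
                 max_hits: int = 100) -> Library:
    """Retain reads with length in [min_len, max_len] and n_hits <= max_hits.

    The default multimap cap of 100 mirrors standard small-RNA mapping
    practice (bowtie ``-m 100``). ``total_mapped`` is left untouched so RPM
    keeps referring to the pre-filter depth.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    if max_hits < 1:
        raise ValueError("max_hits must be >= 1")
    kept = [r for r in library.reads
            if min_len <= r.length <= max_len and r.n_hits <= max_hits]
    return Library(reads=kept, total_mapped=library.total_mapped,
                   tissue=library.tissue)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path, format: Literal["bed6", "gff3"] = "bed6") -> list[Locus]:
    """Parse annotation intervals into 0-based half-open :class:`Locus` records.

    GFF3 coordinates (1-based inclusive) are converted; the feature type
    column becomes the class label. Overlapping intervals are kept as-is.
    """
    path = Path(path)
    loci: list[Locus] = []
    if format == "bed6":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 6:
                    raise ValueError(f"{path}:{lineno}: BED6 requires 6 columns")
                try:
                    loci.append(Locus(chrom=f[0], start=int(f[1]), end=int(f[2]),
                                      name=f[3], strand=f[5], label=f[3].split(":")[0]))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed BED6 record") from exc
    elif format == "gff3":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) != 9:
                    raise ValueError(f"{path}:{lineno}: GFF3 requires 9 columns")
                try:
                    attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                    loci.append(Locus(chrom=f[0], start=int(f[3]) - 1, end=int(f[4]),
                                      name=attrs.get("ID", "."), strand=f[6], label=f[2]))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed GFF3 record") from exc
    else:
        raise ValueError(f"unknown annotation format: {format!r}")
    return loci


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def rpm_normalize(library: Library) -> dict[str, float]:
    """Reads-per-million for each read: ``1e6 * copies / total_mapped``.

    The denominator is the library's pre-filter mapped depth, so the RPM sum
    over all reads equals 1e6 only when nothing was filtered out.
    """
    if library.total_mapped <= 0:
        raise ValueError("RPM undefined for a library with total_mapped = 0")
    scale = 1e6 / library.total_mapped
    return {r.read_id: r.copies * scale for r in library.reads}


def library_to_frame(library: Library) -> pd.DataFrame:
    """Tabular view of a library (one row per read)."""
    return pd.DataFrame(
        [(r.read_id, r.chrom, r.start, r.end, r.strand, r.length, r.copies, r.n_hits)
         for r in library.reads],
        columns=["read_id", "chrom", "start", "end", "strand", "length", "copies", "n_hits"],
    )


def write_bed6(reads: Iterable[AlignedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.read_id}\t{r.copies}\t{r.strand}\n")
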