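"""Putative siRNA / piRNA pair prediction, discard filters and RPM profiles.

Candidate pairs are opposite-strand reads whose 5'-5' overlap matches one
class geometry: siRNA pairs overlap by read length - 2 (equal member lengths,
default 21 nt), piRNA pairs overlap by exactly 10 nt (member lengths in the
24-30 nt window). Candidates are then discarded when either member has fewer
than 5 collapsed copies, when the absolute log2 ratio of the two copy counts
exceeds 1.5, or when either member intersects an annotated miRNA region; the
three reasons are checked in that order and only the first failure is
recorded.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .sncrna_io import AlignedRead, Library, Locus, rpm_normalize
from .overlap_signature import pair_overlap

logger = logging.getLogger("sncsig")

MIN_COVERAGE_DEFAULT = 5
MAX_ABS_LOG_RATIO_DEFAULT = 1.5
SIRNA_WINDOW_DEFAULT = (21, 21)
PIRNA_WINDOW_DEFAULT = (24, 30)


@dataclass
class SncPair:
    """One opposite-strand read pair with its class call and filter status."""

    plus_member: AlignedRead
    minus_member: AlignedRead
    overlap: int
    pair_class: Literal["sirna", "pirna"]
    cov_plus: int
    cov_minus: int
    log_ratio: float
    status: Literal["kept", "discarded"] = "kept"
    discard_reason: Literal["low_coverage", "log_ratio", "mirna_region", "none"] = "none"


def find_candidate_pairs(library: Library, pair_class: Literal["sirna", "pirna"],
                         length_window: tuple[int, int] | None = None) -> list[SncPair]:
    """All opposite-strand pairs matching one class geometry.

    siRNA: both members the same length L within the window and overlap
    exactly L - 2. piRNA: both member lengths within the window and overlap
    exactly 10. The log2 copy-count ratio (plus over minus) is attached to
    each candidate. Indexed on plus-read start, so cost is linear in reads
    for fixed candidate density.
    """
    if pair_class == "sirna":
        window = SIRNA_WINDOW_DEFAULT if length_window is None else length_window
    elif pair_class == "pirna":
        window = PIRNA_WINDOW_DEFAULT if length_window is None else length_window
    else:
        raise ValueError(f"unknown pair class: {pair_class!r}")
    lo, hi = window

    plus_index: dict[tuple[str, int], list[AlignedRead]] = defaultdict(list)
    minus_reads: list[AlignedRead] = []
    for r in library.reads:
        if not lo <= r.length <= hi:
            continue
        if r.strand == "+":
            plus_index[(r.chrom, r.start)].append(r)
        else:
            minus_reads.append(r)

    pairs: list[SncPair] = []
    for m in minus_reads:
        if pair_class == "sirna":
            # overlap = L - 2 with equal lengths L  =>  plus.start = m.end - (L - 2)
            targets = [(m.end - (m.length - 2), m.length - 2)]
        else:
            targets = [(m.end - 10, 10)]
        for plus_start, k in targets:
            for p in plus_index.get((m.chrom, plus_start), ()):
                if pair_class == "sirna" and p.length != m.length:
                    continue
                if k < 1 or k > min(p.length, m.length):
                    continue
                pairs.append(SncPair(
                    plus_member=p, minus_member=m, overlap=k, pair_class=pair_class,
                    cov_plus=p.copies, cov_minus=m.copies,
                    log_ratio=math.log2(p.copies / m.copies),
                ))
    pairs.sort(key=lambda x: (x.plus_member.chrom, x.plus_member.start,
                              x.minus_member.end, x.plus_member.read_id))
    return pairs


def _region_trees(mirna_regions: Iterable[Locus]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for loc in mirna_regions:
        trees[loc.chrom].addi(loc.start, loc.end)
    return trees


def filter_pairs(pairs: Sequence[SncPair],
                 min_coverage: int = MIN_COVERAGE_DEFAULT,
                 max_abs_log_ratio: float = MAX_ABS_LOG_RATIO_DEFAULT,
                 mirna_regions: Iterable[Locus] = ()) -> list[SncPair]:
    """Apply the three discard rules, recording the first failing reason.

    A pair is discarded when (1) either member's coverage is below
    ``min_coverage``, else (2) |log2(cov_plus / cov_minus)| exceeds
    ``max_abs_log_ratio``, else (3) either member's interval intersects a
    miRNA region by at least 1 nt. Returns new pair records; the input is
    partitioned exactly into kept + discarded.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    trees = _region_trees(mirna_regions)

    out: list[SncPair] = []
    for pair in pairs:
        reason = "none"
        if min(pair.cov_plus, pair.cov_minus) < min_coverage:
            reason = "low_coverage"
        elif abs(pair.log_ratio) > max_abs_log_ratio:
            reason = "log_ratio"
        else:
            for member in (pair.plus_member, pair.minus_member):
                tree = trees.get(member.chrom)
                if tree is not None and tree.overlap(member.start, member.end):
                    reason = "mirna_region"
                    break
        out.append(SncPair(
            plus_member=pair.plus_member, minus_member=pair.minus_member,
            overlap=pair.overlap, pair_class=pair.pair_class,
            cov_plus=pair.cov_plus, cov_minus=pair.cov_minus,
            log_ratio=pair.log_ratio,
            status="kept" if reason == "none" else "discarded",
            discard_reason=reason,
        ))
    n_kept = sum(p.status == "kept" for p in out)
    logger.info("filter_pairs: %d/%d kept (min_cov=%d, max|log2|=%g, %d regions)",
                n_kept, len(out), min_coverage, max_abs_log_ratio, len(list(trees)))
    return out


def pairs_to_frame(pairs: Sequence[SncPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.plus_member.chrom, p.plus_member.start, p.minus_member.end,
          p.pair_class, p.overlap, p.cov_plus, p.cov_minus,
          p.log_ratio, p.status, p.discard_reason)
         for p in pairs],
        columns=["chrom", "plus_start", "minus_end", "class", "overlap",
                 "cov_plus", "cov_minus", "log_ratio", "status", "reason"],
    )


def class_length_profile(library: Library, kept_pairs: Sequence[SncPair],
                         mirna_annotations: Iterable[Locus] = ()) -> pd.DataFrame:
    """Per-class, per-length RPM expression profile.

    Reads intersecting a miRNA annotation are miRNA; otherwise membership in
    a kept siRNA / piRNA pair assigns the class; the rest are unclassified.
    Precedence on conflicts is mirna > sirna > pirna (logged). Returns a
    long-format table (class, length, rpm).
    """
    rpm = rpm_normalize(library)
    trees = _region_trees(mirna_annotations)

    member_class: dict[str, str] = {}
    for p in kept_pairs:
        if p.status != "kept":
            continue
        for member in (p.plus_member, p.minus_member):
            prev = member_class.get(member.read_id)
            if prev is None or (prev == "pirna" and p.pair_class == "sirna"):
                member_class[member.read_id] = p.pair_class

    totals: dict[tuple[str, int], float] = defaultdict(float)
    n_conflicts = 0
    for r in library.reads:
        tree = trees.get(r.chrom)
        in_mirna = tree is not None and bool(tree.overlap(r.start, r.end))
        pair_cls = member_class.get(r.read_id)
        if in_mirna:
            cls = "mirna"
            if pair_cls is not None:
                n_conflicts += 1
        elif pair_cls is not None:
            cls = pair_cls
        else:
            cls = "unclassified"
        totals[(cls, r.length)] += rpm[r.read_id]
    if n_conflicts:
        logger.info("class_length_profile: %d reads in both a miRNA region and a "
                    "kept pair; assigned mirna by precedence", n_conflicts)

    rows = [(cls, length, val) for (cls, length), val in sorted(totals.items())]
    return pd.DataFrame(rows, columns=["class", "length", "rpm"])


def compare_tissues(profiles_ovary: pd.DataFrame, profiles_soma: pd.DataFrame,
                    pseudocount: float = 1.0) -> pd.DataFrame:
    """Descriptive per-class ovary-vs-soma comparison.

    log2((RPM_ovary + p) / (RPM_soma + p)) on per-class RPM totals, with
    pseudocount p = 1 so a class missing from one tissue stays finite.
    """
    ov = profiles_ovary.groupby("class")["rpm"].sum()
    so = profiles_soma.groupby("class")["rpm"].sum()
    classes = sorted(set(ov.index) | set(so.index))
    rows = []
    for cls in classes:
        a = float(ov.get(cls, 0.0))
        b = float(so.get(cls, 0.0))
        rows.append((cls, a, b, math.log2((a + pseudocount) / (b + pseudocount))))
    return pd.DataFrame(rows, columns=["class", "rpm_ovary", "rpm_soma", "log2_fold_change"])
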