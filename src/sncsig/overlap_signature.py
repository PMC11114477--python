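"""Opposite-strand read-pair overlap histograms and Z-score signatures.

Dicer-2 cuts long dsRNA into siRNA duplexes with 2-nt 3' overhangs, so the two
strands of a duplex overlap by read length - 2 (19 nt for canonical 21-mers).
Ping-pong piRNA amplification produces sense/antisense pairs whose 5' ends
overlap by exactly 10 nt. Counting opposite-strand read pairs per 5'-5'
overlap length k (k = 4..20 by default) and standardising the counts to
Z-scores turns these geometries into detectable peaks: z > 1 at k = L - 2
marks Dicer processing, z > 1 at k = 10 marks the ping-pong cycle.

The 5'-5' overlap of a plus read and a minus read is defined here as
``minus.end - plus.start`` in 0-based half-open coordinates. A pair is counted
as "overlapping by k" only when 1 <= k <= min(read lengths), in which case k
equals the length of the interval intersection of the two reads.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .sncrna_io import AlignedRead, Library

Stratum = int | tuple[int, int] | Literal["all"]
Weighting = Literal["copy_weighted", "raw_pairs"]

K_MIN_DEFAULT = 4
K_MAX_DEFAULT = 20
Z_THRESHOLD_DEFAULT = 1.0


@dataclass
class OverlapHistogram:
    """Weighted pair counts ``n_k`` over overlap groups k in [k_min, k_max]."""

    stratum_length: Stratum
    k_min: int
    k_max: int
    counts: dict[int, float]
    weighting: Weighting

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[k] for k in range(self.k_min, self.k_max + 1)])


@dataclass
class ZScoreProfile:
    """Standardised overlap-group counts ``z_k = (n_k - mean) / sd``.

    ``sd`` is the population standard deviation over the overlap groups; when
    it is zero (all groups equal) the profile is flagged degenerate and every
    z is 0 rather than NaN.
    """

    z: dict[int, float]
    mean: float
    sd: float
    degenerate: bool


@dataclass
class SignatureCall:
    signature: Literal["dicer", "pingpong"]
    stratum_length: Stratum
    overlap_k: int
    z_value: float
    present: bool


def pair_overlap(plus_read: AlignedRead, minus_read: AlignedRead) -> int:
    """5'-5' overlap of an opposite-strand read pair, in nt (may be <= 0).

    Equals ``minus.end - plus.start``: the distance from the plus read's 5'
    end to one past the minus read's 5' end. A canonical 21-nt siRNA duplex
    with a 2-nt 3' overhang gives 19; a ping-pong pair gives 10.
    """
    if plus_read.strand != "+":
        raise ValueError("plus_read must be on the + strand")
    if minus_read.strand != "-":
        raise ValueError("minus_read must be on the - strand")
    if plus_read.chrom != minus_read.chrom:
        raise ValueError("pair members must map to the same chromosome")
    return minus_read.end - plus_read.start


def _in_stratum(read: AlignedRead, stratum: Stratum) -> bool:
    if stratum == "all":
        return True
    if isinstance(stratum, tuple):
        lo, hi = stratum
        return lo <= read.length <= hi
    return read.length == stratum


def overlap_histogram(library: Library, stratum_length: Stratum = 21,
                      k_min: int = K_MIN_DEFAULT, k_max: int = K_MAX_DEFAULT,
                      weighting: Weighting = "copy_weighted") -> OverlapHistogram:
    """Histogram of opposite-strand pair overlaps for one read-length stratum.

    Both pair members must belong to the stratum: a single length (classic
    "21 bp reads only" mode), a (min, max) length window (the mixed-length
    mode used for the ping-pong call on 24-30 nt reads), or ``"all"``.

    ``copy_weighted`` adds ``(copies_p / n_hits_p) * (copies_m / n_hits_m)``
    per pair, so collapsed duplicates count fully while multimappers are
    down-weighted fractionally; ``raw_pairs`` adds 1 per read pair.

    Runs in O(reads x k_range) by indexing plus reads on their start
    coordinate: a pair overlaps by k exactly when plus.start = minus.end - k.
    """
    if k_min > k_max:
        raise ValueError("k_min must be <= k_max")
    counts: dict[int, float] = {k: 0.0 for k in range(k_min, k_max + 1)}

    plus_index: dict[tuple[str, int], list[AlignedRead]] = defaultdict(list)
    minus_reads: list[AlignedRead] = []
    for r in library.reads:
        if not _in_stratum(r, stratum_length):
            continue
        if r.strand == "+":
            plus_index[(r.chrom, r.start)].append(r)
        else:
            minus_reads.append(r)

    for m in minus_reads:
        w_m = (m.copies / m.n_hits) if weighting == "copy_weighted" else 1.0
        for k in range(k_min, k_max + 1):
            if k < 1 or k > m.length:
                continue
            for p in plus_index.get((m.chrom, m.end - k), ()):
                if k > p.length:
                    continue
                w_p = (p.copies / p.n_hits) if weighting == "copy_weighted" else 1.0
                counts[k] += w_p * w_m

    return OverlapHistogram(stratum_length=stratum_length, k_min=k_min,
                            k_max=k_max, counts=counts, weighting=weighting)


def zscore_profile(histogram: OverlapHistogram) -> ZScoreProfile:
    """Standardise the overlap-group counts across k.

    Mean and population sd (ddof 0) are taken over the k_max - k_min + 1
    groups of this histogram; a z of 1 therefore means that overlap group is
    one standard deviation more populated than the average group.
    """
    ks = range(histogram.k_min, histogram.k_max + 1)
    values = histogram.as_array()
    mean = float(values.mean())
    sd = float(values.std(ddof=0))
    if sd == 0.0:
        return ZScoreProfile(z={k: 0.0 for k in ks}, mean=mean, sd=sd, degenerate=True)
    z = {k: (histogram.counts[k] - mean) / sd for k in ks}
    return ZScoreProfile(z=z, mean=mean, sd=sd, degenerate=False)


def call_signatures(profile: ZScoreProfile, stratum_length: int,
                    threshold: float = Z_THRESHOLD_DEFAULT) -> tuple[SignatureCall, SignatureCall]:
    """Dicer and ping-pong presence calls from one Z-score profile.

    The Dicer signature sits at k = stratum_length - 2 (the 2-nt 3' overhang
    geometry); the ping-pong signature at k = 10. A signature is "present"
    when its z exceeds the threshold (default 1: the group is at least one
    standard deviation more populated than the mean group).
    """
    dicer_k = stratum_length - 2
    for k in (dicer_k, 10):
        if k not in profile.z:
            raise ValueError(f"required overlap group k={k} outside histogram range")
    dicer = SignatureCall("dicer", stratum_length, dicer_k, profile.z[dicer_k],
                          profile.z[dicer_k] > threshold)
    pingpong = SignatureCall("pingpong", stratum_length, 10, profile.z[10],
                             profile.z[10] > threshold)
    return dicer, pingpong


def signature_table(libraries: Mapping[str, Library], stratum_length: int = 21,
                    k_min: int = K_MIN_DEFAULT, k_max: int = K_MAX_DEFAULT,
                    threshold: float = Z_THRESHOLD_DEFAULT,
                    weighting: Weighting = "copy_weighted") -> pd.DataFrame:
    """Library x k matrix of Z-scores plus the two signature calls per library.

    Rows are sorted by library name for deterministic output.
    """
    if not libraries:
        raise ValueError("at least one library is required")
    rows = []
    for name in sorted(libraries):
        hist = overlap_histogram(libraries[name], stratum_length, k_min, k_max, weighting)
        prof = zscore_profile(hist)
        dicer, pingpong = call_signatures(prof, stratum_length, threshold)
        row: dict[str, object] = {"library": name}
        row.update({f"z{k}": prof.z[k] for k in range(k_min, k_max + 1)})
        row.update({
            "dicer_z": dicer.z_value, "dicer_present": dicer.present,
            "pingpong_z": pingpong.z_value, "pingpong_present": pingpong.present,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def brute_force_histogram(library: Library, stratum_length: Stratum = 21,
                          k_min: int = K_MIN_DEFAULT, k_max: int = K_MAX_DEFAULT,
                          weighting: Weighting = "copy_weighted") -> OverlapHistogram:
    """O(n^2) all-pairs reference implementation of :func:`overlap_histogram`.

    Enumerates every plus/minus read pair explicitly; intended as an oracle
    for small libraries, not for production use.
    """
    if k_min > k_max:
        raise ValueError("k_min must be <= k_max")
    counts: dict[int, float] = {k: 0.0 for k in range(k_min, k_max + 1)}
    stratum = [r for r in library.reads if _in_stratum(r, stratum_length)]
    plus = [r for r in stratum if r.strand == "+"]
    minus = [r for r in stratum if r.strand == "-"]
    for p in plus:
        for m in minus:
            if p.chrom != m.chrom:
                continue
            k = pair_overlap(p, m)
            if k < 1 or k > min(p.length, m.length) or not (k_min <= k <= k_max):
                continue
            if weighting == "copy_weighted":
                counts[k] += (p.copies / p.n_hits) * (m.copies / m.n_hits)
            else:
                counts[k] += 1.0
    return OverlapHistogram(stratum_length=stratum_length, k_min=k_min,
                            k_max=k_max, counts=counts, weighting=weighting)
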