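# Methods

## Overlap signature model

The central quantity is the 5′–5′ overlap of an opposite-strand read pair,
defined as `minus.end − plus.start` in 0-based half-open coordinates. A pair
"overlaps by k" only when 1 ≤ k ≤ min(read lengths); in that regime k equals
the interval-intersection length of the two reads, which ties the definition
to the intuitive picture. The convention reproduces both biological anchors:
a 21-nt Dicer-2 duplex with a 2-nt 3′ overhang overlaps by 19, a ping-pong
pair by 10. The minus strand's biological 5′ end is `end − 1` in these
coordinates.

Counts n_k over k ∈ [4, 20] (17 groups, zero-filled) are standardised with
the **population** standard deviation (ddof 0) over the groups. Sample vs
population sd is not externally fixed for this statistic; population sd was
chosen because it is stable on tiny fixtures and changes z by a factor
√(17/16) ≈ 1.03, immaterial to a threshold of 1. When sd = 0 (e.g. an empty
stratum) the profile is flagged degenerate and all z are set to 0 rather than
raising, so batch tabulation over many libraries never aborts on an empty
one.

Both members of a pair must belong to the length stratum. The default
stratum is the single length 21 nt; a (min, max) window form exists for the
ping-pong call on 24–30 nt reads, since ping-pong partners need not share a
length. Pair weighting defaults to `copy_weighted`:
(copies₊/NH₊)·(copies₋/NH₋), i.e. collapsed duplicates count fully and
multimappers fractionally. Whether multimapped reads should be fractionally
weighted is genuinely open; fractional weighting avoids a single repetitive
locus inflating one overlap group, and a `raw_pairs` mode (weight 1 per pair)
is kept both for oracle tests and for sensitivity checks. The production
histogram indexes plus reads by start coordinate (a pair overlaps by k iff
`plus.start = minus.end − k`), giving O(reads × 17) cost; an O(n²) all-pairs
enumeration is retained as a test oracle.

A signature is called present when z exceeds 1 (one standard deviation above
the mean group): Dicer at k = stratum − 2, ping-pong at k = 10.

## Pair classification and filters

Candidates: siRNA pairs are opposite-strand reads of equal length L within
[21, 21] overlapping by exactly L − 2 (the equal-length requirement follows
from the "read length − 2" geometry presupposing a common length; it can be
relaxed by widening the window); piRNA pairs have both lengths in [24, 30]
and overlap exactly 10. "Coverage" of a member is its collapsed copy count —
the only per-read count available before locus calling. Discard rules are
applied in a fixed order (coverage < 5, then |log ratio| > 1.5, then miRNA
region intersection ≥ 1 nt) and only the first failing reason is recorded,
making the discard accounting reproducible. The log ratio is log base 2 of
cov₊/cov₋ compared by absolute value — the fold-change convention in
small-RNA work; base and signedness are configurable assumptions.

Expression profiles assign each read to miRNA (annotation intersection),
else siRNA/piRNA (membership in a kept pair), else unclassified, with
precedence mirna > sirna > pirna on conflicts (logged), and sum RPM per class
per read length. RPM uses the library's pre-filter mapped depth
(1e6 · copies / total_mapped) so values are comparable across filter
settings. Tissue comparison is descriptive: per-class
log2((RPM_ovary + 1)/(RPM_soma + 1)); no count-model differential testing is
attempted.

## miRNA families

The seed is mature positions 2–8 (7 nt, 1-based inclusive) — the MirGeneDB
convention. Local alignment uses match +1, mismatch −2, gap −3 with
thresholds on identity (matches / aligned columns, gaps counted) and on
coverage of the shorter sequence, in place of E-values, which would depend
on an arbitrary database size. Known-family assignment takes the
best-scoring reference hit passing identity ≥ 0.6 and coverage ≥ 0.5 (ties:
identity, then reference id — making the result independent of reference
order) and assigns its family only on an identical seed. Novel families are
connected components of the graph joining genes with a passing mutual hit
and seed Hamming distance ≤ 1; single linkage means a chained family can
contain seed pairs at distance 2, which is documented behaviour of the
pairwise rule, not an error. Family ids are the lexicographically smallest
member, so clustering is input-order invariant. The star filter (star read
support ≥ 5, strict "lower than" discards) applies to novel candidates only.
Conservation against a second genome requires a hit at identity ≥ 0.8 and
coverage ≥ 0.8 on either strand whose alignment covers the seed gap-free
with zero mismatches — treating seed conservation as part of "shared", the
stricter of the two readings.

## Tree metrics

Root-to-tip distance is the branch-length sum on the unique root→tip path;
trees are taken as rooted as written, with no re-rooting logic. The group
comparison is a two-sided Mann–Whitney U test (choice of test is an
assumption; the one-sided alternatives are available). The U convention is
U_A = n_A·n_B + n_A(n_A+1)/2 − R_A (counts of b > a with midrank ties), so
U_A + U_B = n_A·n_B. For pooled n ≤ 12 the null is enumerated exactly over
all C(n, n_A) labellings; larger samples use the normal approximation with
tie-corrected variance (cross-checked against an independent implementation
in the tests).

## Synthetic data

The simulator generates what the analysis assumes and nothing more: a
uniform-random A/C/G/T genome; non-overlapping loci with ≥ 50 nt gaps
(placement by rejection sampling, erroring with the class name when a locus
cannot be placed); miRNA hairpins of 22-nt arms and a 15-nt loop whose 3′
arm is the reverse complement of the 5′ arm, emitting mature/star reads with
±1 nt end jitter (lengths 20–24 nt) at a configurable star fraction
(default 0.1); siRNA duplexes of 21-nt reads with a 2-nt overhang (uniform
or phased starts); ping-pong pairs with plus 5′ at x and minus 5′ at x + 9,
lengths independently uniform on 24–30 nt; and background reads uniform over
positions, strands and 18–35 nt. Default read budgets (500 siRNA duplexes,
500 ping-pong pairs, 1000 miRNA reads, 5000 background reads on a 100 kb
genome) give signature z-scores near 4 — a clearly positive but not
saturated signal. All randomness flows through one seeded NumPy generator in
a documented draw order (genome, then siRNA, ping-pong, miRNA, background),
so outputs are byte-identical across runs.

Read sequences always equal the genome subsequence at their coordinates
(reverse-complemented on minus), so SAM/FASTQ output is internally
consistent; the optional ping-pong 5′-U bias is implemented by rejection
sampling over start positions to preserve that invariant, and defaults off
since no fidelity claim is attached to it. Simulated reads are unique
mappers (NH = 1) unless the multimap flag marks siRNA reads NH = 2 to
exercise fractional weighting.

What the simulator does **not** model: sequencing errors, quality variation,
adapter contamination, nucleotide composition bias, transposon-derived
sequence, phased piRNA trails, or realistic expression dispersion. Passing
tests therefore demonstrate that the statistics recover planted geometric
structure over a uniform background — not that the pipeline is robust to
the mapping artefacts and composition biases of real libraries.

## Problem sizes and numerical choices

Test and validation runs use 100 kb genomes with the default read budgets;
the null-calibration check averages z_19 over 50 background-only seeds,
sizes chosen so the whole suite runs in well under a minute while keeping
per-stratum pair counts in the hundreds. Exact Mann–Whitney enumeration caps
at pooled n = 12 (C(12,6) = 924 labellings). Zero-filled histograms make the
group count fixed at 17 regardless of data sparsity. Degenerate inputs
(empty library, all-equal counts, sd = 0) return flagged zero profiles
rather than errors throughout.

## Known limitations

* The signature operates on collapsed read counts; it does not model
  per-position coverage or call genomic siRNA/piRNA loci.
* Candidate discovery for miRNA genes (hairpin prediction and scoring) is an
  upstream input; only the downstream filtering/assignment is implemented.
* The conservation check aligns precursors against whole chromosomes with a
  quadratic-time aligner, which is fine at simulation scale but would need a
  seeded search for real genomes.
* Tissue comparison is descriptive (pseudocounted fold change), not a
  statistical test.
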