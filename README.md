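# sncsig

Small non-coding RNA (sncRNA) classes leave geometric fingerprints in aligned
small RNA-seq libraries. Dicer-2 cuts long double-stranded RNA into
endo-siRNA duplexes with 2-nt 3′ overhangs, so the two reads of a duplex
overlap by *read length − 2* (19 nt for canonical 21-mers). Ping-pong piRNA
amplification produces sense/antisense pairs whose 5′ ends overlap by exactly
10 nt. `sncsig` detects these signatures, classifies siRNA/piRNA read pairs,
profiles class expression, assigns miRNA genes to seed-based families, and
compares branch rates on gene-family trees — for anyone asking whether an
RNAi pathway is active in a species from its small-RNA data alone.

## The statistic

For a read-length stratum *L* (default 21 nt), count opposite-strand read
pairs per 5′–5′ overlap *k* ∈ [4, 20], where the overlap of a plus read and a
minus read is `minus.end − plus.start` (0-based half-open coordinates) and a
pair counts only when 1 ≤ k ≤ min(read lengths). The counts n_k are
standardised over the 17 overlap groups,

    z_k = (n_k − mean(n)) / sd(n)        (population sd)

so z_k > 1 means pairs overlapping by k are at least one standard deviation
more numerous than the average overlap group. z_{L−2} > 1 marks Dicer
processing; z_10 > 1 marks the ping-pong cycle. Pairs are copy-weighted with
fractional 1/NH weight for multimappers by default.

Downstream, candidate pairs (siRNA: equal lengths, overlap L−2; piRNA:
lengths 24–30 nt, overlap 10) are discarded when either member has < 5
collapsed copies, |log2(cov₊/cov₋)| > 1.5, or a member intersects an
annotated miRNA region. miRNA genes are assigned to a reference family by a
best local-alignment hit *with an identical 7-nt seed* (mature positions
2–8); the rest cluster into novel families via mutual hits with seed Hamming
distance ≤ 1 (single linkage).

## Worked example

```python
from sncsig import (SimConfig, simulate_library, overlap_histogram,
                    zscore_profile, call_signatures)

sim = simulate_library(SimConfig(seed=1))          # 100 kb genome; siRNA,
                                                   # piRNA, miRNA + background
prof = zscore_profile(overlap_histogram(sim.library, stratum_length=21))
dicer, pingpong = call_signatures(prof, stratum_length=21)
print(f"z_19 = {prof.z[19]:.2f}  dicer present: {dicer.present}")

prof_pi = zscore_profile(overlap_histogram(sim.library, stratum_length=(24, 30)))
print(f"z_10 = {prof_pi.z[10]:.2f} in the 24-30 nt window")
```

prints

```
z_19 = 3.96  dicer present: True
z_10 = 3.99 in the 24-30 nt window
```

The 500 simulated Dicer duplexes put the 19-overlap group ~4 standard
deviations above the mean overlap group in the 21-nt stratum, and the 500
ping-pong pairs do the same for the 10-overlap group among 24–30 nt reads —
the two signature calls a real library with active pathways would show.

The same analyses are scriptable from the shell:

```
sncsig simulate --seed 1 --outdir sim/
sncsig signature --in sim/library.sam --stratum 21
sncsig classify  --in sim/library.sam --min-cov 5 --max-log-ratio 1.5
sncsig tree --newick tree.nwk --group-a miago.txt --group-b piwi.txt
```

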