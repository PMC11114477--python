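import numpy as np
import pytest

from sncsig.sncrna_io import AlignedRead, Library


def make_read(read_id="r", chrom="chr1", start=100, end=121, strand="+",
              copies=1, n_hits=1, seq=None):
    return AlignedRead(read_id=read_id, chrom=chrom, start=start, end=end,
                       strand=strand, copies=copies, n_hits=n_hits, seq=seq)


def make_library(reads, total_mapped=None, tissue="unspecified"):
    if total_mapped is None:
        total_mapped = sum(r.copies for r in reads)
    return Library(reads=list(reads), total_mapped=total_mapped, tissue=tissue)


def random_library(rng: np.random.Generator, n_reads: int, genome_len: int = 2000,
                   len_range=(18, 30), max_copies: int = 4, max_hits: int = 3) -> Library:
    """A random small library for oracle-equivalence tests."""
    reads = []
    for i in range(n_reads):
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        start = int(rng.integers(0, genome_len - length))
        reads.append(AlignedRead(
            read_id=f"r{i}", chrom=f"chr{int(rng.integers(1, 3))}",
            start=start, end=start + length,
            strand="+" if rng.random() < 0.5 else "-",
            copies=int(rng.integers(1, max_copies + 1)),
            n_hits=int(rng.integers(1, max_hits + 1)),
        ))
    return make_library(reads)


@pytest.fixture(scope="session")
def default_simulation():
    """One full simulated dataset shared by read-only tests."""
    from sncsig.simdata import SimConfig, simulate_library
    return simulate_library(SimConfig(seed=11))
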