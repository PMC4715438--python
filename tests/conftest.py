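import numpy as np
import pytest

from phylogeokit.seqstats import Alignment


@pytest.fixture
def toy_alignment() -> Alignment:
    """Five 12-bp sequences with a handful of segregating sites."""
    seqs = [
        "AAAAAAAAAAAA",
        "AAAAAAAAAAAT",
        "AAGAAAAAAAAT",
        "AAGAATAAAAAT",
        "CAGAATAAAAAT",
    ]
    return Alignment([f"s{i}" for i in range(5)], seqs)


@pytest.fixture
def random_alignment() -> Alignment:
    """20 random 60-bp sequences (seeded) for brute-force comparisons."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    seqs = ["".join(bases[rng.integers(0, 4, 60)]) for _ in range(20)]
    return Alignment([f"r{i}" for i in range(20)], seqs)


def brute_force_pi(alignment: Alignment) -> float:
    """All-pairs per-site nucleotide diversity, straight from the definition."""
    n = alignment.n
    L = alignment.length
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(a != b for a, b in
                         zip(alignment.sequences[i], alignment.sequences[j]))
    return total / (L * n * (n - 1) / 2)
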