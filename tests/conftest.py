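import numpy as np
import pytest

from cenpop.alignment_io import Alignment


def make_alignment(seqs, locus_id="test", ids=None):
    ids = ids or [f"s{i+1}" for i in range(len(seqs))]
    return Alignment(locus_id, tuple(zip(ids, seqs)))


@pytest.fixture
def aln():
    return make_alignment


def random_alignment(rng: np.random.Generator, n: int, L: int,
                     p_missing: float = 0.2, p_gap: float = 0.1) -> Alignment:
    """Random alignment over ACGTN- for oracle property tests."""
    chars = np.array(list("ACGT"))
    seqs = []
    for i in range(n):
        s = rng.choice(chars, size=L)
        mask = rng.uniform(size=L)
        s = np.where(mask < p_missing, "N", s)
        s = np.where((mask >= p_missing) & (mask < p_missing + p_gap), "-", s)
        seqs.append("".join(s))
    return make_alignment(seqs)


def brute_force_pi(alignment: Alignment) -> float:
    """Mean pairwise difference proportion over valid pairs, averaged per
    site over sites with >=2 valid bases — independent of the per-site
    allele-count formula."""
    valid = set("ACGT")
    n_sites = 0
    total = 0.0
    for col in range(alignment.length):
        bases = [b for b in alignment.column(col) if b in valid]
        if len(bases) < 2:
            continue
        n_sites += 1
        diffs = pairs = 0
        for i in range(len(bases)):
            for j in range(i + 1, len(bases)):
                pairs += 1
                diffs += bases[i] != bases[j]
        # unbiased per-site heterozygosity equals mean pairwise difference
        total += diffs / pairs
    return total / n_sites if n_sites else 0.0
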