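import numpy as np
import pytest
from hypothesis import settings

from wigpeak import GenomeTable, ReadAlignment

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def toy_genome():
    return GenomeTable([("chr1", 1000), ("chr2", 500)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_read(chrom="chr1", pos5=0, strand="+", alen=36, n_k=1,
              read_id="r1", score=42):
    return ReadAlignment(read_id=read_id, chrom=chrom, pos5=pos5, strand=strand,
                         alen=alen, n_k=n_k, score=score)


def naive_bin_counts(alignments, genome, bin_size, fragment_length):
    """Independent per-base oracle for r_x: walk every base of every extended
    fragment, record which bins it touches, and add the read weight once per
    touched bin."""
    out = {}
    for chrom, length in genome:
        nbins = -(-length // bin_size)
        out[chrom] = np.zeros(nbins)
    for a in alignments:
        length = genome.length_of(a.chrom)
        flen = max(fragment_length, a.alen)
        if a.strand == "+":
            start = a.pos5
        else:
            start = a.pos5 + a.alen - flen
        bins = set()
        for base in range(start, start + flen):
            if 0 <= base < length:
                bins.add(base // bin_size)
        for b in bins:
            out[a.chrom][b] += 1.0 / a.n_k
    return out


def exact_rank_sum_oracle(chip, control):
    """Brute-force enumeration of all C(2n, n) rank splits (independent of the
    DP used by the implementation): P(chip rank sum >= observed)."""
    from itertools import combinations

    from scipy.stats import rankdata

    chip = list(chip)
    n = len(chip)
    ranks = rankdata(np.asarray(chip + list(control), dtype=float))
    obs = ranks[:n].sum()
    hits = total = 0
    for combo in combinations(range(2 * n), n):
        total += 1
        if sum(ranks[i] for i in combo) >= obs - 1e-9:
            hits += 1
    return hits / total
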