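import numpy as np
import pytest

from promkit.tss import TSSCollection, TSSEvidence


def make_collection(positions, gene_id="G1", chrom="chr1", strand="+", score=5.0, scores=None):
    if scores is None:
        scores = [score] * len(positions)
    return TSSCollection(
        gene_id,
        chrom,
        strand,
        [TSSEvidence(int(p), float(s), "mRNA_model") for p, s in zip(positions, scores)],
    )


def brute_force_profile_score(positions, scores, center, window=3000):
    """Independent O(n) oracle for the clustering score at one center."""
    total = 0.0
    for p, s in zip(positions, scores):
        d = abs(p - center)
        if d <= window / 2:
            total += s * np.cos(np.pi * d / window)
    return total


@pytest.fixture
def rng():
    return np.random.default_rng(20160623)


@pytest.fixture
def toy_genome():
    """Small deterministic contigs keyed by name."""
    r = np.random.default_rng(7)
    return {
        "chr1": "".join(r.choice(list("ACGT"), size=30_000)),
        "chrP": "ACGTACGTNNACGTACGT",
    }
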