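import dendropy
import numpy as np
import pytest


@pytest.fixture
def balanced4_tree():
    """((A:1,B:1):1,(C:2,D:2):1) — used for hand-worked pruning checks."""
    return dendropy.Tree.get(
        data="((A:1,B:1):1,(C:2,D:2):1);", schema="newick"
    )


@pytest.fixture
def star5_tree():
    return dendropy.Tree.get(
        data="(a:1,b:1,c:1,d:1,e:1);", schema="newick"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_features(genome):
    """Independent per-base labelling oracle for the sequence characteristics.

    Marks every base as gene or intergenic in a flat array and counts, rather
    than doing interval arithmetic.
    """
    n = len(genome.sequence)
    mask = np.zeros(n, dtype=bool)
    for g in genome.genes:
        for s, e in g.segments:
            mask[s:e] = True
    seq = genome.sequence.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    return {
        "TL": n,
        "GRL": int(mask.sum()),
        "IGRL": int(n - mask.sum()),
        "GCC": (counts["G"] + counts["C"]) / sum(counts.values()),
        "GN": len(genome.genes),
    }
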