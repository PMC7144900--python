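import numpy as np
import pytest

from tadpole.hic_io import ContactMatrix
from tadpole.synthetic import SyntheticSpec, generate_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_symmetric(rng):
    """Random 20x20 symmetric non-negative matrix with positive diagonal."""
    a = rng.uniform(0.5, 5.0, size=(20, 20))
    vals = (a + a.T) / 2
    return ContactMatrix(chrom="chrT", start_bp=0, resolution=10_000, values=vals)


@pytest.fixture
def planted_two_level():
    """60-bin matrix with a 2-level nested hierarchy and its truth."""
    spec = SyntheticSpec(
        n_bins=60,
        levels=((30,), (15, 30, 45)),
        block_contrast=3.0,
        seed=7,
    )
    return generate_matrix(spec)


def brute_force_coniss(d):
    """From-scratch constrained agglomeration recomputing every dispersion.

    Independent oracle for the CONISS implementation: clusters are kept as
    explicit bin lists, the dispersion of a cluster C is
    ``sum_{i<j in C} d_ij^2 / |C|`` recomputed from the distance matrix at
    every step, and among adjacent pairs the merge with the smallest
    dispersion increase wins (leftmost on ties).  Returns the merge
    sequence as (left cluster bins, right cluster bins, increment).
    """
    d = np.asarray(d, dtype=float)
    clusters = [[i] for i in range(d.shape[0])]

    def dispersion(c):
        if len(c) < 2:
            return 0.0
        idx = np.array(c)
        sub = d[np.ix_(idx, idx)]
        return float(np.sum(np.triu(sub, 1) ** 2) / len(c))

    merges = []
    while len(clusters) > 1:
        costs = [
            dispersion(clusters[a] + clusters[a + 1])
            - dispersion(clusters[a])
            - dispersion(clusters[a + 1])
            for a in range(len(clusters) - 1)
        ]
        a = int(np.argmin(costs))
        merges.append((list(clusters[a]), list(clusters[a + 1]), costs[a]))
        clusters[a : a + 2] = [clusters[a] + clusters[a + 1]]
    return merges
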