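import itertools

import numpy as np
import pandas as pd
import pytest

import specrqe as sq


def naive_rqe(p, D):
    """Brute-force double loop over ordered pairs (the Eq.-style definition)."""
    total = 0.0
    n = len(p)
    for i in range(n):
        for j in range(n):
            if i != j:
                total += D[i, j] * p[i] * p[j]
    return total


def exhaustive_rqe_values(p, D):
    """RQE of every permutation of p (for small n)."""
    perms = np.array(list(itertools.permutations(range(len(p)))))
    V = np.asarray(p)[perms]
    return np.einsum("ij,jk,ik->i", V, D, V)


def random_instance(rng, n):
    """A random (p, D) pair: sparse nonnegative weights, metric-free D."""
    p = rng.random(n)
    p[rng.random(n) < 0.4] = 0.0
    x = rng.random(n) * 100
    D = np.abs(x[:, None] - x[None, :])
    return p, D


def perfect_block_toy():
    """12 samples in 4 habitat blocks; D zero within blocks, positive between.

    The focal feature carries weight only inside block 0, so every pair of
    samples it occupies is at dissimilarity zero: the perfect-specificity
    configuration.
    """
    blocks = np.repeat(np.arange(4), 3)
    D = np.abs(blocks[:, None] - blocks[None, :]).astype(float)
    labels = [f"s{i:02d}" for i in range(12)]
    p = np.zeros(12)
    p[:3] = [0.5, 0.3, 0.2]
    table = pd.DataFrame({"focal": p}, index=labels)
    return table, sq.validate_dissim(D, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def gradient_study():
    """A small synthetic gradient study shared across end-to-end tests."""
    table, metadata, truth = sq.make_dataset(
        n_samples=40, sd_values=(30.0, 100.0, 400.0),
        uniform_mixes=(0.0, 0.5), reps=3, seed=77,
    )
    D = sq.vector_to_dissim(metadata["gradient"].to_numpy(), list(metadata.index))
    return table, D, truth
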