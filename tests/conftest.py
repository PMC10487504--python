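import itertools

import numpy as np
import pytest

from gcscape import SyntheticGenomeSpec, simulate


def write_fasta(path, records, wrap=60):
    """Write (name, sequence-string) pairs as a plain FASTA file."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")
    return path


def brute_force_sdcm(values, weights, k):
    """Exhaustive minimum SDCM over all contiguous k-partitions (oracle).

    Enumerates every choice of k-1 split points among the sorted distinct
    values; independent of the dynamic program it cross-checks.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    m = v.size
    best = np.inf
    for splits in itertools.combinations(range(1, m), k - 1):
        bounds = (0,) + splits + (m,)
        sdcm = 0.0
        for lo, hi in zip(bounds, bounds[1:]):
            seg_v, seg_w = v[lo:hi], w[lo:hi]
            mean = np.average(seg_v, weights=seg_w)
            sdcm += float(np.sum(seg_w * (seg_v - mean) ** 2))
        best = min(best, sdcm)
    return best


def random_weighted_set(rng, max_distinct=15, max_weight=4):
    """A small random strictly-ascending weighted value set for oracle tests."""
    m = int(rng.integers(2, max_distinct + 1))
    values = np.sort(rng.choice(np.arange(0, 1000), size=m, replace=False)) / 10.0
    weights = rng.integers(1, max_weight + 1, size=m)
    return values, weights


@pytest.fixture(scope="session")
def two_state_genome():
    """Gar-like heterogeneous genome: 20 Mb, 35/55 GC domains of mean 500 kb."""
    return simulate(SyntheticGenomeSpec.two_state(seed=7))


@pytest.fixture(scope="session")
def two_state_windows_1kb(two_state_genome):
    return two_state_genome.windows(1000)
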