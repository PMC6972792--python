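import numpy as np
import pandas as pd
import pytest

from pioneerscan.intervals import IntervalSet
from pioneerscan.tracks import SignalTrack


def random_interval_set(rng, n=50, chrom_len=10_000, chroms=("chrA", "chrB")):
    """Random interval set for oracle comparisons (no attributes)."""
    rows = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, chrom_len - 2))
        end = int(start + rng.integers(1, min(400, chrom_len - start)))
        rows.append((chrom, start, end))
    return IntervalSet.from_records(rows)


def coverage(intervals, chroms=("chrA", "chrB"), chrom_len=10_000):
    """Per-base boolean oracle representation of an interval set."""
    return {c: intervals.coverage_array(c, chrom_len) for c in chroms}


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def flat_track():
    """Constant-1 ratio track on two 10 kb chromosomes."""
    return SignalTrack({"chrA": np.ones(10_000), "chrB": np.ones(10_000)})


@pytest.fixture
def random_genome():
    def make(length=10_000, seed=0, chrom="chrA"):
        r = np.random.default_rng(seed)
        return {chrom: "".join(r.choice(list("ACGT"), size=length))}

    return make
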