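import numpy as np
import pytest

from anv import ProteinSequence, accumulate_indicators


@pytest.fixture(scope="session")
def example_seq():
    """The ten-residue worked example used throughout the embedding tests."""
    return ProteinSequence("example", "ARRNADCDCC")


@pytest.fixture(scope="session")
def example_table(example_seq):
    return accumulate_indicators(example_seq)


@pytest.fixture(scope="session")
def benchmark_families():
    """Well-separated 4-family synthetic benchmark (session-cached: the
    hull LPs over 250 dimensions dominate test runtime)."""
    from anv import make_benchmark

    specs, families = make_benchmark(n_families=4, separation=1.0, seed=20230917,
                                     n_sequences=50)
    return specs, families


@pytest.fixture(scope="session")
def benchmark_point_sets(benchmark_families):
    from anv import FamilyPointSet, vectorize_collection

    _, families = benchmark_families
    sets = []
    for name, seqs in families.items():
        table = vectorize_collection(seqs)
        sets.append(FamilyPointSet(name, table.to_numpy(),
                                   ids=tuple(table.index)))
    return sets


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
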