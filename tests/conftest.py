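import numpy as np
import pytest

import motifenrich as me
from motifenrich.affinity import AffinityKind, MappedDataset, SignalKind


def make_mapped(x, y, affinity_kind=AffinityKind.AMA, signal_kind=SignalKind.RAW):
    """Small helper: wrap raw x/y arrays as a MappedDataset."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ids = [f"s{i}" for i in range(len(x))]
    return MappedDataset(ids, x, y, AffinityKind(affinity_kind), SignalKind(signal_kind))


@pytest.fixture(scope="session")
def planted_motif():
    return me.default_planted_motif()


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset (fast to map) shared across tests."""
    spec = me.SyntheticSpec(n_sequences=80, seq_length=120, n_positive=12, seed=7)
    records, truth = me.generate_dataset(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset at the default study conditions."""
    spec = me.SyntheticSpec(seed=11)
    records, truth = me.generate_dataset(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def small_library():
    return [me.default_planted_motif()] + me.generate_decoys(5, width=8, seed=3)
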