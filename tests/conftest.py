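import numpy as np
import pytest

from durumpanel import (
    GenotypeMatrix,
    MarkerMap,
    default_config,
    simulate_panel,
)


def make_matrix(calls, accession_ids=None, marker_ids=None):
    """GenotypeMatrix from a plain nested list (rows = accessions)."""
    calls = np.asarray(calls, dtype=np.int8)
    acc = accession_ids or [f"acc{i}" for i in range(calls.shape[0])]
    mk = marker_ids or [f"m{j}" for j in range(calls.shape[1])]
    return GenotypeMatrix(acc, mk, calls)


def make_map(marker_ids, chromosomes, positions):
    return MarkerMap(marker_ids, np.asarray(chromosomes, dtype=object),
                     np.asarray(positions, dtype=np.int64))


@pytest.fixture(scope="session")
def tiny_panel():
    """Two-population synthetic panel, 24 lines x 160 markers."""
    return simulate_panel(default_config("tiny", seed=11))


@pytest.fixture(scope="session")
def tiny_groups(tiny_panel):
    return tiny_panel.scheme().groups()
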