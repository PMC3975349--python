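import numpy as np
import pytest

from pseaac import classic_property_table, synth_proteins
from pseaac.io import ProteinRecord


@pytest.fixture(scope="session")
def classic_table():
    return classic_property_table()


@pytest.fixture(scope="session")
def classic_raw_props(classic_table):
    """Classic properties as letter->value dicts for the oracles."""
    from pseaac.alphabet import AMINO_ACIDS

    return {
        acc: dict(zip(AMINO_ACIDS, classic_table.raw(acc).tolist()))
        for acc in classic_table.ids()
    }


@pytest.fixture(scope="session")
def random_records():
    """100 seeded random proteins used by the fuzzed oracle comparisons."""
    return synth_proteins(seed=20240917, n=100, length_range=(35, 120))


@pytest.fixture
def rec10():
    return ProteinRecord(id="p1", seq="ACDEFGHIKL")


def make_record(seq: str, rec_id: str = "t") -> ProteinRecord:
    return ProteinRecord(id=rec_id, seq=seq)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
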