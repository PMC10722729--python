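import numpy as np
import pytest

from ppilink.embedding import CooccurrenceVocab, build_class_map
from ppilink.io_formats import EdgeRecord, ProteinRecord
from ppilink.synthetic_data import SyntheticConfig, gen_dataset


@pytest.fixture(scope="session")
def class_map():
    return build_class_map()


@pytest.fixture(scope="session")
def toy_vocab():
    """A small deterministic co-occurrence vocabulary (no training needed)."""
    rng = np.random.default_rng(11)
    letters = "ACDEFGHIKLMNPQRSTVWY"
    return CooccurrenceVocab(
        token_vectors={c: rng.normal(size=5) for c in letters},
        training_meta={"window": 1, "negatives": 5, "seed": 11},
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """12 proteins / 20 edges, noise-free, hub-skewed; fast enough for training tests."""
    cfg = SyntheticConfig(n_proteins=12, length_range=(20, 40), n_edges=20, seed=3)
    return gen_dataset(cfg)


@pytest.fixture
def simple_edges():
    return [
        EdgeRecord("a", "b", frozenset({"binding"})),
        EdgeRecord("b", "c", frozenset({"catalysis"})),
        EdgeRecord("c", "d", frozenset({"activation"})),
        EdgeRecord("d", "e", frozenset({"reaction"})),
    ]


def make_protein(pid: str, seq: str) -> ProteinRecord:
    return ProteinRecord(pid, seq)
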