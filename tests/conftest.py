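import numpy as np
import pytest

from slimfuse import io_formats as io
from slimfuse import synthetic as syn


@pytest.fixture(scope="session")
def small_dataset():
    """12 single-copy labeled sequences with full-strength planted motifs."""
    cfg = syn.SynthConfig(n_sequences=12, cluster_copies=1, seed=2)
    return syn.gen_proteins(cfg), cfg


@pytest.fixture(scope="session")
def small_table(small_dataset):
    """20-entry synthetic AAindex table with 2 complementary informative entries."""
    _, cfg = small_dataset
    table, informative = syn.gen_aaindex_fixture(20, 2, cfg)
    return table, informative


@pytest.fixture()
def toy_records():
    return [
        io.ProteinRecord("a", "MKVQ"),
        io.ProteinRecord("b", "AAAAA"),
    ]
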