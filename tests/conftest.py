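import numpy as np
import pytest

from metaboot import AbundanceTable, SampleMetadata


@pytest.fixture
def tiny_table():
    """3 features x 4 samples, two classes, no subclasses."""
    table = AbundanceTable(
        ["taxA", "taxB", "taxC"],
        ["s1", "s2", "s3", "s4"],
        np.array(
            [
                [2.0, 1.0, 0.0, 4.0],
                [3.0, 1.0, 5.0, 4.0],
                [5.0, 2.0, 5.0, 2.0],
            ]
        ),
    )
    metadata = SampleMetadata(
        ["s1", "s2", "s3", "s4"], ["A", "A", "B", "B"]
    )
    return table, metadata


@pytest.fixture
def random_table():
    """Deterministic 20-feature x 12-sample table with strata."""
    rng = np.random.default_rng(42)
    values = rng.gamma(2.0, 0.05, size=(20, 12))
    table = AbundanceTable(
        [f"f{i:02d}" for i in range(20)],
        [f"s{i:02d}" for i in range(12)],
        values,
        is_normalized=True,
    )
    metadata = SampleMetadata(
        table.sample_ids,
        ["A"] * 6 + ["B"] * 6,
        ["A1"] * 3 + ["A2"] * 3 + ["B1"] * 3 + ["B2"] * 3,
    )
    return table, metadata
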