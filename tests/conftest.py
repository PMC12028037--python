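import numpy as np
import pandas as pd
import pytest

from comstab.io_tables import FeatureTable, SampleMetadata


@pytest.fixture
def toy_counts() -> FeatureTable:
    """3 samples x 4 taxa count table with simple integer entries."""
    values = np.array([
        [4.0, 3.0, 2.0, 1.0],
        [1.0, 1.0, 1.0, 1.0],
        [0.0, 5.0, 0.0, 5.0],
    ])
    return FeatureTable(("s1", "s2", "s3"), ("ta", "tb", "tc", "td"), values)


@pytest.fixture
def toy_metadata() -> SampleMetadata:
    return SampleMetadata(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3"],
        "site": ["LZ", "LZ", "SK"],
        "soil_type": ["clay_loam", "clay_loam", "sandy"],
        "latitude": [21.5, 21.6, 19.9],
        "longitude": [109.7, 109.8, 110.5],
    }))


def metadata_of(n: int, site: str = "X") -> SampleMetadata:
    """Minimal n-sample metadata for generators that only need sample ids."""
    return SampleMetadata(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "site": site, "soil_type": "any",
        "latitude": 0.0, "longitude": 0.0,
    }))
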