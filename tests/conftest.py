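import sys
from pathlib import Path

import numpy as np
import pytest

# make the oracle helpers importable as a plain module
sys.path.insert(0, str(Path(__file__).parent))

from edakit.types import Feature, FeatureTable, Polarity, SampleRole


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_table(rows, sample_id="s", role=SampleRole.EXTRACT, ref=1.0,
               polarity=Polarity.POSITIVE):
    """Build a FeatureTable from (mz, rt, intensity) triples."""
    return FeatureTable(
        sample_id, role, ref,
        [Feature(mz=m, rt=r, intensity=i, polarity=polarity) for m, r, i in rows],
    )


@pytest.fixture
def random_table_pair(rng):
    """Two tables with 30 shared features, jittered within tolerance."""
    mz = 150.0 + 0.5 * np.arange(30)
    rt = rng.uniform(1, 20, 30)
    inten = rng.uniform(100, 1e4, 30)
    a = make_table(list(zip(mz, rt, inten)))
    b = make_table(
        list(zip(mz + rng.normal(0, 0.002, 30), rt + rng.normal(0, 0.02, 30), inten))
    )
    return a, b
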