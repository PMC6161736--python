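import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from ampliedit.reference import (  # noqa: E402
    BarcodePair,
    SampleMeta,
    SampleSheet,
    flnb_synthetic_reference,
)


@pytest.fixture(scope="session")
def flnb_ref():
    return flnb_synthetic_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(20180731)


@pytest.fixture(scope="session")
def small_sheet():
    return SampleSheet(
        [
            (SampleMeta("s1", "cortex", "P120", 1), BarcodePair("AAAAAAAA", "CCCCCCCC")),
            (SampleMeta("s2", "cortex", "P120", 2), BarcodePair("GGGGGGGG", "TTTTTTTT")),
            (SampleMeta("s3", "femur", "P120", 1), BarcodePair("ACGTACGT", "TGCATGCA")),
        ]
    )
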