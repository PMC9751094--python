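import numpy as np
import pytest

from plastomarker.families import handcount_alignment, micro_family
from plastomarker.pipeline import analyze_family


@pytest.fixture(scope="session")
def micro():
    return micro_family(3)


@pytest.fixture(scope="session")
def micro_analysis(micro):
    return analyze_family(
        micro.sequences, micro.alignment, region_columns=micro.truth.region_columns
    )


@pytest.fixture(scope="session")
def handcount():
    return handcount_alignment()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
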