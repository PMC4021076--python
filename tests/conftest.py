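import numpy as np
import pytest

from pedpower.markers import ErrorModel, LocusModel, MarkerPanel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def biallelic():
    return LocusModel("bi", ("A", "B"), np.array([0.5, 0.5]))


@pytest.fixture
def skewed_biallelic():
    return LocusModel("sk", ("A", "B"), np.array([0.9, 0.1]))


@pytest.fixture
def small_panel():
    """Three loci of 2-4 alleles with assorted frequency shapes."""
    return MarkerPanel([
        LocusModel("L1", ("A", "B"), np.array([0.6, 0.4])),
        LocusModel("L2", ("A", "B", "C"), np.array([0.5, 0.3, 0.2])),
        LocusModel("L3", ("A", "B", "C", "D"), np.array([0.4, 0.3, 0.2, 0.1])),
    ])


@pytest.fixture
def no_error():
    return ErrorModel(0.0, 0.0, 0.0)


@pytest.fixture
def study_error():
    """Error rates of the archival-scale genotyping study."""
    return ErrorModel(e1=0.02, e2=0.004, missing_rate=0.11)
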