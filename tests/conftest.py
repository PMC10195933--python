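import numpy as np
import pytest

from mammoqa import phantom


@pytest.fixture(scope="session")
def mlo_phantom():
    """One deterministic MLO phantom with all features present."""
    return phantom.generate_phantom(phantom.PhantomParams(seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """A small mixed phantom dataset reused across tests."""
    data, manifest = phantom.generate_dataset(24, seed=5, view="both")
    return data, manifest


@pytest.fixture(scope="session")
def exam_ideal():
    return phantom.generate_exam(phantom.ExamParams(seed=4))
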