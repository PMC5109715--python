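import numpy as np
import pytest

from chromclass import ClassRegistry, TFRecord
from chromclass.simulate import generate_tf_table, reference_config


@pytest.fixture
def small_registry():
    """A two-superclass registry small enough for exhaustive pair checks."""
    return ClassRegistry(
        superclasses=("1", "2"),
        classes=("1.1", "1.2", "2.1", "2.2", "2.3"),
    )


@pytest.fixture
def tiny_records():
    """A handful of hand-written annotation records."""
    return [
        TFRecord("TFA", "1.1", {"KRAB": 1, "zf-C2H2": 4}, True, 4, True, 12,
                 (True, False, False, False, False, False), 20, 4, "P"),
        TFRecord("TFB", "1.2", {"HLH": 1}, True, 1, True, 3,
                 (True, True, False, True, False, False), 5, 0, "S"),
        TFRecord("TFC", "2.1", {"Hormone_recep": 1, "zf-C4": 2}, True, 2, True, 20,
                 (True, False, True, False, False, False), 30, 0, "M+"),
        TFRecord("TFD", "2.3.1", {"Homeobox": 1}, True, 1, False, 0,
                 (False,) * 6, 0, 1, "M-"),
        TFRecord("TFE", "2.2", {}, False, 0, True, 2,
                 (False,) * 6, 0, 0),
    ]


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (457 TFs), shared across tests."""
    config = reference_config(seed=11)
    records, truth = generate_tf_table(config)
    return config, records, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
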