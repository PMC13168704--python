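import numpy as np
import pytest

from beadtask.likelihood import StackedData
from beadtask.simulate import default_group_level, make_cohort


@pytest.fixture(scope="session")
def nt_cohort():
    """Small neurotypical-like cohort shared across tests."""
    return make_cohort(default_group_level("NT"), 5, seed=101, group="NT")


@pytest.fixture(scope="session")
def nt_stacked(nt_cohort):
    return StackedData.from_frame(nt_cohort.data)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_params(model, rng, scale=0.4):
    """Random constrained parameter set valid for ``model``."""
    out = {}
    for name in model.param_names:
        if name == "alpha_decay" or name.startswith("p_sec"):
            out[name] = float(rng.uniform(0.05, 0.95))
        else:
            out[name] = float(rng.normal(0, scale))
    return out
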