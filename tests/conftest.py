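import numpy as np
import pytest

from replaceseq.design import example_design
from replaceseq.simulate import OutcomeMixture


@pytest.fixture(scope="session")
def design():
    """The directional reporter-style fixture design used across the suite."""
    return example_design(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def demo_mixture():
    """A realistic outcome mixture: correct replacement the modal outcome."""
    return OutcomeMixture(
        weights={
            "original": 0.16,
            "deletion": 0.26,
            "replacement_fwd": 0.39,
            "replacement_rev": 0.08,
            "insertion_up_fwd": 0.07,
            "insertion_up_rev": 0.04,
        }
    )
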