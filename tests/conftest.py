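import numpy as np
import pytest

from postprandial import (
    TrajectoryProfile,
    make_design,
    simulate_panel,
)


@pytest.fixture
def design():
    """The default 18M/16F cohort on the 14-point sampling grid."""
    return make_design()


@pytest.fixture
def rng():
    return np.random.default_rng(20240314)


@pytest.fixture
def flat_profile():
    return TrajectoryProfile(
        metabolite="marker",
        baseline_gmean=10.0,
        shape="flat",
        sigma_subject=0.30,
        sigma_time=0.05,
        sigma_residual=0.20,
    )


@pytest.fixture
def noisy_panel(design, flat_profile, rng):
    return simulate_panel(flat_profile, design, rng)
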