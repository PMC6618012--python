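"""Shared fixtures: a reduced-mesh synthetic study with known truth.

The session-scoped noiseless dataset is the common substrate for the
estimator round-trip tests; it is generated once by the forward model
at the standard four measurement designs.
"""

import pytest

from leafrd import ForwardRunner, KineticParams, LeafAnatomy, SynthTruth, synth_gas_exchange

#: reduced mesh used throughout the test suite (keeps runtimes modest;
#: solver accuracy at this resolution is verified in the solver tests)
RESOLUTION = (10, 28)


@pytest.fixture(scope="session")
def reduced_resolution():
    return RESOLUTION


@pytest.fixture(scope="session")
def truth():
    return SynthTruth(seed=7, noise_an=0.0, noise_phi2=0.0, resolution=RESOLUTION)


@pytest.fixture(scope="session")
def noiseless_table(truth):
    return synth_gas_exchange(truth, "all")


@pytest.fixture(scope="session")
def true_kinetics(truth):
    """Kinetics at the generator's true values (PR-regime Rd)."""
    return KineticParams(
        vcmax=truth.vcmax, rd=truth.rd_pr, tp=truth.tp, s_cal=truth.s_cal
    )


@pytest.fixture(scope="session")
def runner_inner(truth):
    return ForwardRunner(truth.anatomy, "inner", truth.transport, RESOLUTION)


@pytest.fixture(scope="session")
def runners(truth):
    return {
        scen: ForwardRunner(truth.anatomy, scen, truth.transport, RESOLUTION)
        for scen in ("inner", "gaps", "outer")
    }


@pytest.fixture()
def anatomy():
    return LeafAnatomy()
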