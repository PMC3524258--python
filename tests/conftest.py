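"""Shared fixtures: networks and simulation caches reused across the suite.

The hapten-inhibition time courses and the α-grid model curves are the
expensive objects (a stiff ~750-species ODE integration each), so they are
computed once per session and shared by the experiment, synthetic-data and
acceptance tests.
"""

import numpy as np
import pytest

from raftsignal import (
    ExperimentProtocol,
    ParameterSet,
    build_model,
    generate_network,
    hapten_inhibition,
)
from raftsignal.synthetic import DEFAULT_TIMEPOINTS, _model_curves


@pytest.fixture(scope="session")
def defaults() -> ParameterSet:
    return ParameterSet.defaults()


@pytest.fixture(scope="session")
def stim_network(defaults):
    """Stimulation-phase network (bivalent ligand, no hapten)."""
    return generate_network(build_model(defaults), include_hapten=False)


@pytest.fixture(scope="session")
def full_network(defaults):
    """Hapten-extended network used for the inhibition experiments."""
    return generate_network(build_model(defaults))


@pytest.fixture(scope="session")
def toy_network(defaults):
    """Bivalent ligand + receptor only (no kinases, no states)."""
    return generate_network(
        build_model(defaults), include_hapten=False, molecules={"Lig", "Rec"}
    )


@pytest.fixture(scope="session")
def dephos_curves_fast_syk(defaults):
    """Hapten-inhibition curves at the reduced receptor-Syk lifetime
    (off-rate 0.2/s), the parameterization of the lifetime analyses.

    α = 0 uses a longer grid because absolute protection stretches the LAT
    decay far beyond two minutes.
    """
    params = defaults.replace(syk_off_rate=0.2)
    short = ExperimentProtocol(t_grid=np.arange(0.0, 121.0))
    long = ExperimentProtocol(
        t_grid=np.concatenate([np.arange(0.0, 121.0),
                               np.arange(125.0, 601.0, 5.0)])
    )
    out = hapten_inhibition(short, (0.1, 0.2, 0.5, 1.0), params)
    out.update(hapten_inhibition(long, (0.0,), params))
    return out


@pytest.fixture(scope="session")
def alpha_grid_curves(defaults):
    """Noise-free normalized model curves on the standard sampling times for
    the α fitting grid, at canonical parameters."""
    grid = (0.0, 0.05, 0.1, 0.2, 0.5, 1.0)
    proto = ExperimentProtocol()
    return {
        a: _model_curves(a, DEFAULT_TIMEPOINTS, defaults,
                         ("fceri", "lat"), proto)
        for a in grid
    }
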