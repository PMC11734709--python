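import warnings

import numpy as np
import pytest

from scatterkin import (
    CollinearityWarning,
    FitConfig,
    KineticGlobalFit,
    ScenarioConfig,
    default_dt_network,
    generate_map,
)


@pytest.fixture(scope="session")
def qgrid():
    return np.linspace(0.5, 4.5, 60)


@pytest.fixture(scope="session")
def network():
    return default_dt_network()


@pytest.fixture(scope="session")
def noiseless_case(network):
    """Noiseless synthetic map plus ground truth under nominal conditions."""
    cfg = ScenarioConfig(network=network, noise=0.0, seed=11)
    data, truth = generate_map(cfg)
    return data, truth


@pytest.fixture(scope="session")
def noiseless_fit(network, noiseless_case):
    """Multi-start fit of the noiseless map (shared: it is the slow part)."""
    data, truth = noiseless_case
    theory = {g: truth.patterns[m[0]] for g, m in network.groups().items()}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", CollinearityWarning)
        est = KineticGlobalFit(
            network=network, irf=truth.irf,
            config=FitConfig(n_restarts=6, seed=5),
            theory_patterns=theory,
        ).fit(data)
    return est
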