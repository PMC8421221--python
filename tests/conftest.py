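import warnings

import numpy as np
import pytest

from ndfs import (
    AngularDistribution,
    DeviceVariantModel,
    GaussianChainSpec,
    ThermalScale,
    WLCSpec,
    estimate_density,
    generate_angle_ensemble,
)


@pytest.fixture(scope="session")
def wlc_249bp():
    """The 249 bp / 85 nm dsDNA test sample."""
    return WLCSpec(Lc=85.0, lp=50.0)


@pytest.fixture(scope="session")
def thermal():
    return ThermalScale(4.114)


@pytest.fixture(scope="session")
def linker():
    """Default flexible linkage: 4 Kuhn segments of 1.5 nm (RMS EED 3 nm)."""
    return GaussianChainSpec(n=4.0, b=1.5)


@pytest.fixture(scope="session")
def ndfs_b_density():
    """Angular density of a synthetic open-biased (nDFS.B-like) ensemble."""
    ens = generate_angle_ensemble(DeviceVariantModel.preset("nDFS.B"), N=500, seed=1)
    return estimate_density(ens)


@pytest.fixture(scope="session")
def ndfs_c35_density():
    """Angular density of a synthetic closed-biased (nDFS.C-35-like) ensemble."""
    ens = generate_angle_ensemble(DeviceVariantModel.preset("nDFS.C-35"), N=500, seed=3)
    return estimate_density(ens)


@pytest.fixture(scope="session")
def flat_prior():
    """Uniform angular prior over 20-120 degrees in 5-degree bins."""
    edges = np.arange(20.0, 125.0, 5.0)
    return AngularDistribution(edges, np.full(edges.size - 1, 1.0 / 100.0))


@pytest.fixture(autouse=True)
def _no_convergence_warnings():
    """Small hand-built ensembles trip the N<150 convergence warning; hide it."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="ensemble size")
        yield
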