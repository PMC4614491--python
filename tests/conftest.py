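import numpy as np
import pytest

from ventnet import (
    FluidParams,
    VentilatorProtocol,
    build_network,
    simulate,
)


@pytest.fixture(scope="session")
def fluid():
    return FluidParams()


@pytest.fixture(scope="session")
def baseline_results():
    """Baseline inflations (C=0.1, d=0.2, V_T=10 ml/kg) for a fixed seed list."""
    out = []
    for seed in range(8):
        net = build_network(0.2, 0.1, seed)
        out.append((net, simulate(net)))
    return out


@pytest.fixture(scope="session")
def modest_collapse_results():
    """C=0.5, d=0.2 inflations: distinct-avalanche regime."""
    out = []
    for seed in range(6):
        net = build_network(0.2, 0.5, seed)
        out.append((net, simulate(net)))
    return out


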