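"""Shared fixtures.

The heavy objects (calibrated neurons, settled limit cycles, the full
validation run) are session-scoped so the expensive ODE work happens
once; unit tests that only need algebraic objects use the cheap
fixtures.
"""

from __future__ import annotations

import numpy as np
import pytest

from prcnet.config import NetworkSpec, calibrate_network
from prcnet.model import MLNeuronParams, limit_cycle
from prcnet.pipeline import run_validation


@pytest.fixture(scope="session")
def type1_params() -> MLNeuronParams:
    return MLNeuronParams()


@pytest.fixture(scope="session")
def network():
    """Calibrated three-neuron network: periods 60/70/80, the loop
    couplings g12=0.015, g32=0.002, g23=0.0275."""
    return calibrate_network(NetworkSpec())


@pytest.fixture(scope="session")
def validation(network):
    """The full open-loop vs closed-loop validation, run once, with a
    fixed seed for the closed-loop initial phases."""
    return run_validation(seed=1, network=network)


@pytest.fixture(scope="session")
def limit_cycles(network):
    return {
        1: limit_cycle(network.neuron1, period_hint=network.P1i),
        2: limit_cycle(network.neuron2, period_hint=network.P2i),
        3: limit_cycle(network.neuron3, period_hint=network.P3i),
    }


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20230917)
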