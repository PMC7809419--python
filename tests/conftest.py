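"""Shared fixtures: toy networks and plants, and session-scoped CCM
artifacts reused by the heavier end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest

from triscale.ccm import build_ccm_network, nominal_inputs
from triscale.kinetics import StateVectors
from triscale.network import build_toy_network
from triscale.plant import Plant, PlantConfig


@pytest.fixture(scope="session")
def toy_spec():
    return build_toy_network(2, 2, 3, 1, seed=3)


@pytest.fixture(scope="session")
def toy_plant(toy_spec):
    return Plant(PlantConfig(spec=toy_spec))


@pytest.fixture(scope="session")
def ccm_spec():
    return build_ccm_network()


@pytest.fixture(scope="session")
def ccm_plant(ccm_spec):
    return Plant(PlantConfig(spec=ccm_spec, u_default=nominal_inputs(ccm_spec)))


@pytest.fixture(scope="session")
def ccm_init(ccm_spec):
    return StateVectors(
        np.full(ccm_spec.p, 0.5),
        np.full(ccm_spec.s, 0.4),
        np.full(ccm_spec.m, 0.4),
        nominal_inputs(ccm_spec),
    )
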