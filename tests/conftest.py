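"""Shared fixtures: reference kinetics, protocols, and simulated recordings."""

from __future__ import annotations

import numpy as np
import pytest

from cardiotwitch.fixtures import baseline_kinetics
from cardiotwitch.synthgen import (
    DrugEffectProfile,
    PacingProtocol,
    PopulationModel,
    simulate_cell,
)


@pytest.fixture(scope="session")
def table_kinetics():
    """The population-mean twitch: 1.78 µm, 4.31%, TPeak 168 ms, TR90 337 ms."""
    return baseline_kinetics()


@pytest.fixture(scope="session")
def short_protocol():
    """A 16-beat vehicle recording at 1 Hz / 240 Hz (enough for a 15-beat average)."""
    return PacingProtocol(vehicle_duration=16.0, period_duration=16.0)


@pytest.fixture()
def quiet_population():
    return PopulationModel(noise_sd=0.005, seed=0)


@pytest.fixture()
def vehicle_cell(table_kinetics, short_protocol, quiet_population):
    """One noisy vehicle-only recording of the reference twitch."""
    rng = np.random.default_rng(42)
    return simulate_cell(
        table_kinetics,
        DrugEffectProfile.null(),
        short_protocol,
        quiet_population,
        [],
        rng=rng,
    )
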