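import numpy as np
import pandas as pd
import pytest

from riverindic import (
    PlantedSignal,
    RiverDesign,
    default_signal,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_design():
    return RiverDesign(n_stations=15)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    """15 stations x 3 transects, 40 background taxa: fast, full structure."""
    signal = PlantedSignal(
        true_lag=(1, 0),
        switch_fractions=((0.3, 0.7, 0.9), (0.15, 0.5, 0.87)),
        n_coupled_taxa=10,
    )
    return simulate_dataset(small_design, signal, n_noise_taxa=40,
                            library_size=20_000, seed=11)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 60 stations x 3 transects, 200 noise
    taxa, two planted indicator groups with clones, zero response noise."""
    return simulate_dataset(seed=7)


@pytest.fixture(scope="session")
def default_sig():
    return default_signal()
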