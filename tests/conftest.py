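import numpy as np
import pytest

from opaflim import (
    SimulationSpec,
    default_donor_pattern,
    default_grid,
    simulate_histogram,
)


@pytest.fixture(scope="session")
def pattern():
    return default_donor_pattern()


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def donor_hist():
    """One donor-only histogram at high photon count."""
    return simulate_histogram(
        SimulationSpec(binding=0.0, efficiency=0.0, n_photons=1_000_000, seed=42)
    )


@pytest.fixture(scope="session")
def fret_hist():
    """One FRET histogram (B=0.3, E=0.4) at high photon count."""
    return simulate_histogram(
        SimulationSpec(binding=0.3, efficiency=0.4, n_photons=1_000_000, seed=43)
    )


@pytest.fixture(scope="session")
def donor_fit_pairs(pattern):
    """Paired (OPA, mono-donor) BINDING estimates on 15 donor-only replicates."""
    from opaflim import fit_mono_donor, fit_opa

    opa, mono = [], []
    for seed in range(15):
        h = simulate_histogram(
            SimulationSpec(binding=0.0, efficiency=0.0, n_photons=500_000, seed=seed)
        )
        opa.append(fit_opa(h, pattern).binding_hat)
        mono.append(fit_mono_donor(h, pattern).binding_hat)
    return np.array(opa), np.array(mono)
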