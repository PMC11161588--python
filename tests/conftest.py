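"""Shared fixtures. Problem sizes are scaled down from the study design so
the whole suite runs on one CPU within the time budget; the acceptance tests
document their own sizes."""
import numpy as np
import pytest

from attnspot import synthgen
from attnspot.core import DesignSpec


@pytest.fixture(scope="session")
def small_design():
    """Two runs per condition, four cycles: 96 TR per run."""
    return DesignSpec(n_runs_per_condition=2, n_cycles=4)


@pytest.fixture(scope="session")
def geometry150():
    return synthgen.make_geometry(150, seed=0)


@pytest.fixture(scope="session")
def weak_subject(small_design, geometry150):
    """One noisy weak-crowding subject on the small design."""
    ds, truth = synthgen.simulate_subject(
        geometry150,
        small_design,
        synthgen.SCENARIO_PROFILES["weak_crowding"],
        snr=1.0,
        seed=123,
    )
    return ds, truth


@pytest.fixture(scope="session")
def noisefree_subject(small_design, geometry150):
    """Noise-free, nuisance-free subject: BOLD = evoked + latent background."""
    ds, truth = synthgen.simulate_subject(
        geometry150,
        small_design,
        synthgen.SCENARIO_PROFILES["weak_crowding"],
        snr=np.inf,
        seed=321,
        nuisance_weight_sd=0.0,
    )
    return ds, truth
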