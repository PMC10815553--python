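import numpy as np
import pytest

from actnet.synthetic_data import (
    GeometrySpec,
    PIEDASpec,
    make_pieda_tables,
    make_toy_gpcr,
)


@pytest.fixture(scope="session")
def toy_active():
    """Jitter-free active-state toy receptor: descriptors exactly on target."""
    return make_toy_gpcr(GeometrySpec(state="active", jitter_sd=0.0, n_frames=5))


@pytest.fixture(scope="session")
def toy_inactive_md():
    """Inactive-state toy receptor with jitter and a planted pathway,
    shaped like a 100-ns run sampled every 1 ns."""
    return make_toy_gpcr(
        GeometrySpec(
            state="inactive",
            jitter_sd=0.1,
            n_frames=100,
            frame_interval=1.0,
            plant_pathway=True,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def bw_map(toy_active):
    return toy_active[1]


@pytest.fixture(scope="session")
def pieda_tables():
    """7 agonist + 10 antagonist synthetic PIEDA tables (study shape)."""
    return make_pieda_tables(PIEDASpec(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
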