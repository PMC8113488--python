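import numpy as np
import pytest

from smlmdecorr import (
    FieldOfView,
    LocalizationTable,
    SimConfig,
    make_phantom,
    simulate_localizations,
)

# Frozen study conditions for the simulation-based end-to-end checks:
# a 3x3 µm field holding a dense filament network (~126 µm of structure,
# ~30% area coverage, cytoskeleton-like), one emitter per 5 nm of structure,
# 20 localizations per emitter on average, 6 nm localization precision.
FOV_NM = 3000.0
PHANTOM_KW = {"count": 14, "length": 9000.0}
EMITTER_DENSITY = 0.2
LOCS_PER_EMITTER = 20.0
SIGMA_LOC = 6.0


@pytest.fixture(scope="session")
def fov() -> FieldOfView:
    return FieldOfView(0.0, 0.0, FOV_NM, FOV_NM)


def simulated_filaments(fov, seed: int, sigma_loc: float = SIGMA_LOC,
                        emitter_density: float = EMITTER_DENSITY):
    phantom = make_phantom("filaments", PHANTOM_KW, fov, seed=seed)
    config = SimConfig(
        fov=fov,
        emitter_linear_density=emitter_density,
        mean_locs_per_emitter=LOCS_PER_EMITTER,
        sigma_loc=sigma_loc,
        seed=seed + 1000,
    )
    return simulate_localizations(phantom, config)


@pytest.fixture(scope="session")
def dense_table(fov):
    """One dense σ_loc = 6 nm filament dataset shared across tests."""
    return simulated_filaments(fov, seed=1)


@pytest.fixture
def tiny_table() -> LocalizationTable:
    """The three-localization example table (positions in nm, pixel-size-1
    grid units)."""
    return LocalizationTable(
        x=np.array([2.3, 5.2, 4.2]),
        y=np.array([1.8, 1.5, 5.2]),
    )
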