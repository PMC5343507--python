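import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import timscan as ts
from timscan.alphabet import AA20
from timscan.fitness import LANDSCAPE_COLUMNS, FitnessLandscape

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_landscape(
    s_matrix: np.ndarray,
    wt_aa: list[str] | None = None,
    orthologue: str = "X",
    positions_per_library: int = 10,
    rng: np.random.Generator | None = None,
) -> FitnessLandscape:
    """Build a landscape from an (n_positions, 20) matrix of s values."""
    s_matrix = np.asarray(s_matrix, dtype=float)
    n_pos = s_matrix.shape[0]
    aa = np.array(list(AA20))
    if wt_aa is None:
        rng = rng or np.random.default_rng(0)
        wt_aa = aa[rng.choice(20, size=n_pos)]
    table = pd.DataFrame(
        {
            "orthologue": orthologue,
            "library": np.repeat(np.arange(n_pos) // positions_per_library + 1, 20),
            "position": np.repeat(np.arange(1, n_pos + 1), 20),
            "wt_aa": np.repeat(np.asarray(wt_aa), 20),
            "outcome": np.tile(list(AA20), n_pos),
            "w": s_matrix.ravel(),
            "s": s_matrix.ravel(),
            "flags": "",
        },
        columns=LANDSCAPE_COLUMNS,
    )
    return FitnessLandscape(table=table)


@pytest.fixture(scope="session")
def small_design():
    """One 10-position library with barcodes for 4 time points."""
    return ts.random_design(
        n_libraries=1, positions_per_library=10, seed=7, timepoints=(0.0, 1.0, 2.0, 3.0)
    )


@pytest.fixture(scope="session")
def small_counts(small_design):
    cfg = ts.SimulationConfig(
        design=small_design,
        depth_per_timepoint=2000,
        timepoints=(0.0, 1.0, 2.0, 3.0),
        seed=11,
    )
    return ts.simulate_growth_counts(cfg)


@pytest.fixture(scope="session")
def trio_rho_half():
    cfg = ts.LandscapeTrioConfig(n_positions=80, rho=0.5, seed=21)
    return ts.simulate_landscape_trio(cfg)
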