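"""Shared fixtures: seeded RNGs and reusable simulation runs.

The expensive Monte Carlo runs are session-scoped so the suite pays for
each of them once.
"""

import numpy as np
import pytest

import pptsim
from pptsim.transport import TransportConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def water10_grid():
    return pptsim.build_cube(100.0, "water", "point")


@pytest.fixture(scope="session")
def budget_log():
    """1 cm water cube, central point source, 1e6 primaries."""
    grid = pptsim.build_cube(10.0, "water", "point")
    cfg = TransportConfig(track_secondaries=False)
    return pptsim.run_simulation(grid, 1_000_000, cfg, seed=101)


@pytest.fixture(scope="session")
def water10_log(water10_grid):
    """10 cm water cube, 1e6 primaries, full chain."""
    return pptsim.run_simulation(water10_grid, 1_000_000, seed=202)


@pytest.fixture(scope="session")
def positron_sample(water10_grid):
    """1e5 positrons from the 2.617 MeV pair spectrum, stopped in water."""
    rng = np.random.default_rng(303)
    t_plus, _ = pptsim.sample_pair_energies(2.617, rng, 100_000)
    r_p = np.zeros((len(t_plus), 3))
    r_a, _, escaped = pptsim.transport_positron(t_plus, r_p, water10_grid, rng)
    return t_plus, np.linalg.norm(r_a - r_p, axis=1), escaped


@pytest.fixture(scope="session")
def profile_run(water10_grid):
    """Five full-statistics (1e8) water-cube replicates.

    Each replicate matches the published study's primary count; the
    profile FWHMs are taken as the median over replicates because the
    Lorentzian/background decomposition is nearly degenerate and single
    fits scatter (see docs/methods.md).
    """
    rng = np.random.default_rng(404)
    replicates = []
    for _ in range(5):
        pair_pos, ann_pos = [], []
        for _ in range(10):
            log = pptsim.run_simulation(water10_grid, 10_000_000, seed=rng)
            pair_pos.append(log.pair_r_p)
            ann_pos.append(log.ann_r_a)
        replicates.append((np.concatenate(pair_pos), np.concatenate(ann_pos)))
    return replicates


@pytest.fixture(scope="session")
def material_logs():
    """20 cm homogeneous cubes, central point source, 5e6 primaries each."""
    logs = {}
    rng = np.random.default_rng(505)
    for mat in ("water", "adipose", "lung", "bone"):
        grid = pptsim.build_cube(200.0, mat, "point")
        logs[mat] = pptsim.run_simulation(grid, 5_000_000, seed=rng)
    return logs
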