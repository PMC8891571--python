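"""Shared fixtures: the Boolean network, small lattices, and the scaled
simulation batches that several integration tests analyse.

The scaled batches compress the Monte Carlo clock (1 MCS = 1 h instead of
1 min) so that multi-week tumor courses fit in CI; every run is seeded and
bitwise reproducible.
"""

import numpy as np
import pytest

from tumorcpm import boolean_network as bn
from tumorcpm import lattice as lat
from tumorcpm import make_fixture, run_simulation
from tumorcpm.lattice import AdhesionMatrix, CellLattice
from tumorcpm.simulate import SimulationParams
from tumorcpm.therapy import TherapyProtocol

SPHEROID_SEEDS = (1, 2, 3, 4, 5)
DOSE_ARMS = (5.0, 7.5, 10.0)
THERAPY_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def net():
    return bn.load_rules()


@pytest.fixture(scope="session")
def pheno_map(net):
    return bn.input_output_map(net)


def scaled_params(**overrides) -> SimulationParams:
    """Reference parameters on the compressed clock (1 MCS = 1 hour)."""
    return SimulationParams(minutes_per_mcs=60.0, **overrides)


@pytest.fixture()
def toy_lattice():
    """6^3 lattice with two 8-voxel cells (deterministic)."""
    latt = CellLattice((6, 6, 6))
    cube = np.argwhere(np.ones((2, 2, 2), bool))
    latt.add_cell(cube + np.array([1, 2, 2]), lat.TP, target_volume=8,
                  initial_volume=8)
    latt.add_cell(cube + np.array([3, 2, 2]), lat.TP, target_volume=8,
                  initial_volume=8)
    return latt


def random_multicell_lattice(rng, dims=(8, 8, 8), n_cells=4):
    """Random connected cells on a small lattice, for energy oracles."""
    latt = CellLattice(dims)
    for _ in range(n_cells):
        # grow a random blob by seeded dilation
        seed_vox = rng.integers(1, np.array(dims) - 1)
        blob = {tuple(seed_vox)}
        while len(blob) < 6:
            x, y, z = list(blob)[rng.integers(len(blob))]
            step = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                    (0, 0, 1), (0, 0, -1)][rng.integers(6)]
            p = (x + step[0], y + step[1], z + step[2])
            if all(0 <= v < d for v, d in zip(p, dims)):
                blob.add(p)
        vox = np.array([v for v in blob
                        if latt.site_owner[v] == 0])
        if len(vox) == 0:
            continue
        latt.add_cell(vox, int(rng.choice([lat.TP, lat.TQ, lat.TM, lat.EC])),
                      target_volume=float(rng.integers(4, 12)),
                      initial_volume=max(len(vox), 1))
    return latt


# ---------------------------------------------------------------------------
# heavy shared batches (session scope; computed once, reused by several tests)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def spheroid_batch():
    """Avascular spheroid runs: 5 seeds x 22 simulated days (scaled clock)."""
    traces = {}
    for seed in SPHEROID_SEEDS:
        sc = make_fixture("spheroid50", seed=seed)
        traces[seed] = run_simulation(sc, None, days=22.0, seed=seed,
                                      params=scaled_params())
    return traces


@pytest.fixture(scope="session")
def dose_batch():
    """Chemotherapy dose arms on the vascular fixture: 3 doses x 5 seeds."""
    out = {}
    for dose in DOSE_ARMS:
        runs = []
        for seed in THERAPY_SEEDS:
            prot = TherapyProtocol(kind="chemo", dose=dose, cycle_days=5.0,
                                   n_cycles=3, start_day=3.0)
            sc = make_fixture("vascular28", seed=seed)
            runs.append(run_simulation(sc, prot, days=20.0, seed=seed,
                                       params=scaled_params()))
        out[dose] = runs
    return out


@pytest.fixture(scope="session")
def late_start_batch():
    """Dose-10 arm started 5 days later, same seeds as dose_batch."""
    runs = []
    for seed in THERAPY_SEEDS:
        prot = TherapyProtocol(kind="chemo", dose=10.0, cycle_days=5.0,
                               n_cycles=3, start_day=8.0)
        sc = make_fixture("vascular28", seed=seed)
        runs.append(run_simulation(sc, prot, days=20.0, seed=seed,
                                   params=scaled_params()))
    return runs
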