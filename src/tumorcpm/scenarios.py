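"""Synthetic initial conditions: tumor spheroids, vessel plexuses, fixtures.

The reference setup is a ~65 um diameter tumor of proliferating cells at the
centre of a 150 x 150 x 200 lattice (4 um voxels), surrounded by a regular
plexus of pre-existing straight vessels.  Scaled-down variants of the same
construction serve as deterministic test fixtures.  Scenario generation is a
pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from . import lattice as lat
from .lattice import CellLattice

__all__ = ["ScenarioConfig", "Scenario", "build_initial_tumor",
           "build_vessel_plexus", "build_scenario", "make_fixture",
           "FIXTURES"]


@dataclass
class ScenarioConfig:
    """Geometry of the initial condition.

    ``dispersed_seeding`` places the initial cells as separate 64-voxel
    cells with small gaps inside the tumor sphere (emulating dissociated
    cells that must first aggregate into a spheroid, as in culture assays);
    compact seeding tiles the sphere with a Voronoi partition.
    """

    dims: tuple[int, int, int] = (150, 150, 200)
    voxel_size: float = 4.0            # um
    tumor_diameter: float = 65.0       # um
    dispersed_seeding: bool = False
    vessels: bool = True
    vessel_spacing: float = 200.0      # um between vessel axes
    vessel_radius: int = 2             # voxels
    vessel_margin: float = 40.0        # um: keep-out around the tumor sphere
    ec_segment_length: int = 5         # voxels of vessel axis per EC cell
    nutrient_boundary: str = "auto"    # auto | vessels | faces | culture
    seed: int = 0

    def __post_init__(self):
        r_vox = self.tumor_diameter / (2 * self.voxel_size)
        if self.tumor_diameter > 0 and 4.0 / 3.0 * np.pi * r_vox**3 < lat.INITIAL_CELL_VOLUME:
            raise ValueError("tumor diameter below a single-cell volume")
        if min(self.dims) * self.voxel_size <= self.tumor_diameter:
            raise ValueError("tumor does not fit inside the domain with margin")
        if self.vessels and self.vessel_spacing <= 2 * self.vessel_radius * self.voxel_size:
            raise ValueError("vessel spacing below the vessel diameter")

    @property
    def boundary_mode(self) -> str:
        if self.nutrient_boundary != "auto":
            return self.nutrient_boundary
        return "vessels" if self.vessels else "faces"


@dataclass
class Scenario:
    """A generated initial condition plus its provenance."""

    lattice: CellLattice
    config: ScenarioConfig
    name: str = "custom"

    @property
    def boundary_mode(self) -> str:
        return self.config.boundary_mode


def _sphere_mask(dims, centre, radius_vox) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, d) for d in dims)]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, centre))
    return r2 <= radius_vox**2


def build_initial_tumor(config: ScenarioConfig,
                        lattice: CellLattice | None = None,
                        rng: np.random.Generator | None = None) -> CellLattice:
    """Create the centred tumor of ~64-voxel proliferating cells.

    Compact mode tiles the sphere with a seeded Voronoi partition whose seed
    count targets 64 voxels per cell; dispersed mode drops whole 64-voxel
    spherical cells at jittered positions inside the tumor sphere, leaving
    ECM gaps for the aggregation phase.
    """
    if config.tumor_diameter <= 0:
        raise ValueError("tumor diameter must be positive")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if lattice is None:
        lattice = CellLattice(config.dims, config.voxel_size)
    centre = np.array([d / 2.0 - 0.5 for d in config.dims])
    radius_vox = config.tumor_diameter / (2 * config.voxel_size)

    if config.dispersed_seeding:
        _seed_dispersed(lattice, config, centre, radius_vox, rng)
    else:
        _seed_voronoi(lattice, config, centre, radius_vox, rng)
    return lattice


def _seed_voronoi(lattice, config, centre, radius_vox, rng):
    mask = _sphere_mask(config.dims, centre, radius_vox)
    voxels = np.argwhere(mask)
    n_cells = max(1, int(round(len(voxels) / lat.INITIAL_CELL_VOLUME)))
    seeds = voxels[rng.choice(len(voxels), size=n_cells, replace=False)].astype(float)
    d2 = ((voxels[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    ids = []
    for k in range(n_cells):
        vox_k = voxels[assign == k]
        if len(vox_k) == 0:
            continue
        rec = lattice.add_cell(vox_k, lat.TP,
                               target_volume=lat.INITIAL_CELL_VOLUME,
                               initial_volume=lat.INITIAL_CELL_VOLUME)
        ids.append(rec.id)
    _enforce_connectivity(lattice, ids)


def _seed_dispersed(lattice, config, centre, radius_vox, rng):
    # one ~64-voxel ball per cell on a jittered grid with ~2 voxels of ECM
    # between neighbours: dissociated cells that must first aggregate into a
    # spheroid before cycling, as when a culture is seeded.  The innermost
    # grid sites are used first, so the suspension is as compact as the
    # inter-cell gaps allow (~1.6x the final spheroid radius).
    cell_r = (3 * lat.INITIAL_CELL_VOLUME / (4 * np.pi)) ** (1 / 3)  # ~2.5 vox
    pitch = 2 * cell_r + 1.6
    n_target = max(2, int(round(
        (4 / 3 * np.pi * radius_vox**3) / lat.INITIAL_CELL_VOLUME)))
    max_r = min(d / 2.0 - cell_r - 2 for d in config.dims)
    span = np.arange(-max_r, max_r + 1e-9, pitch)
    span -= span.mean()  # centre the grid
    positions = [np.array(p) for p in
                 ((cx, cy, cz) for cx in span for cy in span for cz in span)
                 if np.linalg.norm(p) <= max_r]
    positions.sort(key=lambda p: (np.linalg.norm(p), tuple(p)))
    placed = 0
    for p in positions:
        if placed >= n_target:
            break
        pos = centre + p + rng.uniform(-0.5, 0.5, size=3)
        ball = _sphere_mask(config.dims, pos, cell_r)
        ball &= lattice.site_owner == 0
        vox = np.argwhere(ball)
        if len(vox) < lat.INITIAL_CELL_VOLUME * 3 // 4:
            continue
        lattice.add_cell(vox, lat.TP,
                         target_volume=lat.INITIAL_CELL_VOLUME,
                         initial_volume=lat.INITIAL_CELL_VOLUME)
        placed += 1


def _enforce_connectivity(lattice, ids):
    """Reassign stray fragments of Voronoi cells to an adjacent cell."""
    structure = ndimage.generate_binary_structure(3, 1)
    for cid in ids:
        if cid not in lattice.cells:
            continue
        mask = lattice.site_owner == cid
        labels, k = ndimage.label(mask, structure=structure)
        if k <= 1:
            continue
        sizes = ndimage.sum_labels(mask, labels, index=range(1, k + 1))
        keep = int(np.argmax(sizes)) + 1
        stray = np.argwhere(mask & (labels != keep))
        for x, y, z in stray:
            # donate to any face-adjacent other cell, else to ECM
            new_owner = 0
            for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                               (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                xx, yy, zz = x + dx, y + dy, z + dz
                if all(0 <= v < d for v, d in zip((xx, yy, zz), lattice.dims)):
                    q = lattice.site_owner[xx, yy, zz]
                    if q not in (0, cid):
                        new_owner = q
                        break
            lattice.site_owner[x, y, z] = new_owner
    counts = np.bincount(lattice.site_owner.ravel(), minlength=lattice._next_id)
    for cid in list(lattice.cells):
        lattice.cells[cid].volume = int(counts[cid])
        if counts[cid] == 0:
            del lattice.cells[cid]


def build_vessel_plexus(config: ScenarioConfig, lattice: CellLattice) -> list[int]:
    """Lay straight pre-existing vessels of quiescent EC cells.

    Vessels run along the z axis on a regular x-y grid at the configured
    spacing, skipping any line that would pass within ``vessel_margin`` of
    the central tumor sphere.  Each vessel is segmented into EC cells of
    ``ec_segment_length`` axial voxels (~64 voxels each).  Returns the EC
    cell ids.
    """
    nx, ny, nz = config.dims
    spacing_vox = config.vessel_spacing / config.voxel_size
    if spacing_vox <= 2 * config.vessel_radius:
        raise ValueError("vessel spacing below the vessel diameter")
    centre = np.array([d / 2.0 - 0.5 for d in config.dims])
    keep_out = (config.tumor_diameter / 2 + config.vessel_margin) / config.voxel_size
    r = config.vessel_radius
    # grid of vessel axes, offset half a spacing from the domain edge
    xs = np.arange(spacing_vox / 2, nx - r, spacing_vox)
    ys = np.arange(spacing_vox / 2, ny - r, spacing_vox)
    ids = []
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx))
    for ax in xs:
        for ay in ys:
            if np.hypot(ax - centre[0], ay - centre[1]) <= keep_out:
                continue
            disc = (xx - ax) ** 2 + (yy - ay) ** 2 <= r**2
            dx, dy = np.nonzero(disc)
            for z0 in range(0, nz, config.ec_segment_length):
                z1 = min(z0 + config.ec_segment_length, nz)
                if z1 - z0 < max(1, config.ec_segment_length // 2):
                    continue
                vox = np.array([(a, b, c)
                                for a, b in zip(dx, dy)
                                for c in range(z0, z1)])
                free = lattice.site_owner[vox[:, 0], vox[:, 1], vox[:, 2]] == 0
                vox = vox[free]
                if len(vox) == 0:
                    continue
                rec = lattice.add_cell(
                    vox, lat.EC, target_volume=len(vox),
                    initial_volume=max(len(vox), 1),
                )
                ids.append(rec.id)
    return ids


def build_scenario(config: ScenarioConfig, name: str = "custom") -> Scenario:
    """Full initial condition: tumor plus (optionally) the vessel plexus."""
    rng = np.random.default_rng(config.seed)
    lattice = CellLattice(config.dims, config.voxel_size)
    if config.tumor_diameter > 0:
        build_initial_tumor(config, lattice, rng)
    if config.vessels:
        build_vessel_plexus(config, lattice)
    return Scenario(lattice=lattice, config=config, name=name)


def _fixture_toy6() -> Scenario:
    cfg = ScenarioConfig(dims=(6, 6, 6), tumor_diameter=0.0, vessels=False,
                         nutrient_boundary="faces")
    latc = CellLattice(cfg.dims, cfg.voxel_size)
    latc.add_cell(np.argwhere(np.ones((2, 2, 2), bool)) + np.array([1, 2, 2]),
                  lat.TP, target_volume=8, initial_volume=8)
    latc.add_cell(np.argwhere(np.ones((2, 2, 2), bool)) + np.array([3, 2, 2]),
                  lat.TP, target_volume=8, initial_volume=8)
    return Scenario(lattice=latc, config=cfg, name="toy6")


def _fixture_rod100() -> Scenario:
    cfg = ScenarioConfig(dims=(100, 1, 1), tumor_diameter=0.0, vessels=False,
                         nutrient_boundary="faces")
    return Scenario(lattice=CellLattice(cfg.dims, cfg.voxel_size),
                    config=cfg, name="rod100")


def _fixture_spheroid50(seed: int = 0) -> Scenario:
    cfg = ScenarioConfig(dims=(50, 50, 50), tumor_diameter=65.0,
                         dispersed_seeding=True, vessels=False,
                         nutrient_boundary="faces", seed=seed)
    return build_scenario(cfg, name="spheroid50")


def _fixture_vascular80(seed: int = 0) -> Scenario:
    cfg = ScenarioConfig(dims=(80, 80, 80), tumor_diameter=65.0,
                         vessels=True, vessel_spacing=120.0,
                         vessel_margin=30.0, seed=seed)
    return build_scenario(cfg, name="vascular80")


def _fixture_vascular28(seed: int = 0) -> Scenario:
    """Small vascularized tumor for therapy-protocol experiments."""
    cfg = ScenarioConfig(dims=(28, 28, 28), tumor_diameter=40.0,
                         vessels=True, vessel_spacing=56.0, vessel_radius=2,
                         vessel_margin=10.0, seed=seed)
    return build_scenario(cfg, name="vascular28")


FIXTURES = {
    "toy6": _fixture_toy6,
    "rod100": _fixture_rod100,
    "spheroid50": _fixture_spheroid50,
    "vascular80": _fixture_vascular80,
    "vascular28": _fixture_vascular28,
}


def make_fixture(name: str, seed: int = 0) -> Scenario:
    """Deterministic small scenarios for oracle tests."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    fn = FIXTURES[name]
    try:
        return fn(seed)  # type: ignore[call-arg]
    except TypeError:
        return fn()
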