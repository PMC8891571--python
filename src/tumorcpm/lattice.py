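"""3D cellular Potts lattice: cell registry, Hamiltonian terms, Metropolis dynamics.

Each biological cell occupies many voxels of a 3D grid (``site_owner`` maps
voxels to cell ids, 0 = ECM/medium).  The effective energy is the sum of four
terms: differential adhesion between cell types, a quadratic volume
(growth) constraint, a continuity penalty on fragmented cells, and a
chemotaxis term for motile cells.  Dynamics are voxel copy attempts accepted
with the Metropolis rule at motility temperature ``T_m``; one Monte Carlo
step (MCS) performs as many attempts as there are lattice sites and is
calibrated to one minute of real time at the reference clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterable

import numpy as np
from scipy import ndimage

from . import _kernels
from ._kernels import CHEM_NONE, CHEM_NUTRIENT, CHEM_VEGF

__all__ = [
    "MEDIUM", "EC", "TM", "TP", "TQ", "TN", "TYPE_NAMES",
    "CellRecord", "CellLattice", "AdhesionMatrix",
    "adhesion_energy", "growth_energy", "continuity_energy",
    "chemotaxis_delta", "delta_hamiltonian", "hamiltonian",
    "metropolis_accept", "monte_carlo_step", "grow_and_divide",
]

# cell type codes (index into the adhesion matrix)
MEDIUM, EC, TM, TP, TQ, TN = 0, 1, 2, 3, 4, 5
TYPE_NAMES = {MEDIUM: "medium", EC: "EC", TM: "migrating",
              TP: "proliferating", TQ: "quiescent", TN: "necrotic"}

#: default elasticity per type (dimensionless energy units)
DEFAULT_GAMMA = {EC: 0.8, TM: 8.0, TP: 8.0, TQ: 2.0, TN: 2.0}

#: default chemotactic potential per type (negative = attraction)
CHI_EC = -1.61e6
CHI_M = -1.50e6
CHI_P = -1.45e6

INITIAL_CELL_VOLUME = 64  # voxels per freshly created cell


@dataclass
class AdhesionMatrix:
    """Symmetric type-by-type adhesion energy table J (higher = weaker bond)."""

    J: np.ndarray

    def __post_init__(self):
        self.J = np.asarray(self.J, dtype=np.float64)
        if self.J.shape != (6, 6):
            raise ValueError("adhesion matrix must be 6x6 (EC, M, P, Q, N, medium)")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("adhesion matrix must be symmetric")

    @classmethod
    def default(cls, j_medium_medium: float = 6.0) -> "AdhesionMatrix":
        """The calibrated adhesion table.

        Order here is (medium, EC, M, P, Q, N) to match the type codes.  The
        medium-medium entry is exposed because the published table admits two
        readings (6 or 66); it only matters between distinct medium entities
        and the model uses a single medium, so it never enters the dynamics.
        """
        J = np.zeros((6, 6))
        J[MEDIUM, MEDIUM] = j_medium_medium
        J[EC, EC] = 5.0
        for t in (TM, TP, TQ, TN):
            J[EC, t] = J[t, EC] = 30.0
        J[EC, MEDIUM] = J[MEDIUM, EC] = 12.0
        for a in (TM, TP, TQ):
            for b in (TM, TP, TQ):
                J[a, b] = 8.0
            J[a, TN] = J[TN, a] = 10.0
            J[a, MEDIUM] = J[MEDIUM, a] = 12.0
        J[TN, TN] = 8.0
        J[TN, MEDIUM] = J[MEDIUM, TN] = 10.0
        return cls(J)


@dataclass
class CellRecord:
    """Registry entry for one generalized cell."""

    id: int
    type: int
    volume: int
    target_volume: float
    elasticity: float
    chi: float = 0.0
    chem_field: int = CHEM_NONE
    initial_volume: int = INITIAL_CELL_VOLUME
    cum_drug: float = 0.0
    hypoxia_minutes: float = 0.0
    necrosis_minutes: float = 0.0
    drug_quiescent: bool = False
    drug_arrest_minutes: float = 0.0
    ec_activated: bool = False
    # latest receptor readout (integrin, RTK, cadherin, Wnt, APC, NF1)
    receptor_inputs: tuple = (0, 0, 0, 0, 0, 0)
    phenotype_code: int = 0

    def __post_init__(self):
        if self.chi > 0:
            raise ValueError("chemotactic potential must be <= 0")


class CellLattice:
    """Voxel grid plus cell registry; keeps per-id arrays for the kernels."""

    def __init__(self, dims: tuple[int, int, int], voxel_size: float = 4.0):
        self.dims = tuple(int(d) for d in dims)
        self.voxel_size = float(voxel_size)  # micrometres per voxel edge
        self.site_owner = np.zeros(self.dims, dtype=np.int32)
        self.cells: dict[int, CellRecord] = {}
        self._next_id = 1

    # -- registry ----------------------------------------------------------

    def new_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    @property
    def n_sites(self) -> int:
        return int(np.prod(self.dims))

    def add_cell(self, voxels: np.ndarray, type_code: int,
                 target_volume: float | None = None,
                 elasticity: float | None = None,
                 chi: float = 0.0, chem_field: int = CHEM_NONE,
                 initial_volume: int | None = None) -> CellRecord:
        """Claim ``voxels`` (an (n,3) index array) for a new cell."""
        voxels = np.asarray(voxels)
        cid = self.new_id()
        vol = len(voxels)
        if initial_volume is None:
            initial_volume = vol
        rec = CellRecord(
            id=cid, type=type_code, volume=vol,
            target_volume=float(target_volume if target_volume is not None else vol),
            elasticity=float(elasticity if elasticity is not None
                             else DEFAULT_GAMMA.get(type_code, 1.0)),
            chi=chi, chem_field=chem_field, initial_volume=int(initial_volume),
        )
        self.site_owner[voxels[:, 0], voxels[:, 1], voxels[:, 2]] = cid
        self.cells[cid] = rec
        return rec

    def remove_cell(self, cid: int) -> None:
        rec = self.cells.pop(cid)
        if rec.volume > 0:
            self.site_owner[self.site_owner == cid] = 0

    def cell_voxels(self, cid: int) -> np.ndarray:
        return np.argwhere(self.site_owner == cid)

    # -- kernel-facing per-id arrays --------------------------------------

    def id_arrays(self):
        n = self._next_id
        cell_type = np.zeros(n, dtype=np.uint8)
        vol = np.zeros(n, dtype=np.int64)
        tvol = np.zeros(n, dtype=np.float64)
        gamma = np.zeros(n, dtype=np.float64)
        chi = np.zeros(n, dtype=np.float64)
        chem = np.zeros(n, dtype=np.uint8)
        for cid, rec in self.cells.items():
            cell_type[cid] = rec.type
            vol[cid] = rec.volume
            tvol[cid] = rec.target_volume
            gamma[cid] = rec.elasticity
            chi[cid] = rec.chi
            chem[cid] = rec.chem_field
        return cell_type, vol, tvol, gamma, chi, chem

    def type_grid(self) -> np.ndarray:
        cell_type, *_ = self.id_arrays()
        return cell_type[self.site_owner]

    # -- audits ------------------------------------------------------------

    def audit_volumes(self) -> bool:
        """Registry volumes must equal the owned-site counts, exactly."""
        counts = np.bincount(self.site_owner.ravel(), minlength=self._next_id)
        for cid, rec in self.cells.items():
            if counts[cid] != rec.volume:
                return False
        claimed = sum(rec.volume for rec in self.cells.values())
        return claimed == int((self.site_owner != 0).sum())

    def fragmented_cells(self) -> list[int]:
        """Ids of cells whose voxel set is not a single face-connected blob."""
        structure = ndimage.generate_binary_structure(3, 1)
        bad = []
        slices = ndimage.find_objects(self.site_owner)
        for cid, rec in self.cells.items():
            if rec.volume == 0:
                continue
            sl = slices[cid - 1] if cid - 1 < len(slices) else None
            region = self.site_owner[sl] if sl is not None else self.site_owner
            _, k = ndimage.label(region == cid, structure=structure)
            if k != 1:
                bad.append(cid)
        return bad


# ---------------------------------------------------------------------------
# Hamiltonian terms
# ---------------------------------------------------------------------------

_ADH_OFFSETS = {
    1: np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=np.int64),
    2: np.array(
        [[1, 0, 0], [0, 1, 0], [0, 0, 1],
         [1, 1, 0], [1, -1, 0], [1, 0, 1], [1, 0, -1],
         [0, 1, 1], [0, 1, -1]],
        dtype=np.int64,
    ),
}


def adhesion_energy(lattice: CellLattice, J: AdhesionMatrix,
                    neighborhood: int = 1) -> float:
    """Sum of J(type, type') over unordered neighbour pairs with different
    owners (Kronecker delta on cell id, so two touching cells of the same
    type still pay their J)."""
    offsets = _ADH_OFFSETS[neighborhood]
    owner = lattice.site_owner
    tgrid = lattice.type_grid()
    total = 0.0
    for off in offsets:
        a = tuple(slice(max(0, o), None) if o >= 0 else slice(None, o) for o in off)
        b = tuple(slice(None, -o) if o > 0 else slice(-o, None) for o in off)
        oa, ob = owner[a], owner[b]
        diff = oa != ob
        total += float(J.J[tgrid[a][diff], tgrid[b][diff]].sum())
    return total


def growth_energy(lattice: CellLattice) -> float:
    """Quadratic volume constraint: sum of gamma (v - V_target)^2 over cells."""
    return float(sum(
        rec.elasticity * (rec.volume - rec.target_volume) ** 2
        for rec in lattice.cells.values()
    ))


def continuity_energy(lattice: CellLattice, alpha: float = 300.0) -> float:
    """Penalty alpha for every cell whose registered volume differs from its
    largest face-connected component, i.e. for every fragmented cell."""
    return alpha * len(lattice.fragmented_cells())


def chemotaxis_delta(c_source: float, c_target: float, chi: float) -> float:
    """Chemotaxis contribution to dH for a copy attempt of a motile cell:
    chi * (C(target) - C(source)).  chi <= 0, so moves up the gradient are
    favoured."""
    if chi > 0:
        raise ValueError("chemotactic potential must be <= 0")
    return chi * (c_target - c_source)


def hamiltonian(lattice: CellLattice, J: AdhesionMatrix, alpha: float = 300.0,
                neighborhood: int = 1) -> float:
    """Full effective energy (adhesion + growth + continuity).

    The chemotaxis term acts through copy-attempt deltas only (it is a drive,
    not a state function) and is therefore excluded here; see
    :func:`chemotaxis_delta`.
    """
    return (adhesion_energy(lattice, J, neighborhood)
            + growth_energy(lattice)
            + continuity_energy(lattice, alpha))


def delta_hamiltonian(
    lattice: CellLattice,
    site: tuple[int, int, int],
    candidate_owner: int,
    J: AdhesionMatrix,
    alpha: float = 300.0,
    neighborhood: int = 1,
    fields: dict | None = None,
) -> float:
    """Incremental energy change for copying ``candidate_owner`` onto ``site``.

    Adhesion, growth and continuity are computed incrementally and equal the
    brute-force Hamiltonian difference exactly; the chemotaxis term follows
    the copy-attempt contract (``fields`` maps the kernel chemotaxis selector
    to a concentration grid, and the source voxel is implied by the
    candidate: the delta uses the concentration at the nearest voxel of the
    invading cell).
    """
    x, y, z = site
    o = int(lattice.site_owner[x, y, z])
    s = int(candidate_owner)
    if s == o:
        return 0.0
    offsets = _ADH_OFFSETS[neighborhood]
    tgrid_types, vol, tvol, gamma, chi, chem = lattice.id_arrays()
    nx, ny, nz = lattice.dims
    d_adh = 0.0
    t_new, t_old = tgrid_types[s], tgrid_types[o]
    for off in np.vstack([offsets, -offsets]):
        xx, yy, zz = x + off[0], y + off[1], z + off[2]
        if not (0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz):
            continue
        q = int(lattice.site_owner[xx, yy, zz])
        tq = tgrid_types[q]
        if q != s:
            d_adh += J.J[t_new, tq]
        if q != o:
            d_adh -= J.J[t_old, tq]
    d_vol = 0.0
    if s != 0:
        d_vol += gamma[s] * ((vol[s] + 1 - tvol[s]) ** 2 - (vol[s] - tvol[s]) ** 2)
    if o != 0:
        d_vol += gamma[o] * ((vol[o] - 1 - tvol[o]) ** 2 - (vol[o] - tvol[o]) ** 2)
    # exact continuity delta: count fragmented cells among {s, o} before/after
    d_cont = 0.0
    if alpha != 0.0:
        d_cont -= alpha * len(_fragmented_subset(lattice, (s, o)))
        lattice.site_owner[x, y, z] = s
        if s != 0:
            lattice.cells[s].volume += 1
        if o != 0:
            lattice.cells[o].volume -= 1
        d_cont += alpha * len(_fragmented_subset(lattice, (s, o)))
        lattice.site_owner[x, y, z] = o
        if s != 0:
            lattice.cells[s].volume -= 1
        if o != 0:
            lattice.cells[o].volume += 1
    d_chem = 0.0
    if fields and s != 0 and chem[s] != CHEM_NONE:
        grid = fields.get(int(chem[s]))
        if grid is not None:
            # source voxel: the neighbouring voxel of the invading cell
            for off in _ADH_OFFSETS[1]:
                for sgn in (1, -1):
                    xx, yy, zz = x + sgn * off[0], y + sgn * off[1], z + sgn * off[2]
                    if (0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz
                            and lattice.site_owner[xx, yy, zz] == s):
                        d_chem = chemotaxis_delta(
                            float(grid[xx, yy, zz]), float(grid[x, y, z]), chi[s])
                        break
                else:
                    continue
                break
    return float(d_adh + d_vol + d_cont + d_chem)


def _fragmented_subset(lattice: CellLattice, ids: Iterable[int]) -> list[int]:
    structure = ndimage.generate_binary_structure(3, 1)
    bad = []
    for cid in ids:
        if cid == 0 or cid not in lattice.cells:
            continue
        rec = lattice.cells[cid]
        if rec.volume == 0:
            continue
        mask = lattice.site_owner == cid
        _, k = ndimage.label(mask, structure=structure)
        if k != 1:
            bad.append(cid)
    return bad


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def metropolis_accept(delta_h: float, t_m: float, rng: np.random.Generator) -> bool:
    """Accept if dH <= 0, else with Boltzmann probability exp(-dH / T_m)."""
    if t_m <= 0:
        raise ValueError("motility temperature must be > 0")
    if delta_h <= 0:
        return True
    return bool(rng.random() < np.exp(-delta_h / t_m))


def monte_carlo_step(
    lattice: CellLattice,
    J: AdhesionMatrix,
    t_m: float,
    rng: np.random.Generator,
    nutrient: np.ndarray | None = None,
    vegf: np.ndarray | None = None,
    adhesion_neighborhood: int = 1,
    n_attempts: int | None = None,
) -> int:
    """One MCS: ``n_attempts`` (default: the site count) random copy attempts.

    Copies that would locally disconnect the losing cell are rejected
    outright (the continuity constraint enforced as a hard guard in the
    dynamics).  Returns the number of accepted copies.
    """
    cell_type, vol, tvol, gamma, chi, chem = lattice.id_arrays()
    zeros = np.zeros(lattice.dims, dtype=np.float64)
    nut = nutrient if nutrient is not None else zeros
    veg = vegf if vegf is not None else zeros
    if n_attempts is None:
        n_attempts = lattice.n_sites
    seed = int(rng.integers(0, 2**31 - 1))
    accepted = _kernels.mcs_sweep(
        lattice.site_owner, cell_type, vol, tvol, gamma, chi, chem,
        np.ascontiguousarray(nut), np.ascontiguousarray(veg),
        J.J, _ADH_OFFSETS[adhesion_neighborhood], float(t_m),
        seed, int(n_attempts),
    )
    dead = []
    for cid, rec in lattice.cells.items():
        rec.volume = int(vol[cid])
        if rec.volume == 0:
            dead.append(cid)
    for cid in dead:
        del lattice.cells[cid]
    return int(accepted)


def grow_and_divide(
    lattice: CellLattice,
    cid: int,
    rng: np.random.Generator,
    growth_increment: float = 0.0,
) -> int | None:
    """Advance one cell's growth schedule and divide it when doubled.

    The target volume grows by ``growth_increment`` voxels.  When the actual
    volume reaches twice the initial volume the cell splits along a random
    plane through its centroid (median split, ties to the parent): the parent
    target volume is reset to the initial volume and the daughter inherits
    type and target volume under a new unique id.  Returns the daughter id,
    or None if no division happened.  Division of a 1-voxel cell is a no-op.
    """
    rec = lattice.cells[cid]
    # the growth schedule aims at doubling, no further: target saturates at
    # 2x the initial volume until the actual volume catches up and the cell
    # divides (cells blocked by crowding hold a bounded volume deficit)
    rec.target_volume = min(rec.target_volume + growth_increment,
                            2.0 * rec.initial_volume)
    if rec.volume < 2 * rec.initial_volume or rec.volume <= 1:
        return None
    voxels = lattice.cell_voxels(cid).astype(np.float64)
    centroid = voxels.mean(axis=0)
    normal = rng.normal(size=3)
    normal /= np.linalg.norm(normal)
    proj = (voxels - centroid) @ normal
    order = np.argsort(proj, kind="stable")
    half = len(order) // 2
    daughter_sel = order[half:] if len(order) % 2 == 0 else order[half + 1:]
    daughter_vox = voxels[daughter_sel].astype(np.intp)

    new_id = lattice.new_id()
    lattice.site_owner[daughter_vox[:, 0], daughter_vox[:, 1], daughter_vox[:, 2]] = new_id
    d_rec = CellRecord(
        id=new_id, type=rec.type, volume=len(daughter_vox),
        target_volume=float(rec.initial_volume),
        elasticity=rec.elasticity, chi=rec.chi, chem_field=rec.chem_field,
        initial_volume=rec.initial_volume,
    )
    d_rec.ec_activated = rec.ec_activated
    lattice.cells[new_id] = d_rec
    rec.volume -= len(daughter_vox)
    rec.target_volume = float(rec.initial_volume)
    _reunite(lattice, cid, new_id)
    return new_id


def _reunite(lattice: CellLattice, a: int, b: int) -> None:
    """After a plane split, move stray fragments to the sibling owning the
    largest adjacent component so both daughters are face-connected."""
    structure = ndimage.generate_binary_structure(3, 1)
    for cid, sib in ((a, b), (b, a)):
        mask = lattice.site_owner == cid
        labels, k = ndimage.label(mask, structure=structure)
        if k <= 1:
            continue
        sizes = ndimage.sum_labels(mask, labels, index=range(1, k + 1))
        keep = int(np.argmax(sizes)) + 1
        stray = mask & (labels != keep)
        lattice.site_owner[stray] = sib
        moved = int(stray.sum())
        lattice.cells[cid].volume -= moved
        lattice.cells[sib].volume += moved
    for cid, rec in list(lattice.cells.items()):
        if cid in (a, b):
            rec.volume = int((lattice.site_owner == cid).sum())
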