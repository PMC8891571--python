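"""Numba kernels for the hot loops: Potts sweeps, FTCS sub-steps, contact tallies.

All kernels are deterministic given their explicit seed arguments; the
surrounding Python code derives those seeds from the single simulation RNG.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# chemotaxis field selector per cell id
CHEM_NONE = 0
CHEM_NUTRIENT = 1
CHEM_VEGF = 2


@njit(cache=True, inline="always")
def _local_connect_ok(owner, x, y, z, nx, ny, nz):
    """Local articulation check: may voxel (x,y,z) leave cell ``owner[x,y,z]``?

    Examines the 3x3x3 neighbourhood and verifies that all face-neighbours
    belonging to the same cell remain mutually face-connected through the
    neighbourhood once the centre voxel is removed.  Conservative and local:
    a standard simple-point style guard against cell fragmentation.
    """
    o = owner[x, y, z]
    mask = np.zeros(27, dtype=np.uint8)
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            for dz in range(-1, 2):
                if dx == 0 and dy == 0 and dz == 0:
                    continue
                xx, yy, zz = x + dx, y + dy, z + dz
                if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
                    if owner[xx, yy, zz] == o:
                        mask[(dx + 1) * 9 + (dy + 1) * 3 + (dz + 1)] = 1
    # face neighbours of the centre, as local indices
    faces = np.empty(6, dtype=np.int64)
    faces[0] = 0 * 9 + 1 * 3 + 1
    faces[1] = 2 * 9 + 1 * 3 + 1
    faces[2] = 1 * 9 + 0 * 3 + 1
    faces[3] = 1 * 9 + 2 * 3 + 1
    faces[4] = 1 * 9 + 1 * 3 + 0
    faces[5] = 1 * 9 + 1 * 3 + 2
    start = -1
    n_face = 0
    for k in range(6):
        if mask[faces[k]] == 1:
            n_face += 1
            if start < 0:
                start = faces[k]
    if n_face <= 1:
        # 0 or 1 same-cell face neighbours: removal cannot split the cell
        # (an isolated voxel is its own component; a single neighbour stays
        # connected to the rest through itself)
        return True
    # BFS over the masked neighbourhood using face adjacency
    visited = np.zeros(27, dtype=np.uint8)
    queue = np.empty(27, dtype=np.int64)
    head = 0
    tail = 0
    queue[tail] = start
    tail += 1
    visited[start] = 1
    while head < tail:
        cur = queue[head]
        head += 1
        cx = cur // 9
        cy = (cur % 9) // 3
        cz = cur % 3
        for k in range(6):
            ddx = (1 if k == 1 else (-1 if k == 0 else 0))
            ddy = (1 if k == 3 else (-1 if k == 2 else 0))
            ddz = (1 if k == 5 else (-1 if k == 4 else 0))
            ax, ay, az = cx + ddx, cy + ddy, cz + ddz
            if 0 <= ax < 3 and 0 <= ay < 3 and 0 <= az < 3:
                if ax == 1 and ay == 1 and az == 1:
                    continue  # the centre is being removed
                idx = ax * 9 + ay * 3 + az
                if mask[idx] == 1 and visited[idx] == 0:
                    visited[idx] = 1
                    queue[tail] = idx
                    tail += 1
    for k in range(6):
        if mask[faces[k]] == 1 and visited[faces[k]] == 0:
            return False
    return True


@njit(cache=True)
def mcs_sweep(
    owner,
    cell_type,       # uint8[n_ids], type code per cell id (0 = medium)
    vol,             # int64[n_ids]
    tvol,            # float64[n_ids]
    gamma,           # float64[n_ids]
    chi,             # float64[n_ids]
    chem_sel,        # uint8[n_ids]: CHEM_NONE/NUTRIENT/VEGF
    nutrient,
    vegf,
    J,               # float64[6, 6]
    adh_off,         # int64[k, 3] adhesion neighbourhood offsets (half-shell)
    tm,
    seed,
    n_attempts,
):
    """One Monte Carlo step: ``n_attempts`` random voxel copy attempts.

    Returns the number of accepted copies.  Volumes in ``vol`` are updated in
    place; the Python registry is synchronised afterwards.
    """
    np.random.seed(seed)
    nx, ny, nz = owner.shape
    accepted = 0
    for _ in range(n_attempts):
        x = np.random.randint(0, nx)
        y = np.random.randint(0, ny)
        z = np.random.randint(0, nz)
        k = np.random.randint(0, 6)
        dx = (1 if k == 1 else (-1 if k == 0 else 0))
        dy = (1 if k == 3 else (-1 if k == 2 else 0))
        dz = (1 if k == 5 else (-1 if k == 4 else 0))
        sx, sy, sz = x + dx, y + dy, z + dz
        if sx < 0 or sx >= nx or sy < 0 or sy >= ny or sz < 0 or sz >= nz:
            continue
        s = owner[sx, sy, sz]  # invading cell id
        o = owner[x, y, z]     # current owner of the target site
        if s == o:
            continue
        # continuity guard: the target voxel must be removable from its cell
        if o != 0 and not _local_connect_ok(owner, x, y, z, nx, ny, nz):
            continue
        t_new = cell_type[s]
        t_old = cell_type[o]
        # adhesion delta over the configured neighbourhood (full shell)
        d_adh = 0.0
        for a in range(adh_off.shape[0]):
            for sgn in range(2):
                ox = adh_off[a, 0] if sgn == 0 else -adh_off[a, 0]
                oy = adh_off[a, 1] if sgn == 0 else -adh_off[a, 1]
                oz = adh_off[a, 2] if sgn == 0 else -adh_off[a, 2]
                xx, yy, zz = x + ox, y + oy, z + oz
                if xx < 0 or xx >= nx or yy < 0 or yy >= ny or zz < 0 or zz >= nz:
                    continue
                q = owner[xx, yy, zz]
                tq = cell_type[q]
                if q != s:
                    d_adh += J[t_new, tq]
                if q != o:
                    d_adh -= J[t_old, tq]
        # growth (volume elasticity) delta; medium (id 0) carries no term
        d_vol = 0.0
        if s != 0:
            v = float(vol[s])
            d_vol += gamma[s] * ((v + 1.0 - tvol[s]) ** 2 - (v - tvol[s]) ** 2)
        if o != 0:
            v = float(vol[o])
            d_vol += gamma[o] * ((v - 1.0 - tvol[o]) ** 2 - (v - tvol[o]) ** 2)
        # chemotaxis for the invading cell only, when motile
        d_chem = 0.0
        if s != 0 and chem_sel[s] != CHEM_NONE:
            if chem_sel[s] == CHEM_NUTRIENT:
                d_chem = chi[s] * (nutrient[x, y, z] - nutrient[sx, sy, sz])
            else:
                d_chem = chi[s] * (vegf[x, y, z] - vegf[sx, sy, sz])
        dh = d_adh + d_vol + d_chem
        if dh <= 0.0 or np.random.random() < np.exp(-dh / tm):
            owner[x, y, z] = s
            if s != 0:
                vol[s] += 1
            if o != 0:
                vol[o] -= 1
            accepted += 1
    return accepted


@njit(cache=True)
def ftcs_substep(
    field,
    d_vox,           # diffusion constant, voxel^2 / s
    dt,
    decay_factor,    # exp(-k dt), 1.0 for no decay
    uptake_cap,      # float64 grid: max uptake rate pg/voxel/s (0 = none)
    uptake_linear,   # linear uptake rate constant 1/s applied below the cap
    source,          # float64 grid: source rate pg/voxel/s
    dirichlet_mask,  # uint8 grid: 1 where the value is clamped
    dirichlet_values,  # float64 grid of clamp values
):
    """One explicit FTCS sub-step with no-flux domain faces.

    Operator split: diffusion, exact exponential decay, capped uptake,
    source, Dirichlet clamp.  Uptake never drives a voxel negative.
    """
    nx, ny, nz = field.shape
    new = np.empty_like(field)
    lam = d_vox * dt
    # no-flux faces via clamped ghosts (ghost = face value): the pairwise
    # exchange form is antisymmetric, so pure diffusion conserves mass to
    # round-off on a closed domain
    for x in range(nx):
        xm = x - 1 if x > 0 else x
        xp = x + 1 if x < nx - 1 else x
        for y in range(ny):
            ym = y - 1 if y > 0 else y
            yp = y + 1 if y < ny - 1 else y
            for z in range(nz):
                zm = z - 1 if z > 0 else z
                zp = z + 1 if z < nz - 1 else z
                c = field[x, y, z]
                lap = (
                    field[xm, y, z] + field[xp, y, z]
                    + field[x, ym, z] + field[x, yp, z]
                    + field[x, y, zm] + field[x, y, zp]
                    - 6.0 * c
                )
                v = c + lam * lap
                v *= decay_factor
                cap = uptake_cap[x, y, z]
                if cap > 0.0:
                    rate = uptake_linear * v
                    if rate > cap:
                        rate = cap
                    amt = rate * dt
                    if amt > v:
                        amt = v
                    v -= amt
                v += source[x, y, z] * dt
                if dirichlet_mask[x, y, z] == 1:
                    v = dirichlet_values[x, y, z]
                if v < 0.0:
                    v = 0.0
                new[x, y, z] = v
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                field[x, y, z] = new[x, y, z]
    return field


@njit(cache=True)
def uptake_tally(field, owner, uptake_cap, uptake_linear, dt, n_ids):
    """Per-cell uptake amounts for one sub-step interval (pg), without
    modifying the field.  Mirrors the uptake rule of :func:`ftcs_substep`."""
    nx, ny, nz = field.shape
    out = np.zeros(n_ids, dtype=np.float64)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                cap = uptake_cap[x, y, z]
                if cap > 0.0:
                    v = field[x, y, z]
                    rate = uptake_linear * v
                    if rate > cap:
                        rate = cap
                    amt = rate * dt
                    if amt > v:
                        amt = v
                    out[owner[x, y, z]] += amt
    return out


@njit(cache=True)
def contact_and_field_tally(owner, cell_type, nutrient, vegf, n_ids):
    """One lattice pass gathering, per cell id:

    boundary face counts split by neighbour class (same cell excluded):
    viable tumor / EC / medium-ECM / necrotic, plus voxel count and summed
    nutrient and VEGF over the cell's voxels.

    Returns (counts[n_ids, 5], nut_sum[n_ids], vegf_sum[n_ids]) where the
    count columns are: total boundary faces, viable-tumor contact, EC
    contact, ECM contact, necrotic contact.  Domain faces count as ECM.
    """
    nx, ny, nz = owner.shape
    counts = np.zeros((n_ids, 5), dtype=np.int64)
    nut = np.zeros(n_ids, dtype=np.float64)
    veg = np.zeros(n_ids, dtype=np.float64)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                c = owner[x, y, z]
                if c == 0:
                    continue
                nut[c] += nutrient[x, y, z]
                veg[c] += vegf[x, y, z]
                for k in range(6):
                    ddx = (1 if k == 1 else (-1 if k == 0 else 0))
                    ddy = (1 if k == 3 else (-1 if k == 2 else 0))
                    ddz = (1 if k == 5 else (-1 if k == 4 else 0))
                    xx, yy, zz = x + ddx, y + ddy, z + ddz
                    if xx < 0 or xx >= nx or yy < 0 or yy >= ny or zz < 0 or zz >= nz:
                        counts[c, 0] += 1
                        counts[c, 3] += 1  # domain face counts as ECM
                        continue
                    q = owner[xx, yy, zz]
                    if q == c:
                        continue
                    counts[c, 0] += 1
                    tq = cell_type[q]
                    if tq == 0:
                        counts[c, 3] += 1
                    elif tq == 1:
                        counts[c, 2] += 1
                    elif tq == 5:
                        counts[c, 4] += 1
                    else:
                        counts[c, 1] += 1
    return counts, nut, veg


@njit(cache=True)
def helmholtz_matvec(v, out, dims0, dims1, dims2, diag, d_vox):
    """out = diag*v - d_vox*lap(v) with no-flux (clamped ghost) faces."""
    f = v.reshape((dims0, dims1, dims2))
    o = out.reshape((dims0, dims1, dims2))
    for x in range(dims0):
        xm = x - 1 if x > 0 else x
        xp = x + 1 if x < dims0 - 1 else x
        for y in range(dims1):
            ym = y - 1 if y > 0 else y
            yp = y + 1 if y < dims1 - 1 else y
            for z in range(dims2):
                zm = z - 1 if z > 0 else z
                zp = z + 1 if z < dims2 - 1 else z
                lap = (f[xm, y, z] + f[xp, y, z] + f[x, ym, z] + f[x, yp, z]
                       + f[x, y, zm] + f[x, y, zp] - 6.0 * f[x, y, z])
                o[x, y, z] = diag * f[x, y, z] - d_vox * lap
    return out
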