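"""Reaction-diffusion fields: nutrient, VEGF and chemotherapeutic drug.

The three concentration fields live on the same voxel grid as the cell
lattice and obey

    dn/dt = D_n lap(n) - B(x, n)       + S_n   (nutrient)
    dV/dt = D_V lap(V) - k_V V - E(x, V) + S_V (VEGF)
    dc/dt = D_c lap(c) - k_c c - R(x, c) + S_c (drug)

with piecewise, cell-type-dependent uptake terms (linear below a per-voxel
cap, capped above it, zero outside the consuming type) and sources at vessel
(EC) voxels, respectively at hypoxic tumor voxels for VEGF.

Numerics: explicit FTCS with no-flux domain faces, operator-split exact
exponential decay, automatic sub-stepping at the diffusion stability limit
(D dt / dx^2 <= 1/6).  Internal canonical units are picograms per voxel and
seconds; molar per-cell rates from the physical parameter table are
converted once via an explicit conversion constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels

__all__ = [
    "FieldSet", "TransportParams", "StabilityError",
    "step_nutrient", "step_vegf", "step_drug", "relax_to_quasi_steady",
]


class StabilityError(ValueError):
    """Requested time step violates the explicit-scheme stability bound."""

    def __init__(self, dt: float, dt_max: float):
        self.required_substeps = int(np.ceil(dt / dt_max))
        super().__init__(
            f"dt={dt:g}s exceeds the FTCS stability limit {dt_max:g}s; "
            f"use at least {self.required_substeps} sub-steps"
        )


@dataclass
class TransportParams:
    """Physical transport and signalling parameters.

    Diffusion constants are in um^2/s, decay rates in 1/s equivalents of the
    tabulated values, per-cell molar rates in mol/cell/s.  ``mol_to_pg``
    converts molar per-cell rates to picograms and is the single calibrated
    unit bridge (logged in run summaries); its default is set so that the
    nutrient penetration depth into consuming tumor tissue is a few cell
    diameters, which places avascular growth arrest near the 150 um scale.
    """

    d_nutrient: float = 1.0e3        # um^2/s
    d_vegf: float = 10.0             # um^2/s
    d_drug: float = 1.5e3            # um^2/s
    k_vegf: float = 0.9375 / 3600.0  # 1/s (tabulated 0.9375 / h)
    k_drug: float = np.log(2) / (6 * 3600.0)  # 1/s; 6 h half-life default
    s_nutrient: float = 8.83e-16     # mol/cell/s released at vessel voxels
    beta_p: float = 5.17e-17         # mol/cell/s uptake, proliferating/migrating
    beta_q: float = 2.41e-17         # mol/cell/s uptake, quiescent
    beta_n: float = 0.0              # necrotic cells consume nothing
    kappa_p: float = 9.2e-18         # mol/cell/s drug uptake, proliferative
    vegf_uptake_e: float = 0.001     # pg/cell/s EC uptake cap
    s_vegf: float = 0.035            # pg/voxel per reference MCS (1 min), hypoxic voxels
    n0: float = 4.6                  # pg/voxel initial & vessel nutrient level
    mol_to_pg: float = 1.2e20        # pg per mol, calibrated unit bridge (nutrient)
    drug_mol_to_pg: float = 2.5e13   # pg per mol for the drug field (separate
                                     # bridge: drug doses are far below nutrient
                                     # turnover and share no physical unit link)
    uptake_linear_rate: float = 100.0  # 1/s: linear uptake regime below the cap
    drug_uptake_linear_rate: float = 1e-5  # 1/s, the R = c branch of drug uptake
                                     # (keeps uptake dose-proportional below the cap)
    voxel_size: float = 4.0          # um
    cell_voxels: int = 64            # voxels per cell for per-voxel rate caps

    # -- derived, voxel units ---------------------------------------------

    def d_vox(self, d_um: float) -> float:
        return d_um / self.voxel_size**2

    def dt_max(self, d_um: float, safety: float = 1.0) -> float:
        d = self.d_vox(d_um)
        if d <= 0:
            return np.inf
        return safety / (6.0 * d)

    def per_voxel(self, mol_rate: float) -> float:
        """mol/cell/s -> pg/voxel/s via the conversion constant."""
        return mol_rate * self.mol_to_pg / self.cell_voxels

    @property
    def beta_p_vox(self) -> float:
        return self.per_voxel(self.beta_p)

    @property
    def beta_q_vox(self) -> float:
        return self.per_voxel(self.beta_q)

    def per_voxel_drug(self, mol_rate: float) -> float:
        """mol/cell/s -> pg/voxel/s on the drug unit bridge."""
        return mol_rate * self.drug_mol_to_pg / self.cell_voxels

    @property
    def kappa_p_vox(self) -> float:
        return self.per_voxel_drug(self.kappa_p)

    @property
    def e_vox(self) -> float:
        return self.vegf_uptake_e / self.cell_voxels  # already pg/cell/s


@dataclass
class FieldSet:
    """The three scalar concentration fields on one grid (pg/voxel)."""

    nutrient: np.ndarray
    vegf: np.ndarray
    drug: np.ndarray

    @classmethod
    def initial(cls, dims: tuple[int, int, int], params: TransportParams) -> "FieldSet":
        """Start-of-run fields: uniform nutrient at n0, no VEGF, no drug."""
        return cls(
            nutrient=np.full(dims, params.n0, dtype=np.float64),
            vegf=np.zeros(dims, dtype=np.float64),
            drug=np.zeros(dims, dtype=np.float64),
        )

    def check(self) -> None:
        for name in ("nutrient", "vegf", "drug"):
            arr = getattr(self, name)
            if (arr < 0).any():
                raise ValueError(f"negative concentration in {name} field")


def _zeros(shape):
    return np.zeros(shape, dtype=np.float64)


def _substep_count(dt: float, dt_max: float, enforce: bool) -> tuple[int, float]:
    if dt <= dt_max:
        return 1, dt
    if enforce:
        raise StabilityError(dt, dt_max)
    n = int(np.ceil(dt / dt_max))
    return n, dt / n


def step_nutrient(
    n_field: np.ndarray,
    dt: float,
    params: TransportParams,
    uptake_cap: np.ndarray | None = None,
    vessel_mask: np.ndarray | None = None,
    boundary_dirichlet: bool = False,
    substep: bool = True,
) -> np.ndarray:
    """Advance the nutrient field by ``dt`` seconds (in place).

    ``uptake_cap`` is the per-voxel uptake cap grid (pg/voxel/s; zero where
    no consuming cell sits).  Vessel voxels are clamped to the supply level
    n0 (the vessel-surface condition); with ``boundary_dirichlet`` the domain
    faces are clamped instead (avascular culture with fresh medium outside).
    """
    dims = n_field.shape
    dmax = params.dt_max(params.d_nutrient)
    n_sub, sub_dt = _substep_count(dt, dmax, enforce=not substep)
    cap = uptake_cap if uptake_cap is not None else _zeros(dims)
    mask = np.zeros(dims, dtype=np.uint8)
    if vessel_mask is not None:
        mask |= vessel_mask.astype(np.uint8)
    if boundary_dirichlet:
        mask[0, :, :] = mask[-1, :, :] = 1
        mask[:, 0, :] = mask[:, -1, :] = 1
        mask[:, :, 0] = mask[:, :, -1] = 1
    dval = np.full(dims, params.n0, dtype=np.float64)
    for _ in range(n_sub):
        _kernels.ftcs_substep(
            n_field, params.d_vox(params.d_nutrient), sub_dt, 1.0,
            cap, params.uptake_linear_rate, _zeros(dims), mask, dval,
        )
    return n_field


def step_vegf(
    v_field: np.ndarray,
    dt: float,
    params: TransportParams,
    secretion: np.ndarray | None = None,
    ec_mask: np.ndarray | None = None,
    substep: bool = True,
) -> np.ndarray:
    """Advance the VEGF field by ``dt`` seconds (in place).

    ``secretion`` is the per-voxel secretion rate grid (pg/voxel/s) at
    hypoxic tumor voxels; EC voxels take VEGF up with cap ``e``.
    """
    dims = v_field.shape
    dmax = params.dt_max(params.d_vegf)
    n_sub, sub_dt = _substep_count(dt, dmax, enforce=not substep)
    decay = float(np.exp(-params.k_vegf * sub_dt))
    cap = _zeros(dims)
    if ec_mask is not None:
        cap[ec_mask.astype(bool)] = params.e_vox
    src = secretion if secretion is not None else _zeros(dims)
    mask = np.zeros(dims, dtype=np.uint8)
    for _ in range(n_sub):
        _kernels.ftcs_substep(
            v_field, params.d_vox(params.d_vegf), sub_dt, decay,
            cap, params.uptake_linear_rate, src, mask, _zeros(dims),
        )
    return v_field


def step_drug(
    c_field: np.ndarray,
    dt: float,
    params: TransportParams,
    infusing: bool = False,
    source_rate: float = 0.0,
    ec_mask: np.ndarray | None = None,
    uptake_cap: np.ndarray | None = None,
    substep: bool = True,
) -> np.ndarray:
    """Advance the drug field by ``dt`` seconds (in place).

    While ``infusing``, EC voxels release drug at ``source_rate`` (pg/voxel/s,
    already mapped from the protocol dose); proliferative tumor voxels take
    drug up subject to ``uptake_cap``; elsewhere R = 0.
    """
    dims = c_field.shape
    dmax = params.dt_max(params.d_drug)
    n_sub, sub_dt = _substep_count(dt, dmax, enforce=not substep)
    decay = float(np.exp(-params.k_drug * sub_dt))
    cap = uptake_cap if uptake_cap is not None else _zeros(dims)
    src = _zeros(dims)
    if infusing and ec_mask is not None and source_rate > 0:
        src[ec_mask.astype(bool)] = source_rate
    mask = np.zeros(dims, dtype=np.uint8)
    for _ in range(n_sub):
        _kernels.ftcs_substep(
            c_field, params.d_vox(params.d_drug), sub_dt, decay,
            cap, params.uptake_linear_rate, src, mask, _zeros(dims),
        )
    return c_field


def relax_to_quasi_steady(
    field: np.ndarray,
    d_um: float,
    params: TransportParams,
    uptake_cap: np.ndarray | None = None,
    source: np.ndarray | None = None,
    dirichlet_mask: np.ndarray | None = None,
    dirichlet_values: np.ndarray | float = 0.0,
    decay_rate: float = 0.0,
    tol: float = 1e-4,
    max_substeps: int | None = None,
    budget_seconds: float | None = 60.0,
) -> tuple[np.ndarray, int]:
    """Sub-cycle the explicit solver toward the quasi-steady field.

    Bridges the seconds-scale PDE to the minutes-scale Monte Carlo clock:
    iterate FTCS sub-steps (at the stability limit) until the maximum
    relative change per sub-step falls below ``tol``, the optional
    ``max_substeps`` cap is hit, or the integrated pseudo-time reaches
    ``budget_seconds``.  Returns (field, sub-steps taken).
    """
    if tol <= 0:
        raise ValueError("tolerance must be > 0")
    dims = field.shape
    dt = params.dt_max(d_um, safety=0.9)
    if budget_seconds is not None:
        n_budget = int(np.ceil(budget_seconds / dt))
    else:
        n_budget = np.iinfo(np.int64).max
    if max_substeps is not None:
        n_budget = min(n_budget, max_substeps)
    cap = uptake_cap if uptake_cap is not None else _zeros(dims)
    src = source if source is not None else _zeros(dims)
    mask = (dirichlet_mask.astype(np.uint8) if dirichlet_mask is not None
            else np.zeros(dims, dtype=np.uint8))
    if np.isscalar(dirichlet_values):
        dirichlet_values = np.full(dims, float(dirichlet_values))
    decay = float(np.exp(-decay_rate * dt))
    steps = 0
    while steps < n_budget:
        before = field.max()
        prev = field.copy()
        _kernels.ftcs_substep(
            field, params.d_vox(d_um), dt, decay,
            cap, params.uptake_linear_rate, src, mask, dirichlet_values,
        )
        steps += 1
        scale = max(before, field.max(), 1e-300)
        if np.abs(field - prev).max() <= tol * scale:
            break
    return field, steps


# ---------------------------------------------------------------------------
# implicit transport step (hour-scale fields: VEGF, drug)
# ---------------------------------------------------------------------------


def implicit_field_step(
    field: np.ndarray,
    d_um: float,
    dt: float,
    params: TransportParams,
    decay_rate: float = 0.0,
    source: np.ndarray | None = None,
    uptake_cap: np.ndarray | None = None,
    uptake_linear_rate: float | None = None,
    cg_tol: float = 1e-6,
) -> np.ndarray:
    """One backward-Euler step of dC/dt = D lap C - k C - R + S over ``dt``.

    Unconditionally stable, so suitable for fields whose dynamics span the
    minutes-to-hours scale of one Monte Carlo step (VEGF, drug), where the
    explicit scheme would need thousands of sub-steps.  Diffusion and decay
    are implicit (matrix-free conjugate gradient on the 7-point no-flux
    Laplacian); the capped uptake term is applied explicitly and clamped so
    it never overdraws a voxel.  Returns the field (updated in place).
    """
    from scipy.sparse.linalg import LinearOperator, cg

    dims = field.shape
    n = field.size
    d_vox = params.d_vox(d_um)

    if uptake_linear_rate is None:
        uptake_linear_rate = params.uptake_linear_rate
    rhs = field / dt
    if source is not None:
        rhs = rhs + source
    if uptake_cap is not None:
        rate = np.minimum(uptake_cap, uptake_linear_rate * field)
        rate = np.minimum(rate, field / dt)
        rhs = rhs - rate

    diag = 1.0 / dt + decay_rate
    buf = np.empty(n)

    def matvec(v):
        return _kernels.helmholtz_matvec(
            np.ascontiguousarray(v), buf, dims[0], dims[1], dims[2],
            diag, d_vox).copy()

    A = LinearOperator((n, n), matvec=matvec, dtype=np.float64)
    x, info = cg(A, rhs.ravel(), x0=field.ravel().copy(),
                 rtol=cg_tol, maxiter=1000)
    if info != 0:
        raise RuntimeError(f"implicit transport solve did not converge (info={info})")
    np.copyto(field, np.maximum(x.reshape(dims), 0.0))
    return field
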