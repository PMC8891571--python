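"""Simulation loop: signalling -> Potts dynamics -> fields -> therapy, per MCS.

Every Monte Carlo step (one minute of model time at the reference clock;
scaled fixtures compress the clock via ``minutes_per_mcs``):

1. each cell reads its microenvironment (contact fractions, mean nutrient /
   VEGF) and the Boolean network maps the receptor inputs to a phenotype;
2. the phenotype is applied to the Potts registry (cell type, chemotaxis,
   apoptotic shrink-out) and the nutrient-driven state machine advances
   (quiescence, necrosis, clearance), as does EC activation;
3. one Potts sweep of voxel copy attempts runs at temperature T_m;
4. licensed cells advance their growth schedule and divide when doubled;
5. the three reaction-diffusion fields relax toward their quasi-steady
   profiles and per-cell drug uptake accumulates;
6. therapy rules fire (drug kill transitions, targeted receptor blockade).

Daily trace records (tumor volume, state census, EC counts, field totals,
FKC) make up the SimulationTrace.  Runs are bitwise reproducible per seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import _kernels, boolean_network as bn, coupling, fields as flds
from . import lattice as lat
from . import therapy as ther
from .coupling import ReceptorThresholds
from .fields import FieldSet, TransportParams
from .lattice import AdhesionMatrix, CellLattice
from .scenarios import Scenario
from .therapy import TherapyProtocol

__all__ = ["SimulationParams", "SimulationTrace", "run_simulation",
           "growth_phase_segmentation", "LatticeOverflow"]

MINUTES_PER_DAY = 1440.0


class LatticeOverflow(RuntimeError):
    """Tumor reached the domain boundary (run stops cleanly with a flag)."""


@dataclass
class SimulationParams:
    """Everything tunable about the model dynamics.

    The defaults are the reference physical parameters; scaled test fixtures
    override ``minutes_per_mcs`` (time compression) and the field relaxation
    caps.  ``drug_theta_quiescent`` / ``drug_theta_necrotic`` are the
    cumulative-uptake kill thresholds in pg, calibrated once on the scaled
    vascular fixture (see scripts/calibrate_kill_thresholds.py).
    """

    t_m: float = 10.0
    adhesion_neighborhood: int = 1
    minutes_per_mcs: float = 1.0
    cycle_minutes: float = 1440.0          # fastest cell cycle: ~24 h
    tau_n_minutes: float = 2880.0          # sustained hypoxia -> necrosis
    tau_clear_minutes: float = 4320.0      # necrotic clearance
    # effective chemotactic weights used in the dynamics.  The catalogue
    # potentials (order 1e6 in their native units) act on concentration
    # differences many orders of magnitude below the pg/voxel field scale
    # used here; these defaults are the equivalent weights calibrated so a
    # typical near-tumor gradient contributes O(10) energy units (the same
    # order as T_m), which preserves the intended drift without letting the
    # chemotaxis term overwhelm the volume constraint.
    chi_m: float = -10.0
    chi_ec: float = -2000.0
    proliferation_requires_cadherin: bool = True
    vegf_from_necrotic: bool = True
    apc: int = 0
    nf1: int = 0
    drug_theta_quiescent: float = 17.0     # cumulative uptake (calibrated)
    drug_theta_necrotic: float = 42.0      # cumulative uptake (calibrated)
    # mitotically inhibited (drug-quiescent) cells die after this delay even
    # without further uptake: the arrested state progresses to necrosis
    drug_death_delay_minutes: float = 2880.0
    # avascular culture mode: ECM voxels replenish toward n0 at this rate
    # (1/s), emulating rate-limited perfusion of the chamber; growth arrests
    # when tumor consumption outgrows the perfusion capacity
    medium_refresh_rate: float = 1.0
    field_tol: float = 5e-4
    nutrient_substeps: int = 150
    nutrient_substeps_first: int = 2000
    vegf_substeps: int = 150
    drug_substeps: int = 150
    thresholds: ReceptorThresholds = dc_field(default_factory=ReceptorThresholds)
    transport: TransportParams = dc_field(default_factory=TransportParams)
    adhesion: AdhesionMatrix = dc_field(default_factory=AdhesionMatrix.default)

    @property
    def mcs_per_day(self) -> float:
        return MINUTES_PER_DAY / self.minutes_per_mcs

    @property
    def mcs_seconds(self) -> float:
        return self.minutes_per_mcs * 60.0

    @property
    def growth_increment(self) -> float:
        """Target-volume voxels gained per MCS by a licensed cycling cell."""
        return lat.INITIAL_CELL_VOLUME * self.minutes_per_mcs / self.cycle_minutes

    def config_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["adhesion"] = self.adhesion.J.tolist()
        return d


@dataclass
class SimulationTrace:
    """Daily records plus run metadata."""

    data: pd.DataFrame
    seed: int
    config: dict
    overflow: bool = False
    therapy_start_day: float | None = None
    therapy_end_day: float | None = None

    @property
    def days(self) -> np.ndarray:
        return self.data["day"].to_numpy()

    @property
    def volumes(self) -> np.ndarray:
        return self.data["tumor_voxels"].to_numpy()


def _beta_lut(params: SimulationParams) -> np.ndarray:
    """Per-type nutrient uptake caps, pg/voxel/s, indexed by type code."""
    tp = params.transport
    lut = np.zeros(6)
    lut[lat.TM] = lut[lat.TP] = tp.beta_p_vox
    lut[lat.TQ] = tp.beta_q_vox
    lut[lat.TN] = tp.per_voxel(tp.beta_n)
    return lut


def run_simulation(
    scenario: Scenario,
    protocol: TherapyProtocol | None = None,
    days: float = 10.0,
    seed: int = 0,
    params: SimulationParams | None = None,
    on_day=None,
) -> SimulationTrace:
    """Run the coupled model for ``days`` simulated days.

    ``on_day(day, lattice, fields)`` is an optional callback fired at every
    daily record (snapshotting hooks).  Two runs with identical inputs and
    seed produce bitwise-identical traces.
    """
    params = params or SimulationParams()
    protocol = protocol or TherapyProtocol()
    if protocol.kind == "chemo" and protocol.dose <= 0:
        protocol = TherapyProtocol()  # a zero-dose protocol is the null protocol
    if (protocol.kind == "targeted" and not protocol.blocked_receptors):
        protocol = TherapyProtocol()
    rng = np.random.default_rng(seed)
    lattice = scenario.lattice
    dims = lattice.dims
    tp = params.transport
    fields = FieldSet.initial(dims, tp)
    thr = params.thresholds
    net = bn.load_rules()
    pheno_map = {k: v.code for k, v in bn.input_output_map(net).items()}
    beta_lut = _beta_lut(params)
    boundary_mode = scenario.boundary_mode

    n_mcs_total = int(round(days * params.mcs_per_day))
    record_every = max(1, int(round(params.mcs_per_day)))
    minute = 0.0

    killed_cum = 0
    births_since_start = 0
    viable_at_start: float | None = None
    overflow = False
    records: list[dict] = []

    def viable_count():
        return sum(1 for r in lattice.cells.values()
                   if r.type in (lat.TP, lat.TM, lat.TQ))

    def record(day: float):
        cens = {t: 0 for t in (lat.EC, lat.TM, lat.TP, lat.TQ, lat.TN)}
        ec_active = 0
        for r in lattice.cells.values():
            cens[r.type] = cens.get(r.type, 0) + 1
            if r.type == lat.EC and r.ec_activated:
                ec_active += 1
        tumor_vox = int(sum(r.volume for r in lattice.cells.values()
                            if r.type in (lat.TM, lat.TP, lat.TQ, lat.TN)))
        vol_um3 = tumor_vox * lattice.voxel_size**3
        diam = (6.0 * vol_um3 / np.pi) ** (1.0 / 3.0)
        denom_ok = viable_at_start is not None and viable_at_start > 0
        records.append({
            "day": day,
            "mcs": int(round(day * params.mcs_per_day)),
            "tumor_voxels": tumor_vox,
            "volume_um3": vol_um3,
            "diameter_um": diam,
            "n_proliferating": cens[lat.TP],
            "n_migrating": cens[lat.TM],
            "n_quiescent": cens[lat.TQ],
            "n_necrotic": cens[lat.TN],
            "n_ec": cens[lat.EC],
            "n_ec_active": ec_active,
            "n_viable": cens[lat.TP] + cens[lat.TM] + cens[lat.TQ],
            "nutrient_total": float(fields.nutrient.sum()),
            "vegf_total": float(fields.vegf.sum()),
            "drug_total": float(fields.drug.sum()),
            "killed_cum": killed_cum,
            "births_since_start": births_since_start,
            "fkc": (min(1.0, killed_cum / (viable_at_start + births_since_start))
                    if denom_ok else 0.0),
        })
        if on_day is not None:
            on_day(day, lattice, fields)

    record(0.0)

    for step_i in range(n_mcs_total):
        minute += params.minutes_per_mcs
        therapy_on = (protocol.kind != "none"
                      and minute >= protocol.start_day * MINUTES_PER_DAY)
        if therapy_on and viable_at_start is None:
            viable_at_start = float(viable_count())
        block_on = protocol.block_active(minute)

        # 1-2. per-cell signalling, phenotype, state machine -----------------
        cell_type_arr, *_ = lattice.id_arrays()
        counts, nut_sum, veg_sum = _kernels.contact_and_field_tally(
            lattice.site_owner, cell_type_arr, fields.nutrient, fields.vegf,
            lattice._next_id,
        )
        licensed: list[int] = []
        for cid, rec in list(lattice.cells.items()):
            if rec.volume == 0:
                continue
            mean_nut = nut_sum[cid] / rec.volume
            mean_veg = veg_sum[cid] / rec.volume
            if rec.type == lat.EC:
                coupling.ec_activation(rec, mean_veg, thr, params.chi_ec)
                if rec.ec_activated:
                    if coupling.ve_cadherin_inhibition(counts[cid], thr):
                        rec.chem_field = _kernels.CHEM_NONE
                    else:
                        rec.chem_field = _kernels.CHEM_VEGF
                        licensed.append(cid)
                continue
            if rec.type == lat.TN:
                coupling.update_viability_state(
                    rec, False, mean_nut, thr, params.minutes_per_mcs,
                    params.tau_n_minutes, params.tau_clear_minutes)
                continue
            quiescent = rec.type == lat.TQ
            inputs = coupling.receptor_inputs(
                counts[cid], mean_nut, thr, quiescent=quiescent,
                apc=params.apc, nf1=params.nf1)
            inputs = ther.targeted_block(protocol, inputs, minute)
            rec.receptor_inputs = inputs
            rtk_on = bool(inputs[1])
            state = coupling.update_viability_state(
                rec, rtk_on, mean_nut, thr, params.minutes_per_mcs,
                params.tau_n_minutes, params.tau_clear_minutes)
            # the network sees cycling cells; quiescence itself is invisible
            # to it, but an active receptor blockade re-evaluates everyone
            if state == "viable" or (block_on and state == "quiescent"):
                code = pheno_map[inputs]
                was_alive = rec.target_volume > 0
                coupling.apply_phenotype(rec, code, params.chi_m)
                if code in (10, 11):
                    if was_alive and therapy_on and block_on:
                        killed_cum += 1
                    continue
                if rec.type in (lat.TP, lat.TM):
                    cad_on = bool(inputs[2])
                    if (code in (1100, 1101)
                            and (cad_on or not params.proliferation_requires_cadherin)):
                        licensed.append(cid)
            # drug kill rule
            if protocol.kind in ("chemo", "combination"):
                if rec.drug_quiescent and rec.type == lat.TQ:
                    rec.hypoxia_minutes = 0.0  # arrested, not hypoxic
                    rec.drug_arrest_minutes += params.minutes_per_mcs
                    if rec.drug_arrest_minutes >= params.drug_death_delay_minutes:
                        rec.type = lat.TN
                        rec.elasticity = lat.DEFAULT_GAMMA[lat.TN]
                        rec.necrosis_minutes = 0.0
                        killed_cum += 1
                        continue
                trans = ther.drug_kill_update(
                    rec, params.drug_theta_quiescent, params.drug_theta_necrotic)
                if trans == "necrotic":
                    killed_cum += 1

        # 3. Potts sweep -----------------------------------------------------
        lat.monte_carlo_step(
            lattice, params.adhesion, params.t_m, rng,
            nutrient=fields.nutrient, vegf=fields.vegf,
            adhesion_neighborhood=params.adhesion_neighborhood,
        )

        # 4. growth & division ------------------------------------------------
        for cid in licensed:
            if cid not in lattice.cells:
                continue
            daughter = lat.grow_and_divide(
                lattice, cid, rng, params.growth_increment)
            if daughter is not None and viable_at_start is not None:
                births_since_start += 1

        # 5. fields ------------------------------------------------------------
        type_grid = lattice.type_grid()
        nut_cap = beta_lut[type_grid]
        ec_mask = (type_grid == lat.EC)
        nut_src = None
        if boundary_mode == "culture":
            dmask = np.zeros(dims, dtype=np.uint8)
            nut_src = np.where(type_grid == lat.MEDIUM,
                               params.medium_refresh_rate
                               * np.maximum(tp.n0 - fields.nutrient, 0.0), 0.0)
        elif boundary_mode == "faces":
            dmask = np.zeros(dims, dtype=np.uint8)
            dmask[0], dmask[-1] = 1, 1
            dmask[:, 0], dmask[:, -1] = 1, 1
            dmask[:, :, 0], dmask[:, :, -1] = 1, 1
        else:
            dmask = ec_mask.astype(np.uint8)
        dvals = np.full(dims, tp.n0)
        cap_first = params.nutrient_substeps_first if step_i == 0 else params.nutrient_substeps
        flds.relax_to_quasi_steady(
            fields.nutrient, tp.d_nutrient, tp, uptake_cap=nut_cap,
            source=nut_src, dirichlet_mask=dmask, dirichlet_values=dvals,
            tol=params.field_tol, max_substeps=cap_first, budget_seconds=None)

        # VEGF and drug evolve on the minutes-to-hours scale of one MCS:
        # one unconditionally stable implicit step per MCS each
        secr = np.zeros(dims)
        hypoxic_types = [lat.TQ] + ([lat.TN] if params.vegf_from_necrotic else [])
        hyp_mask = np.isin(type_grid, hypoxic_types)
        if hyp_mask.any():
            secr[hyp_mask] = tp.s_vegf / 60.0  # pg/voxel/s (rate per ref. minute)
        vcap = np.zeros(dims)
        vcap[ec_mask] = tp.e_vox
        if hyp_mask.any() or fields.vegf.any():
            flds.implicit_field_step(
                fields.vegf, tp.d_vegf, params.mcs_seconds, tp,
                decay_rate=tp.k_vegf, source=secr, uptake_cap=vcap)

        if protocol.kind in ("chemo", "combination") and protocol.dose > 0:
            dcap = np.zeros(dims)
            prolif_mask = np.isin(type_grid, (lat.TP, lat.TM))
            dcap[prolif_mask] = tp.kappa_p_vox
            dsrc = None
            if protocol.infusing(minute):
                dsrc = np.zeros(dims)
                dsrc[ec_mask] = tp.per_voxel_drug(
                    ther.dose_to_source_rate(protocol.dose))
            if dsrc is not None or fields.drug.any():
                if fields.drug.any():
                    uptake = _kernels.uptake_tally(
                        fields.drug, lattice.site_owner, dcap,
                        tp.drug_uptake_linear_rate, params.mcs_seconds,
                        lattice._next_id)
                    for cid, rec in lattice.cells.items():
                        if uptake[cid] > 0:
                            rec.cum_drug += float(uptake[cid])
                flds.implicit_field_step(
                    fields.drug, tp.d_drug, params.mcs_seconds, tp,
                    decay_rate=tp.k_drug, source=dsrc, uptake_cap=dcap,
                    uptake_linear_rate=tp.drug_uptake_linear_rate)

        # 6. bookkeeping -------------------------------------------------------
        if (step_i + 1) % record_every == 0:
            day = (step_i + 1) / params.mcs_per_day
            record(day)
            if _touches_boundary(lattice):
                overflow = True
                break

    therapy_end = None
    if protocol.kind in ("chemo", "combination"):
        therapy_end = protocol.start_day + protocol.cycle_days * protocol.n_cycles
    elif protocol.kind == "targeted":
        therapy_end = protocol.block_end_day
    return SimulationTrace(
        data=pd.DataFrame.from_records(records),
        seed=seed,
        config=params.config_dict(),
        overflow=overflow,
        therapy_start_day=(protocol.start_day if protocol.kind != "none" else None),
        therapy_end_day=therapy_end,
    )


def _touches_boundary(lattice: CellLattice) -> bool:
    """True when the main tumor mass (largest face-connected component of
    tumor tissue) reaches a domain face; stray single cells that wander to
    the wall do not end the run."""
    from scipy import ndimage
    tumor = lattice.type_grid() >= lat.TM
    if not tumor.any():
        return False
    labels, k = ndimage.label(tumor, structure=ndimage.generate_binary_structure(3, 1))
    if k == 0:
        return False
    sizes = ndimage.sum_labels(tumor, labels, index=range(1, k + 1))
    main = int(np.argmax(sizes)) + 1
    m = labels == main
    return bool(m[0].any() or m[-1].any() or m[:, 0].any() or m[:, -1].any()
                or m[:, :, 0].any() or m[:, :, -1].any())


# ---------------------------------------------------------------------------
# trace analysis
# ---------------------------------------------------------------------------


def growth_phase_segmentation(
    days: np.ndarray,
    volumes: np.ndarray,
    min_points: int = 4,
) -> dict:
    """Fit a continuous 3-segment piecewise-linear model to log-volume.

    Least squares over a grid of breakpoint pairs; returns the fitted
    breakpoints (days), the three slopes (per day, on log volume) and the
    residual.  Requires at least ``min_points`` samples per segment.
    """
    days = np.asarray(days, dtype=float)
    vols = np.asarray(volumes, dtype=float)
    if len(days) < 3 * min_points:
        raise ValueError(
            f"need >= {3 * min_points} samples for 3 segments of {min_points}")
    y = np.log(np.maximum(vols, 1.0))
    best = None
    n = len(days)
    for i in range(min_points, n - 2 * min_points + 1):
        for j in range(i + min_points, n - min_points + 1):
            b1, b2 = days[i], days[j]
            X = np.column_stack([
                np.ones_like(days), days,
                np.maximum(days - b1, 0.0), np.maximum(days - b2, 0.0)])
            beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            sse = float(((X @ beta - y) ** 2).sum())
            if best is None or sse < best["sse"]:
                best = {
                    "sse": sse,
                    "breakpoints": (b1, b2),
                    "slopes": (float(beta[1]),
                               float(beta[1] + beta[2]),
                               float(beta[1] + beta[2] + beta[3])),
                }
    if best is None:
        raise ValueError("no admissible breakpoint pair")
    return best
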