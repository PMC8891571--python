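"""Microenvironment -> receptor inputs -> phenotype -> cell behaviour.

Each cell reads its microenvironment once per Monte Carlo step:

* E-cadherin: ON when the fraction of its boundary in contact with other
  viable tumor cells reaches ``t_cadherin`` (cell-cell junction signalling).
* Integrin: ON when the fraction of boundary contacting ECM reaches ``t_itg``.
* Wnt: ON when the cadherin contact fraction falls below ``t_wnt`` (Wnt
  signalling is licensed by E-cadherin loss).
* RTK: ON when the mean nutrient over the cell's voxels reaches ``t_rtk``
  (``t_rtk_q`` for currently quiescent cells: hysteresis on re-entry).
* APC / NF1: scenario or therapy flags (both OFF by default: tumor cells).

The resulting 6-bit input drives the Boolean network to its attractor and
the 4-bit phenotype is mapped onto Potts behaviour: proliferative (P),
migrating (M, chemotactic along nutrient), or apoptotic (target volume 0,
removal on shrink-out).  Independent of the network, nutrient starvation
moves viable cells through quiescence (Q) into necrosis (N), and endothelial
cells activate on local VEGF with VE-cadherin contact inhibition of stalk
proliferation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import lattice as lat
from ._kernels import CHEM_NONE, CHEM_NUTRIENT, CHEM_VEGF

__all__ = [
    "ReceptorThresholds", "receptor_inputs", "apply_phenotype",
    "update_viability_state", "ec_activation", "ve_cadherin_inhibition",
    "UnreachablePhenotypeError",
]


class UnreachablePhenotypeError(RuntimeError):
    """Phenotype code outside the reachable attractor set (defensive)."""


@dataclass
class ReceptorThresholds:
    """Signal-activation thresholds (concentrations in pg/voxel, fractions
    dimensionless)."""

    t_rtk: float = 4.48e-3
    t_rtk_q: float = 8.96e-3       # quiescent cells need more to re-enter the cycle
    t_itg: float = 0.3
    t_cadherin: float = 0.3
    t_wnt: float = 0.15
    t_vegf: float = 0.00095        # EC activation threshold
    theta_ve: float = 0.25         # VE-cadherin junction fraction blocking EC growth

    def __post_init__(self):
        for name in ("t_rtk", "t_rtk_q", "t_itg", "t_cadherin", "t_wnt",
                     "t_vegf", "theta_ve"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.t_rtk_q < self.t_rtk:
            raise ValueError("t_rtk_q must be >= t_rtk (hysteresis)")


def contact_fractions(counts_row: np.ndarray) -> tuple[float, float, float]:
    """(viable-tumor, EC, ECM) boundary contact fractions from a tally row
    of (total, viable, EC, ECM, necrotic) face counts."""
    total = counts_row[0]
    if total == 0:
        return 0.0, 0.0, 1.0
    return (counts_row[1] / total, counts_row[2] / total, counts_row[3] / total)


def receptor_inputs(
    counts_row: np.ndarray,
    mean_nutrient: float,
    thresholds: ReceptorThresholds,
    quiescent: bool = False,
    apc: int = 0,
    nf1: int = 0,
) -> tuple[int, int, int, int, int, int]:
    """6-bit receptor input (integrin, RTK, E-cadherin, Wnt, APC, NF1)."""
    cad_frac, _, ecm_frac = contact_fractions(counts_row)
    cadherin = 1 if cad_frac >= thresholds.t_cadherin else 0
    integrin = 1 if ecm_frac >= thresholds.t_itg else 0
    wnt = 1 if cad_frac < thresholds.t_wnt else 0
    t_rtk = thresholds.t_rtk_q if quiescent else thresholds.t_rtk
    rtk = 1 if mean_nutrient >= t_rtk else 0
    return (integrin, rtk, cadherin, wnt, int(bool(apc)), int(bool(nf1)))


#: the phenotype codes reachable from the signalling network
REACHABLE_CODES = frozenset({1100, 1101, 10, 11})


def apply_phenotype(
    rec: lat.CellRecord,
    code: int,
    chi_m: float = lat.CHI_M,
) -> None:
    """Translate a phenotype code onto Potts behaviour flags for a tumor cell.

    1100: proliferative type, no chemotaxis.  1101: additionally migrating
    (M type, nutrient chemotaxis).  0010/0011: apoptosis -- the target volume
    is set to zero and the cell shrinks away.  Necrotic and drug-quiescent
    cells are not re-phenotyped here (their state machine owns them).
    """
    if rec.type in (lat.TN, lat.EC):
        return
    if code not in REACHABLE_CODES:
        raise UnreachablePhenotypeError(f"phenotype code {code:04d} is not reachable")
    rec.phenotype_code = code
    if code in (10, 11):  # apoptosis (0010 / 0011)
        rec.target_volume = 0.0
        rec.chem_field = CHEM_NONE
        rec.chi = 0.0
        return
    if code == 1101 and not rec.drug_quiescent:
        rec.type = lat.TM
        rec.elasticity = lat.DEFAULT_GAMMA[lat.TM]
        rec.chi = chi_m
        rec.chem_field = CHEM_NUTRIENT
    else:  # 1100
        if rec.type == lat.TM:
            rec.type = lat.TP
        rec.chi = 0.0
        rec.chem_field = CHEM_NONE
    # a surviving cell whose target collapsed (interrupted apoptosis, e.g. a
    # lifted receptor blockade) re-establishes its homeostatic volume
    if rec.target_volume < 1.0:
        rec.target_volume = float(min(max(rec.volume, 1), rec.initial_volume))


def update_viability_state(
    rec: lat.CellRecord,
    rtk_on: bool,
    mean_nutrient: float,
    thresholds: ReceptorThresholds,
    dt_minutes: float,
    tau_n_minutes: float = 2880.0,
    tau_clear_minutes: float = 7200.0,
) -> str:
    """Advance the nutrient-driven state machine for one tumor cell.

    P/M -> Q when the RTK signal is lost; Q -> P when the mean nutrient
    clears the higher re-entry threshold; Q -> N after ``tau_n`` minutes of
    sustained hypoxia; N is absorbing and cleared (shrunk away) after
    ``tau_clear`` minutes.  Returns the resulting state name.
    """
    if rec.type == lat.TN:
        rec.necrosis_minutes += dt_minutes
        if rec.necrosis_minutes >= tau_clear_minutes:
            rec.target_volume = 0.0  # clearance: shrink-out and removal
        return "necrotic"
    if rec.type in (lat.TP, lat.TM):
        if not rtk_on:
            rec.type = lat.TQ
            rec.elasticity = lat.DEFAULT_GAMMA[lat.TQ]
            rec.chi = 0.0
            rec.chem_field = CHEM_NONE
            rec.hypoxia_minutes = 0.0
            return "quiescent"
        return "viable"
    if rec.type == lat.TQ:
        if not rec.drug_quiescent and mean_nutrient >= thresholds.t_rtk_q:
            rec.type = lat.TP
            rec.elasticity = lat.DEFAULT_GAMMA[lat.TP]
            rec.hypoxia_minutes = 0.0
            return "viable"
        rec.hypoxia_minutes += dt_minutes
        if rec.hypoxia_minutes >= tau_n_minutes:
            rec.type = lat.TN
            rec.elasticity = lat.DEFAULT_GAMMA[lat.TN]
            rec.chi = 0.0
            rec.chem_field = CHEM_NONE
            return "necrotic"
        return "quiescent"
    return "viable"


def ec_activation(
    rec: lat.CellRecord,
    mean_vegf: float,
    thresholds: ReceptorThresholds,
    chi_ec: float = lat.CHI_EC,
) -> bool:
    """Activate a quiescent vessel EC when local VEGF reaches the threshold.

    Activated ECs become tip-capable: chemotactic along the VEGF gradient and
    allowed to proliferate subject to VE-cadherin contact inhibition.
    Activation is sticky (an activated EC stays responsive).
    """
    if rec.type != lat.EC:
        return False
    if rec.ec_activated or mean_vegf >= thresholds.t_vegf:
        rec.ec_activated = True
        rec.chi = chi_ec
        rec.chem_field = CHEM_VEGF
        return True
    return False


def ve_cadherin_inhibition(
    counts_row: np.ndarray,
    thresholds: ReceptorThresholds,
) -> bool:
    """True when EC-EC junctions block proliferation (contact inhibition).

    The EC boundary fraction in contact with other ECs is compared with the
    junction threshold ``theta_ve``; at or above it, growth and the VEGF
    response of a stalk cell are suppressed.
    """
    if thresholds.theta_ve >= 1.0:
        return False  # degenerate configuration: inhibition disabled
    total = counts_row[0]
    if total == 0:
        return True
    ec_frac = counts_row[2] / total
    return ec_frac >= thresholds.theta_ve
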