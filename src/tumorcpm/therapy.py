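"""Chemotherapy schedules, drug-induced kill rules, targeted blockade, FKC.

Chemotherapy is dosed per body-surface area (ug/m^2) and mapped linearly
onto the vascular drug source interval (5 ug/m^2 -> 2.55e-16, 10 ug/m^2 ->
5.1e-16 mol/cell/s); each cycle releases drug from vessel ECs during a
24-hour infusion window at the cycle start.  Proliferative tumor cells take
drug up; accumulated uptake first forces a cell quiescent (mitotic
inhibition) and ultimately necrotic.  Targeted therapy forces selected
receptor inputs OFF so the signalling network drives cells into the
apoptosis attractor.  Treatment efficacy is tracked by the fraction of
killed cells (FKC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = [
    "TherapyProtocol", "TreatmentOutcome", "dose_to_source_rate",
    "dose_timeseries", "drug_kill_update", "targeted_block",
    "fkc", "classify_outcome",
]

MINUTES_PER_DAY = 1440.0

#: linear BSA-dose -> vascular source map, mol/cell/s per (ug/m^2)
SD_PER_DOSE = 5.1e-17


@dataclass(frozen=True)
class TherapyProtocol:
    """One treatment protocol.

    ``kind`` is one of none/chemo/targeted/combination.  ``dose`` is the
    per-cycle chemotherapy dose in ug/m^2 (5, 7.5 and 10 in the reference
    scenarios); ``cycle_days`` the cycle period (7 standard, 10 for an MTD
    regimen, 6 metronomic); ``start_day`` when the first cycle begins.
    ``blocked_receptors`` names receptor inputs forced OFF during the block
    window [block_start_day, block_end_day) for targeted/combination kinds.
    """

    kind: str = "none"
    dose: float = 0.0
    cycle_days: float = 7.0
    n_cycles: int = 5
    start_day: float = 62.0
    infusion_hours: float = 24.0
    blocked_receptors: frozenset = dc_field(default_factory=frozenset)
    block_start_day: float = 0.0
    block_end_day: float = 0.0

    _VALID_BLOCK = frozenset({"RTK", "Integrin", "E-cadherin", "Wnt"})

    def __post_init__(self):
        if self.kind not in ("none", "chemo", "targeted", "combination"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.dose < 0 or self.start_day < 0:
            raise ValueError("dose and start_day must be >= 0")
        bad = set(self.blocked_receptors) - self._VALID_BLOCK
        if bad:
            raise ValueError(f"unknown blocked receptors {sorted(bad)}")
        if self.blocked_receptors and self.kind not in ("targeted", "combination"):
            raise ValueError("blocked_receptors requires a targeted/combination kind")

    # -- schedule ----------------------------------------------------------

    def infusing(self, minute: float) -> bool:
        """Is the vascular drug source active at this simulation minute?"""
        if self.kind not in ("chemo", "combination") or self.dose <= 0:
            return False
        t = minute - self.start_day * MINUTES_PER_DAY
        if t < 0:
            return False
        cycle_min = self.cycle_days * MINUTES_PER_DAY
        cycle_idx = int(t // cycle_min)
        if cycle_idx >= self.n_cycles:
            return False
        return (t - cycle_idx * cycle_min) < self.infusion_hours * 60.0

    def block_active(self, minute: float) -> bool:
        if self.kind not in ("targeted", "combination") or not self.blocked_receptors:
            return False
        day = minute / MINUTES_PER_DAY
        return self.block_start_day <= day < self.block_end_day

    @property
    def total_dose(self) -> float:
        return self.dose * self.n_cycles


def dose_to_source_rate(dose: float) -> float:
    """Map a BSA dose (ug/m^2) to the vascular drug source (mol/cell/s).

    Linear through the calibrated interval; doses outside [0, 10] ug/m^2
    extrapolate linearly with a warning.
    """
    if dose < 0 or dose > 10:
        warnings.warn(
            f"dose {dose} ug/m^2 outside the calibrated range [0, 10]; "
            "extrapolating linearly", stacklevel=2,
        )
    return SD_PER_DOSE * dose


def dose_timeseries(
    protocol: TherapyProtocol,
    total_minutes: float,
    minutes_per_step: float = 1.0,
) -> np.ndarray:
    """Per-step vascular source activity s_c(t) in mol/cell/s."""
    n = int(np.ceil(total_minutes / minutes_per_step))
    rate = dose_to_source_rate(protocol.dose)
    out = np.zeros(n)
    for i in range(n):
        if protocol.infusing(i * minutes_per_step):
            out[i] = rate
    return out


def drug_kill_update(
    cell,
    theta_quiescent: float,
    theta_necrotic: float,
) -> str | None:
    """Apply the cumulative-uptake kill rule to one tumor cell.

    Only proliferative/migrating cells accumulate drug (the uptake term is
    restricted to them), so the transition tests the cell's running
    ``cum_drug`` total: above ``theta_quiescent`` the cell is forced into
    drug-induced quiescence; above ``theta_necrotic`` it becomes necrotic.
    Returns the transition applied ("quiescent"/"necrotic") or None.
    """
    from . import lattice as lat

    if cell.type not in (lat.TP, lat.TM, lat.TQ):
        return None
    if cell.cum_drug >= theta_necrotic:
        cell.type = lat.TN
        cell.elasticity = lat.DEFAULT_GAMMA[lat.TN]
        cell.chi = 0.0
        cell.chem_field = 0
        cell.necrosis_minutes = 0.0
        return "necrotic"
    if cell.cum_drug >= theta_quiescent and cell.type in (lat.TP, lat.TM):
        cell.type = lat.TQ
        cell.elasticity = lat.DEFAULT_GAMMA[lat.TQ]
        cell.chi = 0.0
        cell.chem_field = 0
        cell.drug_quiescent = True
        return "quiescent"
    return None


def targeted_block(
    protocol: TherapyProtocol,
    inputs: tuple[int, int, int, int, int, int],
    minute: float,
) -> tuple[int, int, int, int, int, int]:
    """Force blocked receptor inputs OFF while the block window is active.

    Input order: (integrin, RTK, E-cadherin, Wnt, APC, NF1).
    """
    if not protocol.block_active(minute):
        return inputs
    idx = {"Integrin": 0, "RTK": 1, "E-cadherin": 2, "Wnt": 3}
    out = list(inputs)
    for name in protocol.blocked_receptors:
        out[idx[name]] = 0
    return tuple(out)


@dataclass
class TreatmentOutcome:
    fkc: np.ndarray              # per-record FKC
    volume: np.ndarray           # per-record tumor volume (voxels)
    classification: str          # eradicated / dormant / relapse / failure


def fkc(
    killed_cum: np.ndarray,
    viable_at_start: float,
    births_since_start: np.ndarray,
) -> np.ndarray:
    """Fraction of killed cells time series.

    FKC(t) = kills attributable to therapy up to t, divided by the at-risk
    population (viable cells when therapy started plus cells born since),
    clamped to [0, 1].
    """
    if viable_at_start <= 0:
        raise ValueError("therapy baseline has no viable cells (never started?)")
    denom = viable_at_start + np.asarray(births_since_start, dtype=float)
    out = np.asarray(killed_cum, dtype=float) / denom
    return np.clip(out, 0.0, 1.0)


def classify_outcome(
    days: np.ndarray,
    viable_counts: np.ndarray,
    volumes: np.ndarray,
    therapy_start_day: float,
    therapy_end_day: float,
    dormancy_band: float = 0.2,
    dormancy_days: float = 30.0,
) -> str:
    """Classify the treatment outcome from a daily trace.

    eradicated: no viable tumor cells at the end.  dormant: volume stays
    within +-``dormancy_band`` of the post-therapy nadir for at least
    ``dormancy_days``.  relapse: regrowth beyond the pre-therapy volume
    after a nadir.  failure: monotone growth through therapy.
    """
    days = np.asarray(days, dtype=float)
    viable = np.asarray(viable_counts, dtype=float)
    vol = np.asarray(volumes, dtype=float)
    if days[-1] < therapy_end_day + dormancy_days:
        raise ValueError("trace must extend >= 30 days past the last cycle")
    if viable[-1] == 0:
        return "eradicated"
    pre_mask = days <= therapy_start_day
    baseline = vol[pre_mask][-1] if pre_mask.any() else vol[0]
    post = days >= therapy_start_day
    post_vol = vol[post]
    post_days = days[post]
    nadir_idx = int(np.argmin(post_vol))
    nadir = post_vol[nadir_idx]
    if post_vol[nadir_idx:].size and post_vol[-1] > baseline and nadir < baseline:
        return "relapse"
    after = post_days >= post_days[nadir_idx]
    window = post_days[after] - post_days[after][0]
    in_band = np.abs(post_vol[after] - nadir) <= dormancy_band * max(nadir, 1.0)
    if window.size and window[in_band].size and window[in_band].max() >= dormancy_days:
        return "dormant"
    diffs = np.diff(vol)
    if (diffs >= 0).all():
        return "failure"
    return "failure"
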