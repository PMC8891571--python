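"""Therapy protocols: dosing schedules, kill rules, blockade, FKC, outcomes."""

import numpy as np
import pytest

from tumorcpm import lattice as lat
from tumorcpm import therapy as ther
from tumorcpm.lattice import CellRecord
from tumorcpm.therapy import TherapyProtocol


def _cell(type_code=lat.TP, cum=0.0):
    rec = CellRecord(id=1, type=type_code, volume=64, target_volume=64.0,
                     elasticity=8.0)
    rec.cum_drug = cum
    return rec


# -- protocol ---------------------------------------------------------------


def test_protocol_validation():
    with pytest.raises(ValueError):
        TherapyProtocol(kind="magic")
    with pytest.raises(ValueError):
        TherapyProtocol(kind="chemo", dose=-1)
    with pytest.raises(ValueError):
        TherapyProtocol(kind="chemo", blocked_receptors=frozenset({"RTK"}))
    with pytest.raises(ValueError):
        TherapyProtocol(kind="targeted", blocked_receptors=frozenset({"Bax"}))


def test_infusion_windows():
    p = TherapyProtocol(kind="chemo", dose=5.0, cycle_days=7.0, n_cycles=2,
                        start_day=10.0, infusion_hours=24.0)
    day = 1440.0
    assert not p.infusing(9 * day)
    assert p.infusing(10 * day)           # first infusion begins
    assert p.infusing(10.9 * day)
    assert not p.infusing(11.5 * day)     # between infusions
    assert p.infusing(17.5 * day)         # second cycle
    assert not p.infusing(24.5 * day)     # beyond the last cycle


def test_total_dose_bookkeeping():
    p = TherapyProtocol(kind="chemo", dose=7.5, n_cycles=5)
    assert p.total_dose == pytest.approx(37.5)


# -- dose mapping ------------------------------------------------------------


@pytest.mark.parametrize("dose,expected", [
    (0.0, 0.0),
    (5.0, 2.55e-16),
    (7.5, 3.825e-16),
    (10.0, 5.1e-16),
])
def test_dose_maps_linearly_to_source_interval(dose, expected):
    assert ther.dose_to_source_rate(dose) == pytest.approx(expected)


def test_dose_outside_range_warns():
    with pytest.warns(UserWarning, match="outside"):
        ther.dose_to_source_rate(12.0)


def test_dose_timeseries_matches_schedule():
    p = TherapyProtocol(kind="chemo", dose=10.0, cycle_days=2.0, n_cycles=2,
                        start_day=1.0, infusion_hours=24.0)
    ts = ther.dose_timeseries(p, total_minutes=6 * 1440.0, minutes_per_step=60.0)
    active = ts > 0
    # two 24 h infusions: minutes [1440, 2880) and [4320, 5760)
    assert active[24:48].all() and active[72:96].all()
    assert not active[:24].any() and not active[48:72].any()
    assert np.allclose(ts[active], 5.1e-16)


# -- kill rule ---------------------------------------------------------------


def test_quiescent_cells_do_not_take_up_drug():
    rec = _cell(lat.TQ, cum=0.0)
    assert ther.drug_kill_update(rec, 1.0, 2.0) is None
    assert rec.type == lat.TQ


def test_uptake_over_theta1_forces_quiescence():
    rec = _cell(cum=1.5)
    assert ther.drug_kill_update(rec, 1.0, 10.0) == "quiescent"
    assert rec.type == lat.TQ and rec.drug_quiescent


def test_uptake_over_theta2_is_lethal():
    rec = _cell(cum=12.0)
    assert ther.drug_kill_update(rec, 1.0, 10.0) == "necrotic"
    assert rec.type == lat.TN


def test_ec_cells_unaffected_by_kill_rule():
    rec = _cell(lat.EC, cum=100.0)
    assert ther.drug_kill_update(rec, 1.0, 2.0) is None


# -- targeted blockade -------------------------------------------------------


def test_block_forces_receptors_off():
    p = TherapyProtocol(kind="targeted", blocked_receptors=frozenset({"RTK"}),
                        block_start_day=0.0, block_end_day=10.0)
    inputs = (1, 1, 1, 0, 0, 0)
    out = ther.targeted_block(p, inputs, minute=1440.0)
    assert out == (1, 0, 1, 0, 0, 0)


def test_block_noop_outside_window_or_empty():
    p = TherapyProtocol(kind="targeted", blocked_receptors=frozenset({"RTK"}),
                        block_start_day=5.0, block_end_day=6.0)
    inputs = (1, 1, 1, 0, 0, 0)
    assert ther.targeted_block(p, inputs, minute=0.0) == inputs
    none = TherapyProtocol()
    assert ther.targeted_block(none, inputs, minute=0.0) == inputs


# -- FKC ---------------------------------------------------------------------


def test_fkc_trivial_bounds():
    assert ther.fkc(np.array([0, 0]), 10.0, np.array([0, 0])).tolist() == [0, 0]
    assert ther.fkc(np.array([10]), 10.0, np.array([0]))[0] == 1.0
    with pytest.raises(ValueError):
        ther.fkc(np.array([1]), 0.0, np.array([0]))


def test_fkc_monotone_without_births():
    kills = np.array([0, 1, 3, 3, 7, 9])
    out = ther.fkc(kills, 20.0, np.zeros(6))
    assert (np.diff(out) >= 0).all()


def test_fkc_tracks_exponential_kill_on_well_mixed_toy():
    """Constant-hazard kill of 1000 cells: FKC ~ 1 - e^{-kt} within 5%."""
    rng = np.random.default_rng(314)
    n0, k, dt = 1000, 0.25, 0.05
    alive = np.ones(n0, dtype=bool)
    killed, times = [], []
    t = 0.0
    for _ in range(200):
        t += dt
        die = alive & (rng.random(n0) < 1 - np.exp(-k * dt))
        alive &= ~die
        killed.append(n0 - alive.sum())
        times.append(t)
    out = ther.fkc(np.array(killed), float(n0), np.zeros(len(killed)))
    expected = 1 - np.exp(-k * np.array(times))
    assert np.abs(out - expected).max() < 0.05


# -- outcome classification --------------------------------------------------


def _days(n):
    return np.arange(n, dtype=float)


def test_classify_eradicated():
    days = _days(80)
    viable = np.where(days < 30, 50, 0)
    vol = np.where(days < 30, 1000, 0)
    assert ther.classify_outcome(days, viable, vol, 10.0, 40.0) == "eradicated"


def test_classify_relapse_on_v_shape():
    days = _days(120)
    vol = 1000 + np.where(days < 40, 0, np.where(days < 60, -(days - 40) * 30,
                          -600 + (days - 60) * 40))
    viable = np.full_like(days, 30)
    assert ther.classify_outcome(days, viable, vol, 30.0, 70.0) == "relapse"


def test_classify_failure_on_monotone_growth():
    days = _days(100)
    vol = 1000 + days * 25
    viable = np.full_like(days, 50)
    assert ther.classify_outcome(days, viable, vol, 20.0, 55.0) == "failure"


def test_classify_dormant_plateau():
    days = _days(120)
    vol = np.where(days < 30, 1000.0, 400.0)
    viable = np.full_like(days, 20)
    assert ther.classify_outcome(days, viable, vol, 20.0, 50.0) == "dormant"


def test_classify_requires_followup():
    days = _days(30)
    with pytest.raises(ValueError):
        ther.classify_outcome(days, days, days, 10.0, 25.0)
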