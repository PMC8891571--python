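"""Receptor readout, phenotype application and the viability state machine."""

import numpy as np
import pytest

from tumorcpm import _kernels, coupling
from tumorcpm import lattice as lat
from tumorcpm.coupling import ReceptorThresholds
from tumorcpm.lattice import CellLattice, CellRecord


@pytest.fixture()
def thr():
    return ReceptorThresholds()


def _tally(latt):
    ct, *_ = latt.id_arrays()
    zeros = np.zeros(latt.dims)
    return _kernels.contact_and_field_tally(
        latt.site_owner, ct, zeros, zeros, latt._next_id)[0]


# -- receptor inputs ---------------------------------------------------------


def test_isolated_cell_reads_integrin_and_wnt(thr):
    latt = CellLattice((8, 8, 8))
    latt.add_cell(np.argwhere(np.ones((2, 2, 2), bool)) + 3, lat.TP)
    counts = _tally(latt)
    itg, rtk, cad, wnt, apc, nf1 = coupling.receptor_inputs(
        counts[1], mean_nutrient=1.0, thresholds=thr)
    assert (itg, cad, wnt) == (1, 0, 1)
    assert rtk == 1 and apc == 0 and nf1 == 0


def test_interior_cell_reads_cadherin_not_integrin(thr):
    # a 3x1x1 line of cells: the middle one touches only other tumor cells
    latt = CellLattice((6, 2, 2))
    latt.add_cell(np.array([[0, 0, 0], [0, 1, 0], [0, 0, 1], [0, 1, 1]]), lat.TP)
    latt.add_cell(np.array([[1, 0, 0], [1, 1, 0], [1, 0, 1], [1, 1, 1]]), lat.TP)
    latt.add_cell(np.array([[2, 0, 0], [2, 1, 0], [2, 0, 1], [2, 1, 1]]), lat.TP)
    counts = _tally(latt)
    itg, _, cad, wnt, *_ = coupling.receptor_inputs(counts[2], 1.0, thr)
    frac_cad = counts[2][1] / counts[2][0]
    assert frac_cad >= thr.t_cadherin
    assert cad == 1 and wnt == 0


def test_rtk_off_without_nutrient(thr):
    latt = CellLattice((4, 4, 4))
    latt.add_cell(np.array([[1, 1, 1]]), lat.TP)
    counts = _tally(latt)
    inputs = coupling.receptor_inputs(counts[1], 0.0, thr)
    assert inputs[1] == 0


def test_quiescent_cells_use_hysteresis_threshold(thr):
    latt = CellLattice((4, 4, 4))
    latt.add_cell(np.array([[1, 1, 1]]), lat.TQ)
    counts = _tally(latt)
    mid = (thr.t_rtk + thr.t_rtk_q) / 2
    assert coupling.receptor_inputs(counts[1], mid, thr, quiescent=False)[1] == 1
    assert coupling.receptor_inputs(counts[1], mid, thr, quiescent=True)[1] == 0


def test_receptor_inputs_idempotent(thr):
    latt = CellLattice((8, 8, 8))
    latt.add_cell(np.argwhere(np.ones((3, 3, 3), bool)) + 2, lat.TP)
    counts = _tally(latt)
    a = coupling.receptor_inputs(counts[1], 0.5, thr)
    b = coupling.receptor_inputs(counts[1], 0.5, thr)
    assert a == b


def test_raising_rtk_threshold_monotone(thr):
    """More demanding RTK thresholds can only reduce the RTK-ON count."""
    rng = np.random.default_rng(8)
    means = rng.random(200) * 0.01
    def on_count(t):
        t2 = ReceptorThresholds(t_rtk=t, t_rtk_q=max(t, thr.t_rtk_q))
        return sum(m >= t2.t_rtk for m in means)
    counts = [on_count(t) for t in (1e-4, 1e-3, 4.48e-3, 8e-3)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_threshold_validation():
    with pytest.raises(ValueError):
        ReceptorThresholds(t_rtk=-1.0)
    with pytest.raises(ValueError, match="hysteresis"):
        ReceptorThresholds(t_rtk=1.0, t_rtk_q=0.5)


# -- phenotype application ---------------------------------------------------


def _cell(type_code=lat.TP, volume=64):
    return CellRecord(id=1, type=type_code, volume=volume, target_volume=64.0,
                      elasticity=8.0)


def test_apply_phenotype_proliferative():
    rec = _cell()
    coupling.apply_phenotype(rec, 1100)
    assert rec.type == lat.TP and rec.chi == 0.0


def test_apply_phenotype_migratory():
    rec = _cell()
    coupling.apply_phenotype(rec, 1101, chi_m=-1.5e6)
    assert rec.type == lat.TM and rec.chi == -1.5e6
    assert rec.chem_field == _kernels.CHEM_NUTRIENT


@pytest.mark.parametrize("code", [10, 11])
def test_apply_phenotype_apoptosis_shrinks(code):
    rec = _cell()
    coupling.apply_phenotype(rec, code)
    assert rec.target_volume == 0.0


def test_apply_phenotype_rejects_unreachable():
    with pytest.raises(coupling.UnreachablePhenotypeError):
        coupling.apply_phenotype(_cell(), 1111)


# -- viability state machine -------------------------------------------------


def test_starved_cell_goes_quiescent(thr):
    rec = _cell()
    state = coupling.update_viability_state(rec, rtk_on=False,
                                            mean_nutrient=0.0,
                                            thresholds=thr, dt_minutes=60)
    assert state == "quiescent" and rec.type == lat.TQ


def test_refed_quiescent_cell_reenters_cycle(thr):
    rec = _cell(lat.TQ)
    state = coupling.update_viability_state(rec, rtk_on=False,
                                            mean_nutrient=thr.t_rtk_q * 2,
                                            thresholds=thr, dt_minutes=60)
    assert state == "viable" and rec.type == lat.TP


def test_sustained_hypoxia_becomes_necrosis(thr):
    rec = _cell(lat.TQ)
    for _ in range(49):  # 49 h > tau_N = 48 h
        coupling.update_viability_state(rec, False, 0.0, thr, 60.0,
                                        tau_n_minutes=2880.0)
    assert rec.type == lat.TN


def test_necrosis_is_absorbing_then_cleared(thr):
    rec = _cell(lat.TN)
    for _ in range(10):
        s = coupling.update_viability_state(rec, True, 10.0, thr, 60.0,
                                            tau_clear_minutes=300.0)
        assert s == "necrotic" and rec.type == lat.TN
    assert rec.target_volume == 0.0  # clearance initiated


# -- endothelial cells -------------------------------------------------------


def test_ec_activation_threshold(thr):
    rec = _cell(lat.EC)
    assert not coupling.ec_activation(rec, thr.t_vegf * 0.5, thr)
    assert coupling.ec_activation(rec, thr.t_vegf * 2, thr)
    assert rec.ec_activated and rec.chem_field == _kernels.CHEM_VEGF
    # activation is sticky
    assert coupling.ec_activation(rec, 0.0, thr)


def test_ec_activation_only_for_ecs(thr):
    assert not coupling.ec_activation(_cell(lat.TP), 1.0, thr)


def test_ve_cadherin_inhibition_cases(thr):
    fully = np.array([10, 0, 10, 0, 0])  # all boundary on other ECs
    tip = np.array([10, 0, 1, 9, 0])     # one EC neighbour
    assert coupling.ve_cadherin_inhibition(fully, thr)
    assert not coupling.ve_cadherin_inhibition(tip, thr)
    degenerate = ReceptorThresholds(theta_ve=1.0)
    assert not coupling.ve_cadherin_inhibition(fully, degenerate)
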