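"""Boolean signalling network: rule parsing, dynamics, attractors, censuses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tumorcpm import boolean_network as bn

ALL_ON = {"Integrin": 1, "RTK": 1, "E-cadherin": 1, "Wnt": 1, "APC": 1, "NF1": 1}


# -- load_rules --------------------------------------------------------------


def test_rule_table_structure(net):
    assert len(net.internals) == 29
    assert set(net.externals) == set(bn.EXTERNAL_NODES)
    assert set(net.outputs) == set(bn.OUTPUT_NODES)
    assert len(net.nodes) == 6 + 29 + 4
    assert len(set(net.nodes)) == len(net.nodes)


def test_load_rules_rejects_empty_and_unknown(tmp_path):
    empty = tmp_path / "empty.tsv"
    empty.write_text("# nothing here\n")
    with pytest.raises(ValueError, match="empty"):
        bn.load_rules(empty)
    bad = tmp_path / "bad.tsv"
    bad.write_text("A\tB And C\tinternal\n")
    with pytest.raises(ValueError, match="unknown node"):
        bn.load_rules(bad)


def test_load_rules_rejects_duplicates(tmp_path, net):
    ref = (
        "Integrin\tExternal signal\texternal\n"
        "Integrin\tExternal signal\texternal\n"
    )
    f = tmp_path / "dup.tsv"
    f.write_text(ref)
    with pytest.raises(ValueError, match="duplicate"):
        bn.load_rules(f)


# -- step --------------------------------------------------------------------


@pytest.mark.parametrize("source,target,value", [
    ("Integrin", "FAK", 1),   # FAK follows the integrin signal
    ("Mdm2", "p53", 0),       # p53 is inhibited by Mdm2
])
def test_step_propagates_single_rules(net, source, target, value):
    state = bn.make_state(net, {n: 0 for n in bn.EXTERNAL_NODES})
    state.values[net.index[source]] = 1
    nxt = bn.step(state, net)
    assert nxt.values[net.index[target]] == value


def test_step_fixed_point_is_identity(net):
    att = bn.run_to_attractor(
        bn.make_state(net, (1, 1, 1, 0, 0, 0)), net)
    assert att.period == 1
    fixed = att.states[0]
    again = bn.step(fixed, net)
    assert np.array_equal(again.values, fixed.values)


def test_step_is_deterministic(net):
    rng = np.random.default_rng(7)
    state = bn.make_state(net, (1, 0, 1, 0, 0, 0), rng=rng)
    a = bn.step(state, net)
    b = bn.step(state, net)
    assert np.array_equal(a.values, b.values)


@settings(max_examples=25, deadline=None)
@given(bits=st.integers(min_value=0, max_value=2**29 - 1),
       cfg=st.integers(min_value=0, max_value=63))
def test_step_keeps_externals_frozen(net, bits, cfg):
    inputs = tuple((cfg >> k) & 1 for k in range(6))
    internal = np.array([(bits >> j) & 1 for j in range(29)], dtype=np.uint8)
    state = bn.make_state(net, inputs, internal_values=internal)
    nxt = bn.step(state, net)
    for name, bit in zip(bn.EXTERNAL_NODES, inputs):
        assert nxt.values[net.index[name]] == bit


# -- attractors --------------------------------------------------------------


def test_reference_case_grows_and_proliferates(net):
    """Integrin+RTK+cadherin on, Wnt and both suppressors off -> 1100."""
    for internal_seed in range(8):
        rng = np.random.default_rng(internal_seed)
        att = bn.run_to_attractor(
            bn.make_state(net, (1, 1, 1, 0, 0, 0), rng=rng), net)
        assert str(att.phenotype) == "1100"


def test_nf1_restoration_forces_apoptosis(net):
    att = bn.run_to_attractor(bn.make_state(net, (1, 1, 1, 0, 0, 1)), net)
    assert str(att.phenotype) == "0010"


@pytest.mark.parametrize("inputs", [
    (0, 1, 1, 0, 0, 0), (1, 0, 1, 0, 0, 0), (0, 0, 0, 0, 0, 0),
    (0, 1, 0, 1, 0, 0), (1, 0, 0, 1, 0, 0),
])
def test_receptor_disruption_sets_apoptosis_bit(net, inputs):
    """Losing integrin or RTK drives the apoptotic attractor."""
    att = bn.run_to_attractor(bn.make_state(net, inputs), net)
    assert att.phenotype.apoptosis


def test_cadherin_blocks_migration_without_wnt(net):
    """Case 110 with cadherin on: growth+proliferation, no migration."""
    att = bn.run_to_attractor(bn.make_state(net, (1, 1, 1, 0, 0, 0)), net)
    assert not att.phenotype.migration


def test_run_to_attractor_nonconvergence_guard(net):
    with pytest.raises(ValueError):
        bn.run_to_attractor(bn.make_state(net, (0,) * 6), net, max_steps=0)


def test_phenotype_of_cycle_uses_strict_and(net):
    a = bn.make_state(net, (0,) * 6)
    b = bn.make_state(net, (0,) * 6)
    for name in ("Cell apoptosis",):
        a.values[net.index[name]] = 1
        b.values[net.index[name]] = 1
    a.values[net.index["Cell migration"]] = 1  # on in one state only
    code = bn.phenotype_of([a, b], net)
    assert code.apoptosis and not code.migration


# -- input-output map --------------------------------------------------------


def test_map_covers_all_inputs_and_three_classes(pheno_map):
    assert len(pheno_map) == 64
    classes = set()
    for code in pheno_map.values():
        s = str(code)
        classes.add("apoptosis" if s in ("0010", "0011") else s)
    assert classes == {"1100", "1101", "apoptosis"}


def test_map_is_pure_function_of_inputs(net):
    m1 = bn.input_output_map(net, n_internal_seeds=64, seed=11)
    m2 = bn.input_output_map(net, n_internal_seeds=64, seed=99)
    assert {k: str(v) for k, v in m1.items()} == {k: str(v) for k, v in m2.items()}


def test_map_independent_of_internal_seed_heavily_sampled(net):
    """>=10^3 internal seeds per configuration, all must agree."""
    m = bn.input_output_map(net, n_internal_seeds=1024, seed=5)
    assert len(m) == 64


def test_detached_inputs_reach_apoptosis(pheno_map):
    assert str(pheno_map[(0, 0, 0, 0, 0, 0)]) in ("0010", "0011")


# -- robustness scan ---------------------------------------------------------


def test_scan_single_sample_single_phenotype(net):
    scan = bn.robustness_scan(net, n_samples=1, seed=0,
                              inputs=[(1, 1, 1, 0, 0, 0)])
    assert len(scan["phenotypes"]) == 1


def test_scan_reaches_exactly_four_attractors(net):
    scan = bn.robustness_scan(net, n_samples=4096, seed=1729)
    assert {str(p) for p in scan["phenotypes"]} == {"1101", "1100", "0010", "0011"}


def test_input_switch_reconverges_quickly(net):
    """After convergence, flipping the externals re-converges in a few updates."""
    att = bn.run_to_attractor(bn.make_state(net, (1, 1, 1, 0, 0, 0)), net)
    state = att.states[0].copy()
    for name, bit in zip(bn.EXTERNAL_NODES, (1, 1, 0, 1, 0, 0)):
        state.values[net.index[name]] = bit
    att2 = bn.run_to_attractor(state, net)
    assert att2.n_steps <= 12
    assert str(att2.phenotype) == "1101"


def test_exhaustive_guard_raises(net):
    with pytest.raises(MemoryError):
        bn.robustness_scan(net, exhaustive=True, exhaustive_guard=2**20,
                           inputs=[(1, 1, 1, 0, 0, 0)])


def test_async_mode_reaches_same_fixed_point(net):
    """Random-order updates settle into the synchronous fixed point here."""
    rng = np.random.default_rng(3)
    state = bn.make_state(net, (1, 1, 1, 0, 0, 0), rng=rng)
    for _ in range(40):
        state = bn.step_async(state, net, rng)
    sync = bn.run_to_attractor(bn.make_state(net, (1, 1, 1, 0, 0, 0)), net)
    idx = [net.index[n] for n in bn.OUTPUT_NODES]
    assert np.array_equal(state.values[idx], sync.states[0].values[idx])
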