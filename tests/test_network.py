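"""Update engines, attractor detection, clamps and enumeration."""

import logging

import pytest

from cd8net.expr import And, Not, Or, Var, parse_rule
from cd8net.network import (
    BooleanNetwork,
    NodeSpec,
    Scenario,
    StateSpaceTooLargeError,
    UpdateSchedule,
    apply_perturbation,
    enumerate_state_space,
    find_attractor,
    step,
)


@pytest.fixture
def toggle():
    return BooleanNetwork([NodeSpec("A", Not(Var("A")))])


@pytest.fixture
def copy_chain():
    # A self-activates, B requires both A and itself.
    return BooleanNetwork(
        [NodeSpec("A", Var("A")), NodeSpec("B", And([Var("A"), Var("B")]))]
    )


SYNC = UpdateSchedule.synchronous()


class TestStep:
    def test_negation_toggles(self, toggle):
        assert step(toggle, (0,), Scenario(), SYNC) == (1,)
        assert step(toggle, (1,), Scenario(), SYNC) == (0,)

    def test_self_activation_holds(self):
        net = BooleanNetwork([NodeSpec("A", Var("A"))])
        assert step(net, (1,), Scenario(), SYNC) == (1,)

    def test_non_due_node_keeps_value(self, toggle):
        sched = UpdateSchedule("asynchronous", {"A": 2})
        # t=1: 1 % 2 != 0, A not due
        assert step(toggle, (0,), Scenario(), sched, t=1) == (0,)
        assert step(toggle, (0,), Scenario(), sched, t=2) == (1,)

    def test_all_reads_are_pre_step(self):
        # B copies A; with A toggling, B must read A's old value.
        net = BooleanNetwork(
            [NodeSpec("A", Not(Var("A"))), NodeSpec("B", Var("A"))]
        )
        assert step(net, (1, 0), Scenario(), SYNC) == (0, 1)

    def test_perturbation_clamp_overrides_rule_and_schedule(self, toggle):
        scen = Scenario(perturbations={"A": 1})
        assert step(toggle, (1,), scen, SYNC) == (1,)
        sched = UpdateSchedule("asynchronous", {"A": 4})
        assert step(toggle, (0,), scen, sched, t=1) == (1,)

    def test_negative_time_rejected(self, toggle):
        with pytest.raises(ValueError):
            step(toggle, (0,), Scenario(), SYNC, t=-1)


class TestFindAttractor:
    def test_toggle_two_cycle(self, toggle):
        a = find_attractor(toggle, (0,), Scenario(), SYNC)
        assert a.kind == "cycle"
        assert set(a.states) == {(0,), (1,)}

    def test_self_activator_fixed_point(self):
        net = BooleanNetwork([NodeSpec("A", Var("A"))])
        a = find_attractor(net, (1,), Scenario(), SYNC)
        assert a.kind == "fixed_point" and a.states == ((1,),)

    def test_hand_enumerated_transition_graph(self, copy_chain):
        # 4-state graph: (0,1)->(0,0) fixed; (1,1) fixed; (1,0) fixed; (0,0) fixed.
        a = find_attractor(copy_chain, (0, 1), Scenario(), SYNC)
        assert a.kind == "fixed_point" and a.states == ((0, 0),)

    def test_max_steps_guard(self, toggle):
        from cd8net.network import NonterminationError

        with pytest.raises(NonterminationError):
            find_attractor(toggle, (0,), Scenario(), SYNC, max_steps=1)


class TestEnumerate:
    def test_hand_enumerated_basins(self, copy_chain):
        atlas = enumerate_state_space(copy_chain, Scenario(), SYNC)
        got = {a.states[0]: a.basin_size for a in atlas.attractors}
        assert got == {(0, 0): 2, (1, 0): 1, (1, 1): 1}

    def test_toggle_single_cycle(self, toggle):
        atlas = enumerate_state_space(toggle, Scenario(), SYNC)
        assert len(atlas.attractors) == 1
        assert atlas.attractors[0].kind == "cycle"
        assert atlas.attractors[0].basin_size == 2

    def test_fully_clamped_network_has_unique_fixed_point(self, copy_chain):
        scen = Scenario(perturbations={"A": 1, "B": 0})
        atlas = enumerate_state_space(copy_chain, scen, SYNC)
        assert len(atlas.attractors) == 1
        (a,) = atlas.attractors
        assert a.kind == "fixed_point" and a.states == ((1, 0),)
        assert a.basin_size == copy_chain.omega

    def test_determinism(self, copy_chain):
        s = Scenario(perturbations={"A": 1})
        a1 = enumerate_state_space(copy_chain, s, SYNC)
        a2 = enumerate_state_space(copy_chain, s, SYNC)
        assert [(x.canonical_key, x.basin_size) for x in a1.attractors] == [
            (x.canonical_key, x.basin_size) for x in a2.attractors
        ]

    def test_agrees_with_trajectory_engine_per_state(self, copy_chain):
        for sched in (SYNC, UpdateSchedule.asynchronous(copy_chain)):
            atlas = enumerate_state_space(copy_chain, Scenario(), sched)
            counted = {}
            for code in range(copy_chain.omega):
                a = find_attractor(copy_chain, code, Scenario(), sched)
                counted[a.canonical_key] = counted.get(a.canonical_key, 0) + 1
            assert counted == {a.canonical_key: a.basin_size for a in atlas.attractors}

    def test_ceiling_refused_with_pointer_to_sampling(self, copy_chain):
        with pytest.raises(StateSpaceTooLargeError, match="sampl"):
            enumerate_state_space(copy_chain, Scenario(), SYNC, ceiling=1)


class TestScenario:
    def test_inputs_must_be_total(self):
        net = BooleanNetwork([NodeSpec("A", Var("u"))], input_nodes=["u"])
        with pytest.raises(ValueError, match="u"):
            Scenario().validate(net)
        Scenario({"u": 1}).validate(net)

    def test_apply_perturbation_returns_new_scenario(self):
        base = Scenario()
        ko = apply_perturbation(base, "ROS", 0)
        assert ko.perturbations == {"ROS": 0}
        assert base.perturbations == {}

    def test_knockin_overwrites_knockout_with_warning(self, caplog):
        base = apply_perturbation(Scenario(), "mTORC2", 0)
        with caplog.at_level(logging.WARNING):
            ki = apply_perturbation(base, "mTORC2", 1)
        assert ki.perturbations == {"mTORC2": 1}
        assert any("overwriting" in r.message for r in caplog.records)

    def test_perturbing_an_input_is_redirected(self):
        net = BooleanNetwork([NodeSpec("A", Var("u"))], input_nodes=["u"])
        with pytest.raises(ValueError, match="input_clamps"):
            apply_perturbation(Scenario({"u": 0}), "u", 1, network=net)

    def test_unknown_node_is_named(self):
        net = BooleanNetwork([NodeSpec("A", Var("A"))])
        with pytest.raises(ValueError, match="Bogus"):
            apply_perturbation(Scenario(), "Bogus", 1, network=net)


class TestSchedule:
    def test_synchronous_rejects_periods(self):
        with pytest.raises(ValueError):
            UpdateSchedule("synchronous", {"A": 2})

    def test_class_periods_from_network(self):
        net = BooleanNetwork(
            [
                NodeSpec("m", Var("m"), "metabolite"),
                NodeSpec("s", Var("s"), "signaling"),
                NodeSpec("tf", Var("tf"), "transcription_factor"),
            ]
        )
        sched = UpdateSchedule.asynchronous(net, periods={"s": 8})
        assert sched.period_of("m") == 1
        assert sched.period_of("tf") == 4
        assert sched.period_of("s") == 8  # explicit override wins
        assert sched.phase_count(net) == 8

    def test_clamped_network_invariants_hold_during_async_run(self):
        net = BooleanNetwork(
            [
                NodeSpec("A", Not(Var("A")), "metabolite"),
                NodeSpec("B", Or([Var("A"), Var("B")]), "transcription_factor"),
            ]
        )
        sched = UpdateSchedule.asynchronous(net)
        scen = Scenario(perturbations={"B": 0})
        atlas = enumerate_state_space(net, scen, sched)
        for a in atlas.attractors:
            for state in a.states:
                assert state[net.index["B"]] == 0  # clamp dominance
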