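"""Unit tests for the generic circuit layer and its integrators."""

import numpy as np
import pytest

from cardiotal.circuits import (CircuitElement, InstabilityError,
                                IntegrationError, Network,
                                NonConvergenceError, State, TopologyError,
                                assemble_state_equations, capacitor,
                                euler_step, inductive, make_state, resistor,
                                run_to_periodic_steady_state, simulate)

BIG_C = 1e9  # effectively a constant-pressure reservoir


def rc_network(C=1.0, R=1.0):
    """Capacitor discharging through R into a 0-mmHg reservoir."""
    return Network("rc", [
        capacitor("C", "a", C),
        resistor("R", "a", "b", R),
        capacitor("Cref", "b", BIG_C),
    ])


class TestAssembly:
    def test_isolated_capacitor_has_zero_derivative(self):
        net = Network("single", [capacitor("C", "a", 2.0)])
        f = assemble_state_equations(net)
        state = make_state(net, {"V:C": 17.0})
        assert f(0.0, state.values) == pytest.approx([0.0])

    def test_rc_loop_initial_discharge_rate(self):
        # 10 mmHg across 1 mmHg*s/ml drives -10 ml/s out of the capacitor
        net = rc_network()
        f = assemble_state_equations(net)
        state = make_state(net, {"V:C": 10.0})
        dy, P, Q = f.evaluate(0.0, state.values)
        assert P[0] == pytest.approx(10.0)
        assert Q[0] == pytest.approx(10.0)
        assert dy[0] == pytest.approx(-10.0)

    def test_inductor_with_equal_end_pressures_keeps_flow(self):
        net = Network("rl", [
            capacitor("C1", "a", 1.0),
            capacitor("C2", "b", 1.0),
            inductive("L", "a", "b", R=0.0, L=2.0),
        ])
        f = assemble_state_equations(net)
        state = make_state(net, {"V:C1": 5.0, "V:C2": 5.0})
        dy = f(0.0, state.values)
        assert dy[2] == pytest.approx(0.0)

    def test_node_without_storage_is_rejected(self):
        net = Network("bad", [
            capacitor("C", "a", 1.0),
            resistor("R1", "a", "floating", 1.0),
            resistor("R2", "floating", "a", 1.0),
        ])
        with pytest.raises(TopologyError, match="floating"):
            assemble_state_equations(net)

    def test_invalid_element_parameters_are_rejected(self):
        with pytest.raises(ValueError):
            capacitor("C", "a", -1.0)
        with pytest.raises(ValueError):
            resistor("R", "a", "b", 0.0)
        with pytest.raises(ValueError):
            CircuitElement("R", "resistor", "a", "a", params={"R": 1.0})

    def test_infinite_resistance_disables_the_branch(self):
        el = resistor("R", "a", "b", float("inf"))
        assert not el.enabled


class TestEulerStep:
    def test_update_rule(self):
        state = State(0.0, np.array([1.0]), ("V:C",))
        new = euler_step(state, lambda t, y: np.array([2.0]), 0.5)
        assert new.values[0] == pytest.approx(2.0)
        assert new.time == pytest.approx(0.5)

    def test_zero_derivative_only_advances_time(self):
        state = State(1.0, np.array([3.0, -1.0]), ("V:A", "V:B"))
        new = euler_step(state, lambda t, y: np.zeros(2), 0.1)
        assert np.array_equal(new.values, state.values)
        assert new.time == pytest.approx(1.1)

    def test_rc_decay_arithmetic(self):
        state = State(0.0, np.array([10.0]), ("V:C",))
        new = euler_step(state, lambda t, y: -y, 0.01)
        assert new.values[0] == pytest.approx(9.9)

    def test_nonfinite_derivative_names_the_slot(self):
        state = State(0.0, np.array([1.0, 1.0]), ("V:A", "Q:L"))
        with pytest.raises(IntegrationError, match="Q:L"):
            euler_step(state, lambda t, y: np.array([0.0, np.nan]), 0.1)


class TestSimulate:
    def test_zero_duration_returns_initial_sample(self):
        net = rc_network()
        state = make_state(net, {"V:C": 10.0})
        res = simulate(net, state, duration=0.0)
        assert len(res.time) == 1
        assert res["P:a"][0] == pytest.approx(10.0)

    def test_rc_discharge_matches_closed_form(self):
        net = rc_network()
        state = make_state(net, {"V:C": 10.0})
        res = simulate(net, state, duration=1.0, dt=1e-4)
        v_end = res.waveforms["V:C"][-1]
        assert v_end == pytest.approx(10.0 * np.exp(-1.0), abs=0.005)

    def test_first_order_convergence_in_dt(self):
        # halving dt halves the error against the exponential solution
        errors = []
        for dt in (2e-4, 1e-4):
            net = rc_network()
            state = make_state(net, {"V:C": 10.0})
            res = simulate(net, state, duration=1.0, dt=dt)
            errors.append(abs(res.waveforms["V:C"][-1] - 10.0 * np.exp(-1.0)))
        ratio = errors[0] / errors[1]
        assert 1.6 <= ratio <= 2.4

    def test_two_capacitor_loop_conserves_volume(self):
        net = Network("pair", [
            capacitor("C1", "a", 1.0),
            capacitor("C2", "b", 2.0),
            resistor("R", "a", "b", 0.5),
        ])
        state = make_state(net, {"V:C1": 9.0, "V:C2": 1.0})
        res = simulate(net, state, duration=10.0, dt=1e-3, record_every=100)
        total = res.waveforms["V:C1"] + res.waveforms["V:C2"]
        assert np.max(np.abs(total - 10.0)) < 1e-4 * 10.0

    def test_divergence_raises_instability_error(self):
        # negative-compliance-free way to diverge: huge dt on a stiff RC
        net = rc_network(C=1e-4, R=1e-3)
        state = make_state(net, {"V:C": 10.0})
        with pytest.raises(InstabilityError, match="smaller dt"):
            simulate(net, state, duration=5.0, dt=0.1)

    def test_determinism_bit_identical(self, normal_preset):
        from cardiotal.vasculature import build_full_network, initial_state
        net = build_full_network(normal_preset)
        st = initial_state(normal_preset, net)
        r1 = simulate(net, st, duration=0.8, dt=1e-4)
        r2 = simulate(net, st, duration=0.8, dt=1e-4)
        for key in r1.waveforms:
            assert np.array_equal(r1.waveforms[key], r2.waveforms[key])


class TestPeriodicSteadyState:
    def test_already_periodic_converges_in_minimum_cycles(self, normal_preset,
                                                          normal_steady):
        from cardiotal.vasculature import build_full_network
        net = build_full_network(normal_preset)
        result, _, _ = normal_steady
        _, cycles = run_to_periodic_steady_state(net, result.final_state)
        assert cycles == 4

    def test_zero_tolerance_never_converges(self, normal_preset):
        from cardiotal.vasculature import build_full_network, initial_state
        net = build_full_network(normal_preset)
        st = initial_state(normal_preset, net)
        with pytest.raises(NonConvergenceError):
            run_to_periodic_steady_state(net, st, tol=0.0, max_cycles=6)

    def test_needs_a_cardiac_period(self):
        net = rc_network()
        with pytest.raises(ValueError, match="period"):
            run_to_periodic_steady_state(net, make_state(net, {"V:C": 1.0}))
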