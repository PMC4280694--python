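"""TAL block: flow-dependent drops, mode algebra, attachment, mass balance."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cardiotal import _kernel
from cardiotal.protocol import run_steady
from cardiotal.tal import (TALParams, attach_tal, configure_tal,
                           tal_flow_dependent_drop)
from cardiotal.vasculature import build_full_network

INF = math.inf


def steady_summary(preset, tal=None):
    p = dataclasses.replace(preset, tal=tal)
    _, summary, _ = run_steady(p)
    return summary


class TestFlowDependentDrop:
    @pytest.mark.parametrize("q, r0, k, expected", [
        (0.0, 0.02, 1e-4, 0.0),
        (50.0, 0.02, 0.0, 1.0),  # linear limit
        (-50.0, 0.02, 1e-4, -1.25),  # sign-preserving quadratic
    ])
    def test_values(self, q, r0, k, expected):
        assert tal_flow_dependent_drop(q, r0, k) == pytest.approx(expected)

    @given(st.floats(-500, 500), st.floats(0.001, 0.1),
           st.floats(0.0, 1e-3))
    def test_kernel_inversion_round_trip(self, q, r0, k):
        dp = tal_flow_dependent_drop(q, r0, k)
        assert _kernel.flowdep_flow(dp, r0, k) == pytest.approx(
            q, rel=1e-9, abs=1e-9)

    @given(st.floats(-500, 500), st.floats(0.001, 0.1),
           st.floats(0.0, 1e-3))
    def test_odd_symmetry(self, q, r0, k):
        assert tal_flow_dependent_drop(-q, r0, k) == pytest.approx(
            -tal_flow_dependent_drop(q, r0, k))


class TestConfiguration:
    def test_mode_round_trip(self):
        tal = configure_tal(TALParams(), "hybrid")
        assert tal.mode == "hybrid"
        with pytest.raises(ValueError, match="unknown TAL mode"):
            configure_tal(TALParams(), "sideways")

    def test_attach_twice_fails(self, normal_preset):
        net = build_full_network(normal_preset)
        net = attach_tal(net, TALParams(mode="parallel"))
        with pytest.raises(ValueError, match="already attached"):
            attach_tal(net, TALParams(mode="parallel"))

    @pytest.mark.parametrize("mode, disabled", [
        ("off", ("TALin", "TALad", "TALap", "TALala", "TALan")),
        ("parallel", ("TALan",)),
        ("series", ("TALala", "Rpam")),
        ("hybrid", ()),
    ])
    def test_mode_branch_pattern(self, normal_preset, mode, disabled):
        net = attach_tal(build_full_network(normal_preset),
                         TALParams(mode=mode))
        state = {e.name: e.enabled for e in net.elements}
        for name in disabled:
            assert not state[name], f"{name} should be disabled in {mode}"
        for name in set(("TALin", "TALala", "TALan", "Rpam")) - set(disabled):
            if mode != "off":
                assert state[name], f"{name} should be active in {mode}"

    def test_band_resistance_added_to_native_segment(self, normal_preset):
        plain = build_full_network(normal_preset).element("Rpam")
        tal = TALParams(mode="hybrid", R_pab=2.0)
        banded = attach_tal(build_full_network(normal_preset),
                            tal).element("Rpam")
        assert banded.params["R"] == pytest.approx(plain.params["R"] + 2.0)


class TestModeAlgebra:
    def test_off_equals_unattached(self, normal_preset, normal_steady):
        _, base, _ = normal_steady
        s = steady_summary(normal_preset, TALParams(mode="off"))
        for key, value in s.as_dict().items():
            assert value == pytest.approx(base.as_dict()[key], rel=1e-6), key

    def test_parallel_return_branch_carries_no_flow(self, normal_preset):
        p = dataclasses.replace(normal_preset,
                                tal=TALParams(mode="parallel"))
        result, _, _ = run_steady(p)
        assert np.all(result["QTALan"] == 0.0)
        assert np.any(result["QTALala"] != 0.0)

    def test_hybrid_limits_reproduce_pure_modes(self, normal_preset):
        parallel = steady_summary(normal_preset, TALParams(mode="parallel"))
        hybrid_no_an = steady_summary(
            normal_preset, TALParams(mode="hybrid", R_an=INF, L_an=INF))
        series = steady_summary(normal_preset, TALParams(mode="series"))
        hybrid_no_band = steady_summary(
            normal_preset,
            TALParams(mode="hybrid", R_pab=INF, R_ala=INF, L_ala=INF))
        for key in parallel.as_dict():
            assert hybrid_no_an.as_dict()[key] == pytest.approx(
                parallel.as_dict()[key], rel=1e-9), key
            assert hybrid_no_band.as_dict()[key] == pytest.approx(
                series.as_dict()[key], rel=1e-9), key


class TestHaemodynamics:
    def test_parallel_tal_lowers_pap_of_hypertensive_patient(
            self, calibrated_patient):
        patient, _ = calibrated_patient
        _, base, _ = run_steady(dataclasses.replace(patient, tal=None))
        assisted = steady_summary(patient, TALParams(mode="parallel"))
        assert assisted.mean_pap < base.mean_pap

    def test_tal_mass_balance_over_a_cycle(self, calibrated_patient):
        patient, _ = calibrated_patient
        p = dataclasses.replace(patient, tal=TALParams(mode="hybrid"))
        result, _, _ = run_steady(p)
        t = result.time
        q_in = np.trapezoid(result["QTALin"], t)
        q_out = (np.trapezoid(result["QTALala"], t)
                 + np.trapezoid(result["QTALan"], t))
        assert q_in == pytest.approx(q_out, rel=5e-3)

    def test_tighter_band_diverts_more_flow_through_the_tal(
            self, calibrated_patient):
        # The band's role is to divide pulmonary flow between device and
        # natural lung: tightening it monotonically raises the TAL's share
        # of right ventricular output.
        patient, _ = calibrated_patient
        shares = []
        for r_pab in (0.5, 2.0, 6.0):
            p = dataclasses.replace(
                patient, tal=TALParams(mode="hybrid", R_pab=r_pab))
            result, _, _ = run_steady(p)
            t = result.time
            tal_in = np.trapezoid(result["QTALin"], t)
            rv_out = np.trapezoid(result["Qro"], t)
            shares.append(tal_in / rv_out)
        assert shares[0] < shares[1] < shares[2]
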