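"""Full-circulation network: units, topology, physiology, coronary branch."""

import dataclasses

import numpy as np
import pytest

from cardiotal.protocol import run_steady
from cardiotal.vasculature import (PatientPreset,
                                   UnknownParameterError, UnitError,
                                   build_full_network,
                                   cgs_resistance_to_internal, get_parameter,
                                   intramyocardial_pressure, normal_preset,
                                   set_parameter)


class TestUnitConversion:
    @pytest.mark.parametrize("cgs, expected", [
        (1333.22, 1.0),
        (240.0, 0.1800),
        (120.0, 0.09001),
    ])
    def test_cgs_to_internal(self, cgs, expected):
        assert cgs_resistance_to_internal(cgs) == pytest.approx(
            expected, rel=5e-4)

    def test_negative_resistance_rejected(self):
        with pytest.raises(ValueError):
            cgs_resistance_to_internal(-1.0)


class TestNetworkConstruction:
    def test_bill_of_materials(self, normal_preset):
        net = build_full_network(normal_preset)
        assert len(net.elements) == 21  # 4 chambers, 4 valves, 13 vessels
        names = {e.name for e in net.elements}
        for required in ("Rli", "Rlo", "Rri", "Rro", "Ras", "Rvs", "Cvs",
                         "Rpam", "Cpam", "Cpas", "Rlung", "Cvp", "Rvp",
                         "Rcor_in", "Ccor", "Rcor_out"):
            assert required in names

    def test_pressure_references(self, normal_preset):
        net = build_full_network(normal_preset)
        refs = {e.name: e.pressure_ref for e in net.elements if e.is_storage}
        assert refs["Cvs"] == "ambient" and refs["Cas"] == "ambient"
        for name in ("LA", "LV", "RA", "RV", "Cpam", "Cpas", "Cvp"):
            assert refs[name] == "intrathoracic"
        assert refs["Ccor"] == "intramyocardial"

    def test_normal_preset_lands_in_textbook_ranges(self, normal_steady):
        _, summary, cycles = normal_steady
        assert cycles <= 60
        assert 70.0 <= summary.mean_aop <= 105.0
        assert 4.0 <= summary.co <= 6.5

    def test_raising_rpar_raises_pap_and_rvesv_monotonically(
            self, normal_preset):
        paps, rvesvs = [], []
        for factor in (1.0, 2.0, 4.0):
            p = set_parameter(
                normal_preset, "Rpar",
                get_parameter(normal_preset, "Rpar") * factor)
            _, s, _ = run_steady(p)
            paps.append(s.mean_pap)
            rvesvs.append(s.rvesv)
        assert paps[0] < paps[1] < paps[2]
        assert rvesvs[0] < rvesvs[1] < rvesvs[2]

    def test_raising_ras_raises_aop_and_lowers_co(self, normal_preset):
        aops, cos = [], []
        for factor in (0.8, 1.0, 1.3):
            p = set_parameter(normal_preset, "Ras",
                              normal_preset.systemic.Ras * factor)
            _, s, _ = run_steady(p)
            aops.append(s.mean_aop)
            cos.append(s.co)
        assert aops[0] < aops[1] < aops[2]
        assert cos[0] > cos[1] > cos[2]


class TestSetParameter:
    def test_cgs_round_trip(self, normal_preset):
        p = set_parameter(normal_preset, "Rpar", 240.0, units="cgs")
        assert get_parameter(p, "Rpar") == pytest.approx(0.1800, rel=5e-4)
        # original untouched
        assert get_parameter(normal_preset, "Rpar") != \
            get_parameter(p, "Rpar")

    def test_plain_round_trip_identity(self, normal_preset):
        p = set_parameter(normal_preset, "Cvs", 80.0)
        assert get_parameter(p, "Cvs") == 80.0

    def test_unknown_symbol_lists_valid_ones(self, normal_preset):
        with pytest.raises(UnknownParameterError, match="Rpar"):
            set_parameter(normal_preset, "Rxx", 1.0)

    def test_wrong_units_rejected(self, normal_preset):
        with pytest.raises(UnitError):
            set_parameter(normal_preset, "Cvs", 10.0, units="cgs")

    def test_preset_dict_round_trip(self, normal_preset):
        clone = PatientPreset.from_dict(normal_preset.to_dict())
        assert clone == normal_preset


class TestCoronary:
    def test_intramyocardial_pressure_law(self):
        assert intramyocardial_pressure(120.0, 0.0) == 0.0
        assert intramyocardial_pressure(120.0, 1.0) == 120.0
        with pytest.raises(ValueError):
            intramyocardial_pressure(100.0, 1.5)

    def test_coronary_inflow_dips_during_systole(self, normal_steady):
        result, _, _ = normal_steady
        q = result["Qcor"]
        plv = result["Plv"]
        systole = plv > 0.5 * plv.max()
        assert q[systole].min() < q[~systole].max()

    def test_coronary_loop_mass_balance(self, normal_steady):
        result, _, _ = normal_steady
        t = result.time
        q_in = np.trapezoid(result["Qcor"], t)
        q_out = np.trapezoid(result["Qcor_out"], t)
        assert q_in == pytest.approx(q_out, rel=5e-3)

    def test_pump_reshapes_flow_phasically_but_not_its_mean(
            self, normal_preset, normal_steady):
        # For this linear coronary branch the cycle-mean flow is set by the
        # mean aortic-to-atrial gradient and is (nearly) independent of the
        # intramyocardial coupling; what gamma does is squeeze inflow out of
        # systole, which shows up as a much larger CBF-AoP loop.
        result, base, _ = normal_steady
        free = dataclasses.replace(
            normal_preset,
            coronary=dataclasses.replace(normal_preset.coronary, gamma=0.0))
        res0, summary, _ = run_steady(free)
        assert summary.mean_cbf == pytest.approx(base.mean_cbf, rel=0.02)
        assert base.cbf_aop_area > 5.0 * summary.cbf_aop_area
        assert np.min(result["Qcor"]) < np.min(res0["Qcor"])


class TestVolumeConservation:
    def test_closed_loop_volume_drift_under_0p1_percent(self, normal_preset):
        from cardiotal.circuits import simulate
        from cardiotal.vasculature import initial_state
        net = build_full_network(normal_preset)
        st = initial_state(normal_preset, net)
        res = simulate(net, st, duration=20 * net.period, dt=1e-4,
                       record_every=200)
        volumes = np.column_stack(
            [res.waveforms[k] for k in net.compiled().volume_keys])
        total = volumes.sum(axis=1)
        assert np.max(np.abs(total - total[0])) < 1e-3 * total[0]

    def test_stated_blood_volume_is_honoured(self, normal_preset):
        from cardiotal.vasculature import implied_blood_volume, initial_state
        vol = implied_blood_volume(normal_preset)
        preset = dataclasses.replace(normal_preset,
                                     total_blood_volume=vol + 100.0)
        st = initial_state(preset)
        n = len(build_full_network(preset).compiled().storages)
        assert np.sum(st.values[:n]) == pytest.approx(vol + 100.0, abs=1.0)
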