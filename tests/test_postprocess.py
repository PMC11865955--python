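"""Wave-intensity decomposition, reflection coefficient, WSS, summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulsetree.parameters import MMHG, BloodParams, ModelParameters
from pulsetree.postprocess import (
    reflection_coefficient,
    summarize,
    wia,
    wia_at,
    wss,
)
from pulsetree.solver import Solution, SolverConfig, solve
from tests.conftest import make_pulse_inflow

RHO = 1.06
C = 500.0


def signals(n=50, seed=0):
    rng = np.random.default_rng(seed)
    return rng.standard_normal(n).cumsum(), rng.standard_normal(n).cumsum()


class TestWIADecomposition:
    def test_constant_velocity_splits_pressure_evenly(self):
        p = np.array([0.0, 2.0, 5.0, 3.0, 3.5])
        u = np.full(5, 1.7)
        s = wia(p, u, RHO, C)
        assert np.allclose(s.dp_plus, np.diff(p) / 2)
        assert np.allclose(s.dp_minus, np.diff(p) / 2)

    def test_pure_forward_wave_has_no_backward_component(self):
        u = np.array([0.0, 1.0, 3.0, 2.0, 2.5])
        p = RHO * C * u  # dp = rho c du exactly
        s = wia(p, u, RHO, C)
        assert np.allclose(s.dp_minus, 0.0, atol=1e-12)
        assert np.allclose(s.wi_minus, 0.0, atol=1e-12)
        assert np.allclose(s.du_minus, 0.0, atol=1e-12)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True, database=None)
    def test_reconstruction_identities_machine_precision(self, seed):
        # dp+ + dp- = dp, du+ + du- = du, and the cumulated components
        # rebuild the signals exactly
        p, u = signals(seed=seed)
        s = wia(p, u, RHO, C)
        assert np.allclose(s.dp_plus + s.dp_minus, np.diff(p), rtol=0, atol=1e-10)
        assert np.allclose(s.du_plus + s.du_minus, np.diff(u), rtol=0, atol=1e-10)
        assert np.allclose(s.p_plus + s.p_minus, p, rtol=0, atol=1e-9)
        assert np.allclose(s.u_plus + s.u_minus, u, rtol=0, atol=1e-9)

    def test_water_hammer_relation_between_components(self):
        p, u = signals(seed=5)
        s = wia(p, u, RHO, C)
        assert np.allclose(s.dp_plus, RHO * C * s.du_plus)
        assert np.allclose(s.dp_minus, -RHO * C * s.du_minus)


class TestReflectionCoefficient:
    def build(self, forward, backward):
        # engineer p, u so dp+ and dp- are exactly the given increments
        dpf = np.diff(forward)
        dpb = np.diff(backward)
        p = np.concatenate([[0.0], np.cumsum(dpf + dpb)])
        u = np.concatenate([[0.0], np.cumsum((dpf - dpb) / (RHO * C))])
        return wia(p, u, RHO, C)

    def test_pure_forward_wave(self):
        f = np.array([0.0, 3.0, 6.0, 2.0, 0.0])
        s = self.build(f, np.zeros(5))
        assert reflection_coefficient(s) == 0.0

    def test_half_amplitude_reflection(self):
        f = np.array([0.0, 3.0, 6.0, 2.0, 0.0])
        s = self.build(f, 0.5 * f)
        assert reflection_coefficient(s) == pytest.approx(0.5, rel=1e-12)

    def test_no_incident_wave_is_flagged_missing(self):
        f = np.array([0.0, -1.0, -2.0, -2.0])  # only expansion
        s = self.build(f, np.zeros(4))
        assert math.isnan(reflection_coefficient(s))

    def test_matched_outlet_run_has_small_reflection(self):
        # terminal load = characteristic impedance of the (lossy) line:
        # a small pulse leaves without reflection, IR well below 0.05
        import pandas as pd
        from pulsetree.network import build_network
        from pulsetree.waveforms import FlowWaveform

        pars = ModelParameters.nominal("DORV", T=0.71)
        blood = pars.blood
        r0 = 0.5
        A0 = math.pi * r0**2
        f = float(pars.large_law(1)(r0))
        C = 3.0 * A0 / (2.0 * f)

        def z_matched(w):
            w = np.asarray(w, dtype=float)
            zs = 1j * w * blood.rho / A0 + \
                2 * math.pi * blood.nu * blood.rho * r0 / (blood.delta * A0**2)
            ys = 1j * w * C
            out = np.sqrt(zs / np.where(w == 0, 1.0, ys))
            out[w == 0] = abs(out[1]) if len(out) > 1 else 1.0
            return out

        tab = pd.DataFrame([dict(id=1, name="v", length_cm=15.0, r_in_cm=r0,
                                 r_out_cm=r0, group_large=1, group_small=1,
                                 r_min_cm=0.01)])
        net = build_network(tab, [])
        T = 0.71
        t = np.arange(64) * T / 64
        q = 10.0 + 3.0 * np.exp(-0.5 * ((t - 0.12) / 0.02) ** 2)
        sol = solve(net, FlowWaveform(t, q, T), pars,
                    SolverConfig(points_per_cm=2, periodicity_tol=1e-5),
                    terminal_loads={1: z_matched})
        s = wia_at(sol, pars, 1, 0.5)
        assert reflection_coefficient(s) < 0.05


class TestWSS:
    def test_zero_flow_zero_stress(self):
        out = wss(np.zeros(10), np.full(10, 0.5), mu=0.032, delta=0.06)
        assert np.all(out.tau_w == 0.0)

    def test_unit_velocity_value(self):
        # tau = mu * ubar / delta = 0.032 * 1 / 0.06
        out = wss(np.array([0.5]), np.array([0.5]), mu=0.032, delta=0.06)
        assert out.tau_w[0] == pytest.approx(0.032 / 0.06, rel=1e-12)

    def test_linear_in_flow_and_sign_follows(self):
        q = np.array([-2.0, -1.0, 1.0, 2.0])
        A = np.full(4, 0.8)
        out = wss(q, A, mu=0.032, delta=0.05)
        assert np.allclose(out.tau_w, (0.032 / 0.05) * q / A)
        assert np.all(np.sign(out.tau_w) == np.sign(q))

    def test_positive_area_required(self):
        with pytest.raises(ValueError):
            wss(np.ones(3), np.array([1.0, 0.0, 1.0]), 0.032, 0.06)


def fake_solution(p, q, A, T=1.0):
    n = len(p)
    net = None
    return Solution(network=net, T=T, t=np.arange(n) * T / n,
                    x={1: np.array([0.0, 1.0])},
                    p={1: np.column_stack([p, p])},
                    q={1: np.column_stack([q, q])},
                    A={1: np.column_stack([A, A])},
                    converged=True, cycles_used=1, n_t=n)


class TestSummarize:
    def test_constant_fields_zero_pulse(self):
        sol = fake_solution(np.full(8, 90.0), np.full(8, 5.0), np.full(8, 1.2))
        m = summarize(sol, 1, 0.5)
        assert m.pulse_pressure == 0.0
        assert m.pulse_flow == 0.0
        assert m.area_deformation == 0.0

    def test_half_sine_pressure_metrics(self):
        t = np.linspace(0, 1, 200, endpoint=False)
        p = 80.0 + 40.0 * np.maximum(np.sin(2 * np.pi * t), 0.0)
        sol = fake_solution(p, np.zeros(200), np.ones(200))
        m = summarize(sol, 1, 0.0)
        assert m.p_systolic == pytest.approx(120.0, abs=0.01)
        assert m.p_diastolic == pytest.approx(80.0)
        assert m.pulse_pressure == pytest.approx(40.0, abs=0.01)

    def test_location_outside_grid_rejected(self):
        sol = fake_solution(np.ones(4), np.ones(4), np.ones(4))
        with pytest.raises(ValueError):
            summarize(sol, 1, 1.5)


class TestStiffnessDirectionality:
    @pytest.fixture(scope="class")
    def stiff_pair(self):
        from pulsetree.synthetic import three_vessel_network

        net = three_vessel_network("DORV")
        inflow = make_pulse_inflow(T=0.71)
        cfg = SolverConfig(points_per_cm=0.5, periodicity_tol=1e-4)
        base = ModelParameters.nominal("DORV", T=0.71)
        stiff = base.update({"k3": 3 * 5.6e5, "ks3": 3 * 3.8e5})
        return (solve(net, inflow, base, cfg), base,
                solve(net, inflow, stiff, cfg), stiff)

    def test_stiffer_vessels_deform_less(self, stiff_pair):
        sol_a, _, sol_b, _ = stiff_pair
        da = summarize(sol_a, 1, 0.5).area_deformation
        db = summarize(sol_b, 1, 0.5).area_deformation
        assert db < da

    def test_stiffer_vessels_raise_pulse_pressure(self, stiff_pair):
        sol_a, _, sol_b, _ = stiff_pair
        pa = summarize(sol_a, 1, 0.5).pulse_pressure
        pb = summarize(sol_b, 1, 0.5).pulse_pressure
        assert pb > pa
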