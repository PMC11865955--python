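"""Lax-Wendroff scheme, boundary closures and network solver physics."""

import math

import numpy as np
import pandas as pd
import pytest

from pulsetree.network import build_network
from pulsetree.parameters import MMHG, BloodParams, ModelParameters, StiffnessLaw
from pulsetree.solver import (
    SolverConfig,
    large_vessel_stiffness,
    lax_wendroff_step,
    pulse_wave_velocity,
    solve,
    wall_pressure,
)
from pulsetree.structured_tree import root_impedance, vessel_input_impedance
from pulsetree.parameters import TreeParams
from tests.conftest import make_pulse_inflow


PARS = ModelParameters.nominal("DORV", T=0.71)


def single_vessel(L=10.0, r_in=0.5, r_out=0.5, rmin=0.01):
    tab = pd.DataFrame([dict(id=1, name="v", length_cm=L, r_in_cm=r_in,
                             r_out_cm=r_out, group_large=1, group_small=1,
                             r_min_cm=rmin)])
    return build_network(tab, [])


class TestWallPressure:
    def test_unstressed_state(self):
        assert wall_pressure(2.0, 2.0, 5.6e5, p0_mmhg=7.0) == pytest.approx(7.0)

    def test_infinite_distension_asymptote(self):
        p = wall_pressure(1e12, 1.0, 5.6e5)
        assert p == pytest.approx((4.0 / 3.0) * 5.6e5 / MMHG, rel=1e-5)

    def test_four_fold_area(self):
        # (4/3) * 5.6e5 * (1 - 1/2) = 3.733e5 CGS = 280.0 mmHg
        assert wall_pressure(4.0, 1.0, 5.6e5) == pytest.approx(280.0, abs=0.1)

    def test_nonpositive_area_signals_instability(self):
        with pytest.raises(ValueError):
            wall_pressure(np.array([1.0, -0.1]), 1.0, 5.6e5)


class TestLargeVesselStiffness:
    LAW = StiffnessLaw(k1=2.0e7, k2=-25.0, k3=5.6e5)

    def test_large_radius_dominated_by_offset(self):
        assert large_vessel_stiffness(1.0, self.LAW) == pytest.approx(5.600e5, rel=1e-3)
        assert large_vessel_stiffness(50.0, self.LAW) == pytest.approx(5.6e5)

    def test_small_vessels_are_stiffer(self):
        r = np.linspace(0.05, 1.5, 30)
        vals = self.LAW(r)
        assert np.all(np.diff(vals) < 0)

    def test_pwv_from_linearized_wall_law(self):
        c = pulse_wave_velocity(1.0, 5.6e5, rho=1.06)
        assert c == pytest.approx(math.sqrt(2 * 5.6e5 / (3 * 1.06)))


def periodic_march(A, q, blood, A0, f, dt, dx, steps):
    """March the interior scheme on a periodic lattice (ghost-cell wrap)."""
    for _ in range(steps):
        Ae = np.concatenate([A[-1:], A, A[:1]])
        qe = np.concatenate([q[-1:], q, q[:1]])
        An, qn = lax_wendroff_step(Ae, qe, A0, f, dt, dx, blood)
        A, q = An[1:-1], qn[1:-1]
    return A, q


class TestLaxWendroffScheme:
    def test_equilibrium_is_exact(self):
        # uniform vessel at rest is a fixed point of the update
        blood = BloodParams(T=0.8)
        A = np.full(30, 0.5)
        q = np.zeros(30)
        A2, q2 = periodic_march(A, q, blood, 0.5, 5.6e5, 1e-4, 0.5, steps=50)
        assert np.array_equal(A2, A)
        assert np.array_equal(q2, q)

    def test_discrete_mass_conservation(self):
        # interior fluxes telescope: total volume on a periodic lattice is
        # preserved to round-off
        rng = np.random.default_rng(3)
        blood = BloodParams(T=0.8)
        x = np.linspace(0, 1, 64, endpoint=False)
        A = 0.5 * (1.0 + 0.05 * np.sin(2 * np.pi * x) + 0.02 * rng.standard_normal(64))
        q = 2.0 + 0.3 * np.cos(2 * np.pi * x)
        A2, _ = periodic_march(A, q, blood, 0.5, 5.6e5, 2e-5, 1.0 / 64, steps=40)
        assert abs(A2.sum() - A.sum()) <= 1e-12 * A.sum()

    def test_second_order_convergence_on_smooth_pulse(self):
        # frictionless uniform vessel: self-convergence slope >= 1.8
        blood = BloodParams(T=0.8, nu=1e-30)
        A0, f = 0.5, 5.6e5
        c0 = math.sqrt(2 * f / (3 * blood.rho))
        Ldom = 10.0
        t_end = 2e-3

        def run(N):
            dx = Ldom_ = Ldom / N
            x = np.arange(N) * dx
            A = A0 * (1.0 + 0.01 * np.exp(-((x - 5.0) / 0.8) ** 2))
            q = np.zeros(N)
            dt = 0.25 * dx / c0
            steps = int(round(t_end / dt))
            return periodic_march(A, q, blood, A0, f, t_end / steps, dx, steps)[0]

        a1, a2, a4 = run(100), run(200), run(400)
        e1 = np.linalg.norm(a1 - a2[::2]) / math.sqrt(100)
        e2 = np.linalg.norm(a2 - a4[::2]) / math.sqrt(200)
        order = math.log2(e1 / e2)
        assert order >= 1.8

    def test_cfl_violation_aborts(self):
        from pulsetree.solver import SolverError

        blood = BloodParams(T=0.8)
        A = np.full(20, 0.5)
        A[10] *= 1.2
        q = np.zeros(20)
        with pytest.raises(SolverError, match="CFL|area"):
            # dt far above the CFL limit blows the half-step up
            for _ in range(50):
                Ae = np.concatenate([A[-1:], A, A[:1]])
                qe = np.concatenate([q[-1:], q, q[:1]])
                An, qn = lax_wendroff_step(Ae, qe, 0.5, 5.6e5, 5e-3, 0.05, blood)
                A, q = An[1:-1], qn[1:-1]


class TestNetworkSolve:
    def test_constant_inflow_reaches_dc_load(self):
        # after transients p(L) = p0 + Z_DC * qbar
        net = single_vessel(L=5.0, r_in=0.3, r_out=0.3)
        pars = ModelParameters.nominal("DORV", T=0.8)
        from dataclasses import replace

        pars = replace(pars, blood=replace(pars.blood, p0_mmhg=5.0))
        T = 0.8
        t = np.arange(32) * T / 32
        from pulsetree.waveforms import FlowWaveform

        inflow = FlowWaveform(t, np.full(32, 10.0), T)
        sol = solve(net, inflow, pars, SolverConfig(points_per_cm=2,
                                                    periodicity_tol=1e-6))
        tp = pars.tree_params(1, 0.01)
        Z0 = root_impedance(0.3, tp, pars.blood, K_f=4).Z[0].real
        expect = 5.0 + Z0 * 10.0 / MMHG
        assert sol.pressure(1, 1.0).mean() == pytest.approx(expect, rel=1e-3)
        assert sol.flow(1, 1.0).mean() == pytest.approx(10.0, rel=1e-3)

    def test_periodic_mass_balance_three_vessel(self):
        from pulsetree.synthetic import three_vessel_network

        net = three_vessel_network("DORV")
        inflow = make_pulse_inflow(T=0.71)
        sol = solve(net, inflow, PARS, SolverConfig(points_per_cm=0.5,
                                                    periodicity_tol=1e-4))
        out = sum(sol.flow(v, 1.0).mean() for v in net.terminal_ids)
        assert out == pytest.approx(inflow.mean(), rel=0.01)

    def test_junction_mass_and_pressure_continuity(self):
        from pulsetree.synthetic import three_vessel_network

        net = three_vessel_network("DORV")
        sol = solve(net, make_pulse_inflow(T=0.71), PARS,
                    SolverConfig(points_per_cm=0.5))
        qp = sol.flow(1, 1.0)
        qd = sol.flow(7, 0.0) + sol.flow(3, 0.0)
        assert np.allclose(qp, qd, atol=1e-8 * np.max(np.abs(qp)))
        pp = sol.pressure(1, 1.0)
        assert np.allclose(pp, sol.pressure(7, 0.0), atol=1e-8 * np.max(pp))
        assert np.allclose(pp, sol.pressure(3, 0.0), atol=1e-8 * np.max(pp))

    def test_symmetric_bifurcation_splits_flow_evenly(self):
        rows = [dict(id=1, name="p", length_cm=5.0, r_in_cm=0.6, r_out_cm=0.6,
                     group_large=1, group_small=None, r_min_cm=None)]
        for vid in (2, 3):
            rows.append(dict(id=vid, name=f"d{vid}", length_cm=6.0, r_in_cm=0.4,
                             r_out_cm=0.4, group_large=1, group_small=1,
                             r_min_cm=0.01))
        net = build_network(pd.DataFrame(rows), [(1, 2), (1, 3)])
        sol = solve(net, make_pulse_inflow(T=0.71), PARS, SolverConfig())
        assert np.allclose(sol.flow(2, 0.5), sol.flow(3, 0.5), rtol=1e-10)

    def test_single_child_junction_is_transparent(self):
        # a vessel split in two must behave like the unsplit vessel; the
        # residual mismatch is discretization-level and shrinks under
        # refinement
        inflow = make_pulse_inflow(T=0.71)

        def run(split, ppc):
            if split:
                rows = [dict(id=1, name="a", length_cm=5.0, r_in_cm=0.4,
                             r_out_cm=0.4, group_large=1, group_small=None,
                             r_min_cm=None),
                        dict(id=2, name="b", length_cm=5.0, r_in_cm=0.4,
                             r_out_cm=0.4, group_large=1, group_small=1,
                             r_min_cm=0.01)]
                net = build_network(pd.DataFrame(rows), [(1, 2)])
            else:
                net = single_vessel(L=10.0, r_in=0.4, r_out=0.4)
            cfg = SolverConfig(points_per_cm=ppc, n_t=2048, periodicity_tol=1e-5)
            sol = solve(net, inflow, PARS, cfg)
            # x = 2.5 cm from the inlet in both configurations
            return sol.pressure(1, 0.5 if split else 0.25)

        for ppc, tol in ((2, 2e-3), (4, 1e-3)):
            pa = run(False, ppc)
            pb = run(True, ppc)
            amp = pa.max() - pa.min()
            assert np.max(np.abs(pa - pb)) < tol * amp

    def test_linear_regime_matches_frequency_domain_impedance(self):
        # small sinusoid on a steady flow: inlet pressure amplitude agrees
        # with the transmission-line input impedance of vessel + tree load
        net = single_vessel(L=8.0, r_in=0.5, r_out=0.5, rmin=0.01)
        pars = ModelParameters.nominal("DORV", T=0.8)
        blood = pars.blood
        T = 0.8
        n = 64
        t = np.arange(n) * T / n
        eps = 1.0
        from pulsetree.waveforms import FlowWaveform

        inflow = FlowWaveform(t, 10.0 + eps * np.sin(2 * np.pi * t / T), T)
        sol = solve(net, inflow, pars, SolverConfig(points_per_cm=2,
                                                    periodicity_tol=1e-6))
        p_in = sol.pressure(1, 0.0) * MMHG
        spec = np.fft.rfft(p_in)
        amp = 2.0 * np.abs(spec[1]) / sol.n_t

        omega1 = 2 * math.pi / T
        f_large = float(pars.large_law(1)(0.5))
        line = TreeParams(tree_alpha=0.9, tree_beta=0.6, lrr=50.0, r_min_cm=0.01,
                          ks1=0.0, ks2=-1.0, ks3=f_large)  # constant-stiffness line
        tp = pars.tree_params(1, 0.01)
        Z_load = root_impedance(0.5, tp, blood, T=T, K_f=1).Z[1]
        Z_in = vessel_input_impedance(Z_load, omega1, 0.5, 8.0, line, blood)
        assert amp == pytest.approx(abs(Z_in) * eps, rel=0.05)

    def test_wavefront_speed_matches_linearized_pwv(self):
        # long uniform vessel, matched (reflection-free) outlet: transit time
        # between two stations equals distance / sqrt(2Eh/(3 rho r0))
        pars = ModelParameters.nominal("DORV", T=0.8)
        r0 = 1.0
        f = float(pars.large_law(1)(r0))
        c0 = float(pulse_wave_velocity(r0, f, pars.blood.rho))
        A0 = math.pi * r0**2
        Zc = pars.blood.rho * c0 / A0
        net = single_vessel(L=60.0, r_in=r0, r_out=r0)
        T = 0.8
        t = np.arange(64) * T / 64
        q = 2.0 + 5.0 * np.exp(-0.5 * ((t - 0.1) / 0.012) ** 2)
        from pulsetree.waveforms import FlowWaveform

        sol = solve(net, FlowWaveform(t, q, T), pars,
                    SolverConfig(points_per_cm=2, periodicity_tol=1e-5),
                    terminal_loads={1: lambda w: np.full(len(w), Zc, dtype=complex)})
        qa = sol.flow(1, 15.0 / 60.0)
        qb = sol.flow(1, 45.0 / 60.0)
        qa = qa - qa.mean()
        qb = qb - qb.mean()
        xc = np.array([np.dot(qa, np.roll(qb, -k)) for k in range(sol.n_t)])
        k = int(np.argmax(xc))
        # parabolic sub-sample refinement of the correlation peak
        y0, y1, y2 = xc[(k - 1) % sol.n_t], xc[k], xc[(k + 1) % sol.n_t]
        frac = 0.5 * (y0 - y2) / (y0 - 2 * y1 + y2)
        delay = (k + frac) * T / sol.n_t
        assert delay == pytest.approx(30.0 / c0, rel=0.03)

    def test_doubling_resolution_changes_systolic_pressure_little(self):
        from pulsetree.synthetic import three_vessel_network

        net = three_vessel_network("DORV")
        inflow = make_pulse_inflow(T=0.71)
        sys_p = []
        for ppc in (0.5, 1.0):
            sol = solve(net, inflow, PARS, SolverConfig(points_per_cm=ppc,
                                                        periodicity_tol=1e-4))
            sys_p.append(sol.pressure(7, 0.5).max())
        assert abs(sys_p[1] - sys_p[0]) / sys_p[0] < 0.01
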