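import math

import numpy as np
import pytest

from ngvu.net1d import (ArterialNetwork1D, NetworkSolver, Vessel1D,
                        Windkessel0D, default_network, inlet_flow,
                        run_to_periodicity, wave_speed, windkessel_update,
                        young_laplace_pressure)
from ngvu.net1d.solver import solve_junction_system
from ngvu.net1d.vessels import RHO_DEFAULT, RHO_PRINTED, stiffness_g0
from ngvu.units import MMHG_TO_CGS, PA_TO_CGS
from ngvu.viscosity import ConstantViscosity


class TestTubeLaw:
    def test_reference_state(self):
        assert young_laplace_pressure(2.0, 2.0, 1e5) == pytest.approx(0.0)

    def test_quadruple_area(self):
        assert young_laplace_pressure(8.0, 2.0, 1e5) == pytest.approx(1e5)

    def test_vessel37_hand_oracle(self):
        # independent arithmetic from the printed parameters:
        # h0=0.034 cm, E=0.8e6 Pa, R0=0.08 cm, nu=1/2
        h0, e_pa, r0 = 0.034, 0.8e6, 0.08
        a0 = math.pi * r0 ** 2
        g0_pa = math.sqrt(math.pi) * h0 * e_pa / ((1 - 0.25) * math.sqrt(a0))
        v = Vessel1D(id=37, length=6.0, r0=r0, h0=h0, e_pa=e_pa)
        assert v.g0 == pytest.approx(g0_pa * PA_TO_CGS, rel=1e-12)
        assert v.a0 == pytest.approx(a0, rel=1e-15)
        p = young_laplace_pressure(2 * v.a0, v.a0, v.g0)
        assert p == pytest.approx(v.g0 * (math.sqrt(2) - 1.0), rel=1e-12)

    def test_monotone_in_area(self):
        a = np.linspace(0.5, 4.0, 50)
        p = young_laplace_pressure(a, 1.0, 1e5)
        assert np.all(np.diff(p) > 0)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            young_laplace_pressure(-1.0, 1.0, 1e5)


class TestInletFlow:
    def test_zero_at_start(self):
        assert inlet_flow(0.0, 1.0, 485.0) == pytest.approx(0.0)

    def test_peak(self):
        assert inlet_flow(0.15, 1.0, 485.0) == pytest.approx(485.0)

    def test_second_branch_zero(self):
        assert inlet_flow(0.5, 1.0, 485.0) == 0.0

    def test_continuity_at_cutoff(self):
        eps = 1e-9
        assert abs(inlet_flow(0.3 - eps, 1.0, 485.0)) < 1e-4
        assert inlet_flow(0.3 + eps, 1.0, 485.0) == 0.0

    def test_periodic_extension(self):
        assert inlet_flow(1.15, 1.0, 485.0) == pytest.approx(485.0)

    def test_negative_qmax_rejected(self):
        with pytest.raises(ValueError):
            inlet_flow(0.1, 1.0, -1.0)


class TestWindkessel:
    def test_exponential_decay(self):
        # Q=0 from charged state: Pc(t) = Pven + (Pc0-Pven) exp(-t/(R2 C))
        r2, c = 100.0, 0.01
        wk = Windkessel0D(r1=10.0, r2=r2, c=c,
                          state_pressure=1e5, venous_pressure=1e4)
        dt = 1e-4
        n = int(round(r2 * c / dt))  # one time constant
        for _ in range(n):
            windkessel_update(0.0, wk, dt)
        expected = 1e4 + 9e4 * math.exp(-1.0)
        assert wk.state_pressure == pytest.approx(expected, rel=1e-3)

    def test_steady_state(self):
        wk = Windkessel0D(r1=10.0, r2=100.0, c=0.001,
                          state_pressure=0.0, venous_pressure=1e4)
        q = 2.0
        p = 0.0
        for _ in range(20000):
            p = windkessel_update(q, wk, 1e-4)
        assert p == pytest.approx(1e4 + q * 110.0, rel=1e-4)

    def test_infinite_capacitor_limit(self):
        wk = Windkessel0D(r1=10.0, r2=100.0, c=1e9, state_pressure=5e4)
        p0 = wk.state_pressure
        for _ in range(1000):
            windkessel_update(3.0, wk, 1e-3)
        assert wk.state_pressure == pytest.approx(p0, rel=1e-6)

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            Windkessel0D(r1=-1.0, r2=1.0, c=1.0)


def _junction_inputs(g0s, a0s, rho=RHO_DEFAULT):
    a0 = np.array([a0s])
    g0 = np.array([g0s])
    c0 = wave_speed(a0, a0, g0, rho)
    return a0, g0, c0


class TestJunctionNewton:
    def test_symmetric_bifurcation_equal_children(self):
        a0, g0, c0 = _junction_inputs([5e5, 8e5, 8e5], [1.0, 0.4, 0.4])
        sigma = np.array([[1.0, -1.0, -1.0]])
        w_out = np.array([[30.0, -5.0, -5.0]])
        a, u, ok, res = solve_junction_system(
            a0.copy(), np.zeros_like(a0), w_out, a0, g0, c0, sigma,
            RHO_DEFAULT)
        assert ok.all()
        assert a[0, 1] == pytest.approx(a[0, 2], rel=1e-12)
        assert (a[0, 1] * u[0, 1]) == pytest.approx(a[0, 2] * u[0, 2],
                                                    rel=1e-12)
        # mass conservation
        assert a[0, 0] * u[0, 0] == pytest.approx(2 * a[0, 1] * u[0, 1],
                                                  rel=1e-10)

    def test_passthrough_two_vessel_junction(self):
        a0, g0, c0 = _junction_inputs([5e5, 5e5], [1.0, 1.0])
        sigma = np.array([[1.0, -1.0]])
        w_out = np.array([[12.0, -2.0]])
        a, u, ok, _ = solve_junction_system(
            a0.copy(), np.zeros_like(a0), w_out, a0, g0, c0, sigma,
            RHO_DEFAULT)
        assert ok.all()
        # identical properties: both ends take the same state
        assert a[0, 0] == pytest.approx(a[0, 1], rel=1e-10)
        assert u[0, 0] == pytest.approx(u[0, 1], rel=1e-10)

    def test_asymmetric_residuals_tight(self):
        a0, g0, c0 = _junction_inputs([5e5, 7e5, 9e5], [1.0, 0.5, 0.2])
        sigma = np.array([[1.0, -1.0, -1.0]])
        w_out = np.array([[40.0, -3.0, -8.0]])
        a, u, ok, res = solve_junction_system(
            a0.copy(), np.zeros_like(a0), w_out, a0, g0, c0, sigma,
            RHO_DEFAULT)
        assert ok.all()
        assert res[0] < 1e-10
        # verify the two coupling conditions independently
        rho = RHO_DEFAULT
        p = g0 * (np.sqrt(a / a0) - 1.0)
        pt = p + 0.5 * rho * u ** 2
        assert pt[0, 1] == pytest.approx(pt[0, 0], rel=1e-10)
        assert pt[0, 2] == pytest.approx(pt[0, 0], rel=1e-10)
        q = (sigma * a * u).sum()
        assert abs(q) < 1e-10 * abs(a[0, 0] * u[0, 0] + 1e-30)


def single_vessel_net(length=20.0, r0=0.3, h0=0.05, e_pa=4e5, n_cells=100,
                      mu=3.5e-3):
    v = Vessel1D(id=1, length=length, r0=r0, h0=h0, e_pa=e_pa,
                 n_cells=n_cells)
    wk = Windkessel0D(r1=1.0, r2=1e5, c=1e-2, state_pressure=0.0,
                      venous_pressure=0.0)
    return ArterialNetwork1D(vessels={1: v}, junctions=[], inlet_vessel=1,
                             outlet_ids=[1], outlets={1: wk},
                             viscosity_law=ConstantViscosity(mu))


class TestHyperbolicStep:
    def test_rest_state_unchanged(self):
        net = single_vessel_net()
        s = NetworkSolver(net)
        f = s.initial_field()
        for _ in range(50):
            f = s.step(f, lambda t: 0.0)
        assert np.allclose(f.a, s.a0_pad, rtol=1e-12)
        assert np.allclose(f.q, 0.0, atol=1e-12)

    def test_pulse_speed_matches_characteristic(self):
        """Wave-speed oracle: small pulse travels at c(A0) within 5%."""
        net = single_vessel_net(length=40.0, n_cells=400, mu=1e-6)
        s = NetworkSolver(net)
        v = net.vessels[1]
        c0 = wave_speed(v.a0, v.a0, v.g0, net.rho)
        f = s.initial_field()
        t_pulse = 2e-3
        amp = 0.5

        def inflow(t):
            return amp * math.sin(math.pi * t / t_pulse) ** 2 \
                if t < t_pulse else 0.0

        probe = int(0.75 * v.n_cells)
        x_probe = probe * v.dz
        t_arrival = None
        for _ in range(int(1.2 * x_probe / c0 / s.dt) + 200):
            f = s.step(f, inflow)
            if t_arrival is None and f.q[0, probe] > 0.1 * amp:
                t_arrival = f.t
                break
        assert t_arrival is not None
        # subtract half the pulse width as the effective launch time
        speed = x_probe / (t_arrival - 0.5 * t_pulse)
        assert speed == pytest.approx(c0, rel=0.05)

    def test_volume_balance_against_boundary_flux(self):
        net = single_vessel_net(n_cells=200)
        s = NetworkSolver(net)
        f = s.initial_field()
        v = net.vessels[1]

        def vol(field):
            return np.trapezoid(field.a[0, :v.n_cells + 1], dx=v.dz)

        v0 = vol(f)
        flux_in = 0.0
        inflow = lambda t: inlet_flow(t, 1.0, 5.0)
        for _ in range(2000):
            f_new = s.step(f, inflow)
            flux_in += s.dt * 0.5 * (f.q[0, 0] + f_new.q[0, 0])
            flux_in -= s.dt * 0.5 * (f.q[0, v.n_cells]
                                     + f_new.q[0, v.n_cells])
            f = f_new
        dv = vol(f) - v0
        assert dv == pytest.approx(flux_in, rel=2e-2, abs=1e-6)

    def test_grid_self_convergence(self):
        """Halving dz shrinks the error vs a fine-grid reference at
        order >= 1."""
        t_end = 0.02
        results = {}
        for n_cells in (50, 100, 200, 800):
            net = single_vessel_net(length=20.0, n_cells=n_cells, mu=1e-6)
            s = NetworkSolver(net, cfl=0.4)
            f = s.initial_field()
            inflow = lambda t: 2.0 * math.sin(
                math.pi * min(t / 0.01, 1.0)) ** 2
            while f.t < t_end:
                f = s.step(f, inflow)
            v = net.vessels[1]
            x = np.linspace(0.0, v.length, v.n_cells + 1)
            results[n_cells] = (x, f.a[0, :v.n_cells + 1].copy())
        x_ref, a_ref = results[800]
        errs = []
        for n_cells in (50, 100, 200):
            x, a = results[n_cells]
            a_interp = np.interp(x, x_ref, a_ref)
            errs.append(np.max(np.abs(a - a_interp)))
        order = np.log2(errs[0] / errs[1])
        order2 = np.log2(errs[1] / errs[2])
        assert min(order, order2) >= 0.9

    def test_blowup_flagged(self):
        net = single_vessel_net(n_cells=50)
        s = NetworkSolver(net)
        f = s.initial_field()
        f.a[0, :] = -1.0
        with pytest.raises(Exception):
            s.step(f, lambda t: 0.0)


class TestDefaultNetwork:
    def test_loads_37_vessels(self):
        net = default_network()
        assert len(net.vessels) == 37
        assert net.inlet_vessel == 1
        assert set(net.outlets) == {8, 10, 13, 15, 16, 21, 22, 29, 30, 32,
                                    33, 35, 37}

    def test_paper_table_values(self):
        net = default_network()
        for vid in (35, 37):
            v = net.vessels[vid]
            assert (v.length, v.r0, v.h0, v.e_pa) == (6.0, 0.08, 0.034, 0.8e6)
            assert v.source == "paper"
        for vid in (14, 17):
            assert net.vessels[vid].length == pytest.approx(9.866)

    def test_a0_invariant(self):
        net = default_network()
        for v in net.vessels.values():
            assert v.a0 == pytest.approx(math.pi * v.r0 ** 2, rel=1e-14)

    def test_rho_printed_value_warns(self):
        net = default_network(rho=RHO_PRINTED)
        assert any("implausible" in w for w in net.warnings)

    def test_junction_count(self):
        net = default_network()
        # 37 vessels, 13 outlets, 1 inlet -> every other end pairs up
        assert len(net.junctions) == 20
        for parents, children in net.junctions:
            assert len(parents) + len(children) == 3


@pytest.mark.slow
class TestPeriodicRun:
    def test_small_periodic_run(self):
        # single vessel with a calibrated-style windkessel reaches
        # periodicity quickly and satisfies the stopping rule
        net = single_vessel_net(length=10.0, n_cells=40)
        net.outlets[1] = Windkessel0D(r1=50.0, r2=2000.0, c=1.3 / 2000.0,
                                      state_pressure=5e4,
                                      venous_pressure=5e3)
        res = run_to_periodicity(net, T=0.5, q_max=5.0, tol=5e-3,
                                 beats_max=40)
        assert res.converged
        assert res.history[-1] < 5e-3
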