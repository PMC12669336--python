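import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ngvu.nvc import (CrossBridgeState, SmcEcState, WallState,
                      attached_fraction, bk_open_probability,
                      calibrate_fr_norm, cgmp_bk_modulation,
                      cgmp_mlcp_activation, crossbridge_rhs, crossbridge_step,
                      diffusion_taus, enos_activation, hetero_coupling,
                      kir_flux, kir_reversal, nmda_open_prob,
                      no_production_ec, no_production_neuron,
                      no_transport_rhs, sr_uptake, steady_radius,
                      steady_state, wall_radius_rhs, wall_shear_stress,
                      wall_step)
from ngvu.nvc.no_pathway import NOPathwayState


class TestKir:
    def test_zero_at_reversal(self, nvc_params):
        p = nvc_params
        v_kir = kir_reversal(3.5, p)
        assert kir_flux(v_kir, 3.5, p) == pytest.approx(0.0)

    def test_reversal_root(self, nvc_params):
        p = nvc_params
        assert kir_reversal(p.z2 / p.z1, p) == pytest.approx(0.0)

    def test_linearity(self, nvc_params):
        p = nvc_params
        j1 = kir_flux(-40.0, 3.5, p)
        j2 = kir_flux(-30.0, 3.5, p)
        j3 = kir_flux(-20.0, 3.5, p)
        assert j3 - j2 == pytest.approx(j2 - j1, rel=1e-12)


class TestHeteroCoupling:
    def test_equal_compartments_zero(self, nvc_params):
        st = SmcEcState(ca_i=0.3, ca_j=0.3, ip3_i=0.5, ip3_j=0.5,
                        v_i=-40.0, v_j=-40.0)
        fluxes = hetero_coupling(st, nvc_params)
        assert all(abs(v) < 1e-14 for v in fluxes.values())

    def test_antisymmetry(self, nvc_params):
        st = SmcEcState(ca_i=0.2, ca_j=0.5, ip3_i=0.1, ip3_j=0.9,
                        v_i=-30.0, v_j=-60.0)
        sw = SmcEcState(ca_i=0.5, ca_j=0.2, ip3_i=0.9, ip3_j=0.1,
                        v_i=-60.0, v_j=-30.0)
        f1 = hetero_coupling(st, nvc_params)
        f2 = hetero_coupling(sw, nvc_params)
        for k in f1:
            assert f1[k] == pytest.approx(-f2[k], rel=1e-12)

    def test_two_compartment_relaxation_rate(self, nvc_params):
        """Closed-form oracle: isolated pair relaxes to the mean as
        exp(-2 P_Ca t)."""
        p = nvc_params
        ca_i, ca_j = 1.0, 0.0
        dt = 1e-3
        t_end = 5.0
        for _ in range(int(t_end / dt)):
            st = SmcEcState(ca_i=ca_i, ca_j=ca_j)
            f = hetero_coupling(st, p)["J_Ca_cpl"]
            ca_i += dt * f
            ca_j -= dt * f
        diff_expected = math.exp(-2.0 * p.P_Ca * t_end)
        assert ca_i - ca_j == pytest.approx(diff_expected, rel=1e-2)
        assert ca_i + ca_j == pytest.approx(1.0, abs=1e-12)


class TestCrossBridge:
    def test_derivatives_sum_zero(self, nvc_params):
        cb = CrossBridgeState(0.4, 0.3, 0.2, 0.1)
        d = crossbridge_rhs(cb, 0.37, 1.2, nvc_params)
        assert sum(d) == pytest.approx(0.0, abs=1e-14)

    def test_zero_calcium_steady_state(self, nvc_params):
        """Hand-solved steady state at Ca=0: K1=K6=0 forces
        Mp=AMp=AM=0, M=1 (solve the linear system by inspection)."""
        ss = steady_state(0.0, 0.0, nvc_params)
        assert ss.m == pytest.approx(1.0, abs=1e-12)
        assert ss.mp == pytest.approx(0.0, abs=1e-12)
        assert ss.amp == pytest.approx(0.0, abs=1e-12)
        assert ss.am == pytest.approx(0.0, abs=1e-12)

    def test_cgmp_hill_midpoint(self, nvc_params):
        p = nvc_params
        assert cgmp_mlcp_activation(p.K_m_mlcp, p) == pytest.approx(0.5)

    def test_partition_over_long_run(self, nvc_params):
        cb = CrossBridgeState(1.0, 0.0, 0.0, 0.0)
        rng = np.random.default_rng(0)
        dt = 1e-3
        for k in range(10 ** 5):
            ca = 0.3 + 0.2 * math.sin(2 * math.pi * k * dt / 7.0)
            cb = crossbridge_step(cb, ca, 1.0, dt, nvc_params)
            total = cb.m + cb.mp + cb.amp + cb.am
            assert total == pytest.approx(1.0, abs=1e-10)
            assert min(cb.m, cb.mp, cb.amp, cb.am) >= -1e-12

    def test_attached_fraction_endpoints(self, nvc_params):
        cb = CrossBridgeState(1.0, 0.0, 0.0, 0.0, fr_norm=0.5)
        assert attached_fraction(cb) == 0.0
        cb2 = CrossBridgeState(0.5, 0.0, 0.3, 0.2, fr_norm=0.5)
        assert attached_fraction(cb2) == pytest.approx(1.0)

    def test_monotone_response_to_calcium_step(self, nvc_params):
        """ODE oracle: after a step increase in Ca, F_r rises monotonically
        (within solver noise) toward the new equilibrium."""
        p = nvc_params
        ss = steady_state(0.2, 0.0, p)
        cb = CrossBridgeState(ss.m, ss.mp, ss.amp, ss.am,
                              fr_norm=calibrate_fr_norm(p))
        values = []
        for _ in range(40000):
            cb = crossbridge_step(cb, 0.6, 0.0, 1e-3, p)
            values.append(attached_fraction(cb))
        v = np.array(values)
        assert np.all(np.diff(v) >= -1e-9)
        # compare final state to the scipy equilibrium
        ss_end = steady_state(0.6, 0.0, p)
        assert v[-1] * cb.fr_norm == pytest.approx(ss_end.amp + ss_end.am,
                                                   rel=1e-3)


class TestWall:
    def test_equilibrium_no_pressure(self, nvc_params):
        w = WallState(radius=16.8, dp=0.0)
        f_r = 0.4
        from ngvu.nvc import reference_radius
        w.radius = reference_radius(f_r, w)
        assert wall_radius_rhs(w, f_r) == pytest.approx(0.0, abs=1e-12)

    def test_steady_radius_closed_form(self):
        """Algebra oracle: set the rhs to zero by hand ->
        R* = R0(F_r) (1 + 10 dp / E(F_r))."""
        w = WallState(radius=20.0, dp=4000.0, eta=1e5)
        f_r = 0.35
        r_star = steady_radius(w, f_r)
        e = w.e_pas + f_r * (w.e_act - w.e_pas)
        r0 = w.r0_pas + f_r * (w.r0_act - w.r0_pas)
        assert r_star == pytest.approx(r0 * (1.0 + 10.0 * 4000.0 / e),
                                       rel=1e-12)
        # integrate to the steady state and compare to 1e-6 relative
        for _ in range(400000):
            w = wall_step(w, f_r, 1e-3)
        assert w.radius == pytest.approx(r_star, rel=1e-6)

    def test_interpolation_endpoints(self):
        from ngvu.nvc import modulus, reference_radius
        w = WallState()
        assert modulus(0.0, w) == w.e_pas
        assert modulus(1.0, w) == w.e_act
        assert reference_radius(0.0, w) == w.r0_pas
        assert reference_radius(1.0, w) == w.r0_act

    def test_thickness_ratio(self):
        w = WallState(radius=17.3)
        assert w.thickness == pytest.approx(1.73)

    def test_bad_viscosity_rejected(self):
        w = WallState(eta=-1.0)
        with pytest.raises(ValueError):
            wall_radius_rhs(w, 0.5)


class TestNMDAandNO:
    def test_nmda_midpoints(self, nvc_params):
        p = nvc_params
        wa, _ = nmda_open_prob(p.K_m_A, p)
        _, wb = nmda_open_prob(p.K_m_B, p)
        assert wa == pytest.approx(0.5)
        assert wb == pytest.approx(0.5)
        assert nmda_open_prob(0.0, p) == (0.0, 0.0)

    def test_nmda_saturation(self, nvc_params):
        wa, wb = nmda_open_prob(1e9, nvc_params)
        assert wa == pytest.approx(1.0, rel=1e-6)
        assert wb == pytest.approx(1.0, rel=1e-6)

    def test_neuron_production_zero_without_oxygen(self, nvc_params):
        from ngvu.synapse.params import ParamRegistry
        p = nvc_params
        recs = {n: p.record(n) for n in p.names()}
        recs["O2_n"]["value"] = 0.0
        p0 = ParamRegistry(recs)
        assert no_production_neuron(0.5, p0) == pytest.approx(0.0)

    def test_double_half_saturation_quarter(self, nvc_params):
        from ngvu.synapse.params import ParamRegistry
        p = nvc_params
        recs = {n: p.record(n) for n in p.names()}
        recs["O2_n"]["value"] = recs["K_m_O2_n"]["value"]
        recs["LArg_n"]["value"] = recs["K_m_LArg_n"]["value"]
        p4 = ParamRegistry(recs)
        assert no_production_neuron(1.0, p4) \
            == pytest.approx(p.V_max_NO_n / 4.0, rel=1e-12)

    def test_nr2b_weighting_ratio(self, nvc_params):
        from ngvu.nvc.no_pathway import nmda_ca_current
        p = nvc_params
        glu = 7.0
        wa, wb = nmda_open_prob(glu, p)
        i_single = nmda_ca_current(-40.0, p)
        total = i_single * (0.63 * wa + 11.0 * wb)
        ratio = (11.0 * wb) / (0.63 * wa)
        # decompose and verify the printed weighting
        contrib_b = i_single * 11.0 * wb
        contrib_a = i_single * 0.63 * wa
        assert contrib_b / contrib_a == pytest.approx(ratio, rel=1e-12)
        assert total == pytest.approx(contrib_a + contrib_b, rel=1e-12)

    def test_enos_monotone_in_wss(self, nvc_params):
        vals = [enos_activation(0.3, tau, nvc_params)
                for tau in np.linspace(0.0, 50.0, 30)]
        assert np.all(np.diff(vals) >= 0.0)
        assert no_production_ec(0.3, 10.0, nvc_params) \
            >= no_production_ec(0.3, 0.0, nvc_params)


class TestNOTransport:
    def test_equilibrium_all_equal(self, nvc_params):
        st = NOPathwayState(no=np.full(4, 0.3))
        from ngvu.synapse.params import ParamRegistry
        p = nvc_params
        recs = {n: p.record(n) for n in p.names()}
        for k in ("kC_n", "kC_a", "kC_s", "kC_e"):
            recs[k]["value"] = 0.0
        p0 = ParamRegistry(recs)
        d = no_transport_rhs(st, 0.0, 0.0, p0)
        assert np.allclose(d, 0.0, atol=1e-14)

    def test_tau_arithmetic_oracle(self, nvc_params):
        """Independent arithmetic: tau = dx^2/(2 D) for dx = 25 um."""
        p = nvc_params
        taus = diffusion_taus(p)
        assert taus[0] == pytest.approx(25.0 ** 2 / (2.0 * p.D_NO), rel=1e-12)

    def test_scavenging_dissipates(self, nvc_params):
        st = NOPathwayState(no=np.array([0.5, 0.2, 0.4, 0.1]))
        dt = 1e-4
        total_prev = st.no.sum()
        for _ in range(2000):
            d = no_transport_rhs(st, 0.0, 0.0, nvc_params)
            st.no = st.no + dt * d
            total = st.no.sum()
            assert total <= total_prev + 1e-12
            total_prev = total

    def test_wall_shear_stress_formula(self):
        assert wall_shear_stress(2.0, 1.0, 0.003) \
            == pytest.approx(4 * 0.003 * 2.0 / math.pi)
        with pytest.raises(ValueError):
            wall_shear_stress(1.0, 0.0, 0.003)


class TestCgmpBK:
    def test_zero_cgmp_value(self, nvc_params):
        p = nvc_params
        assert cgmp_bk_modulation(0.0, p) \
            == pytest.approx(1.0 / (p.eps_i + p.alpha_i))

    def test_monotone_direction(self, nvc_params):
        """gamma_i < 0: higher cGMP -> larger c_w -> more BK opening."""
        p = nvc_params
        assert p.gamma_i < 0
        c1 = cgmp_bk_modulation(0.5, p)
        c2 = cgmp_bk_modulation(2.0, p)
        assert c2 > c1
        w1 = bk_open_probability(-30.0, 0.5, p)
        w2 = bk_open_probability(-30.0, 2.0, p)
        assert w2 > w1

    def test_invalid_denominator(self):
        from ngvu.synapse.params import ParamRegistry
        p = ParamRegistry({"eps_i": {"value": -2.0}, "alpha_i": {"value": 1.0},
                           "gamma_i": {"value": 0.0}})
        with pytest.raises(ValueError):
            cgmp_bk_modulation(1.0, p)


class TestSrUptake:
    def test_zero(self, nvc_params):
        assert sr_uptake(0.0, nvc_params) == 0.0

    def test_hill_midpoint(self, nvc_params):
        p = nvc_params
        assert sr_uptake(p.c_bi, p) == pytest.approx(p.B_i / 2.0)

    def test_saturation(self, nvc_params):
        p = nvc_params
        assert sr_uptake(1e6, p) == pytest.approx(p.B_i, rel=1e-6)


class TestEndToEndChain:
    def test_monotone_dilation_chain(self, nvc_params):
        """Frozen-input link test: higher sustained cleft Glu ->
        more NO -> more cGMP -> lower F_r -> larger steady radius."""
        from ngvu.nvc import NVCSimulator, constant_drive

        radii, cgmps, frs = [], [], []
        for g in (0.0, 10.0, 60.0):
            sim = NVCSimulator()
            drv = constant_drive(30.0, 1e-3, c_a=0.1, g=g, v_psp=-40.0)
            out = sim.run(drv)
            radii.append(out["R_um"][-1])
            cgmps.append(out["cGMP_uM"][-1])
            frs.append(out["Fr"][-1])
        assert cgmps[0] < cgmps[1] < cgmps[2]
        assert frs[0] > frs[2]
        assert radii[0] < radii[2]
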