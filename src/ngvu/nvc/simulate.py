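"""Coupled neurovascular-coupling simulation.

Advances the SMC/EC compartments, the NO/cGMP pathway, the cross-bridge
cycle and the viscoelastic wall, driven by cellular traces from the
quadripartite synapse (astrocytic calcium, cleft glutamate, postsynaptic
potential) sampled on a uniform grid.  The SMC/EC system is a reduced
Koenigsberger-style model: IP3-gated release from an SR store that is
filled by the astrocytic-calcium uptake flux, a voltage-operated calcium
influx, linear extrusion, BK/KIR/leak currents in the voltage equations
and linearized heterocellular coupling.  Net calcium fluxes are multiplied
by the free fraction (~1%).
"""

from __future__ import annotations

import math

import numpy as np

from .coupling import SmcEcState, hetero_coupling, kir_flux, sr_uptake
from .crossbridge import (CrossBridgeState, attached_fraction,
                          calibrate_fr_norm, crossbridge_rhs, steady_state)
from .no_pathway import (NOPathwayState, bk_open_probability, cgmp_rhs,
                         no_production_ec, no_production_neuron,
                         no_transport_rhs, nnos_activation_rhs,
                         total_nmda_ca_current)
from .params import load_nvc_params
from .wall import WallState, wall_radius_rhs


def constant_drive(t_end: float, dt: float, c_a: float = 0.1,
                   g: float = 0.0, v_psp: float = -70.0,
                   k_p: float = 3.5) -> dict:
    n = int(round(t_end / dt)) + 1
    t = np.arange(n) * dt
    ones = np.ones(n)
    return {"t": t, "c_a": c_a * ones, "g": g * ones,
            "v_psp": v_psp * ones, "k_p": k_p * ones}


def drive_from_synapse(rec: dict, k_p: float = 3.5) -> dict:
    t = rec["t_s"]
    return {"t": t, "c_a": rec["c_a_uM"], "g": rec["g_uM"],
            "v_psp": rec["PSP_mV"], "k_p": np.full(t.size, k_p)}


class NVCSimulator:
    def __init__(self, params=None, overrides=None):
        self.p = params or load_nvc_params(overrides=overrides)
        p = self.p
        self.cells = SmcEcState(k_p=p.K_p_rest)
        self.cb = CrossBridgeState(fr_norm=calibrate_fr_norm(p))
        ss = steady_state(self.cells.ca_i, 0.0, p)
        self.cb.m, self.cb.mp, self.cb.amp, self.cb.am = \
            ss.m, ss.mp, ss.amp, ss.am
        self.wall = WallState(dp=p.dp_wall, eta=p.eta_wall, e_act=p.E_act,
                              e_pas=p.E_pas, r0_act=p.R0_act,
                              r0_pas=p.R0_pas)
        self.wall.radius = self.wall.r0_pas
        self.no = NOPathwayState()

    def run(self, drive: dict, dt: float = 2.0e-4, tau_wss: float | None = None,
            record_every: float = 1.0e-2, warm_start: bool = False) -> dict:
        if warm_start:
            # settle onto the driven operating point, then record a clean
            # pass over the same drive (the absolute initial radius is
            # uncertain; the settling pass is discarded)
            self.run(drive, dt=dt, tau_wss=tau_wss, record_every=1.0)
        return self._run(drive, dt, tau_wss, record_every)

    def _run(self, drive: dict, dt: float = 2.0e-4,
             tau_wss: float | None = None,
             record_every: float = 1.0e-2) -> dict:
        p = self.p
        t_d = drive["t"]
        t_end = float(t_d[-1])
        n_steps = int(t_end / dt)
        stride = max(1, int(round(record_every / dt)))
        tau_w = p.tau_wss_default if tau_wss is None else tau_wss
        f_free = p.free_ca_fraction

        cells, cb, wall, no = self.cells, self.cb, self.wall, self.no
        keys = ("t_s", "Ca_SMC_uM", "Ca_EC_uM", "IP3_SMC_uM", "IP3_EC_uM",
                "v_SMC_mV", "Fr", "R_um", "NO_n_uM", "NO_s_uM", "cGMP_uM",
                "s_SR_uM")
        rec = {k: [] for k in keys}
        dlen = t_d.size
        inv_dt_d = (dlen - 1) / t_end if t_end > 0 else 0.0

        for step in range(n_steps):
            t = step * dt
            di = min(int(t * inv_dt_d), dlen - 1)
            c_a_drv = float(drive["c_a"][di])
            g_drv = float(drive["g"][di])
            v_psp = float(drive["v_psp"][di])
            cells.k_p = float(drive["k_p"][di])

            cpl = hetero_coupling(cells, p)
            # SMC calcium: SR release gated by IP3, VOCC, extrusion
            j_rel = p.k_ip3_rel * cells.s_i * cells.ip3_i ** 2 \
                / (p.K_ip3_i ** 2 + cells.ip3_i ** 2)
            j_vocc = p.g_VOCC / (1.0 + math.exp(
                -(cells.v_i - p.v_VOCC_half) / p.v_VOCC_slope))
            dca_i = f_free * (j_rel + j_vocc + p.J0_i
                              - p.k_ext_i * cells.ca_i + cpl["J_Ca_cpl"])
            ds_i = sr_uptake(c_a_drv, p) - p.k_sr_leak * cells.s_i
            dip3_i = cpl["J_IP3_cpl"] - p.k_deg_ip3_i * cells.ip3_i
            # EC
            j_ip3_j = p.k_ip3_rel * 0.02 * cells.ip3_j ** 2 \
                / (p.K_ip3_i ** 2 + cells.ip3_j ** 2)
            dca_j = f_free * (j_ip3_j + p.J0_j - p.k_ext_j * cells.ca_j
                              - cpl["J_Ca_cpl"])
            dip3_j = p.J_EC_IP3 - p.k_deg_ip3_j * cells.ip3_j \
                - cpl["J_IP3_cpl"]
            # voltages
            w_bk = bk_open_probability(cells.v_i, no.cgmp, p)
            dv_i = -kir_flux(cells.v_i, cells.k_p, p) \
                - p.g_L_v_i * (cells.v_i - p.v_L_i) \
                - p.g_BK * w_bk * (cells.v_i - p.v_K_rev) + cpl["J_V_cpl"]
            dv_j = -p.g_L_v_j * (cells.v_j - p.v_L_j) - cpl["J_V_cpl"]

            # NO pathway
            i_ca_tot = total_nmda_ca_current(g_drv, v_psp, p)
            dnnos = nnos_activation_rhs(no.nnos_act, i_ca_tot, p)
            p_no_n = no_production_neuron(no.nnos_act, p)
            p_no_e = no_production_ec(cells.ca_j, tau_w, p)
            dno = no_transport_rhs(no, p_no_n, p_no_e, p)
            dcgmp = cgmp_rhs(no.cgmp, no.no[2], p)

            # cross-bridges and wall
            dcb = crossbridge_rhs(cb, cells.ca_i, no.cgmp, p)
            f_r = attached_fraction(cb)
            drdt = wall_radius_rhs(wall, f_r)

            # Euler update
            cells.ca_i = max(cells.ca_i + dt * dca_i, 1e-6)
            cells.ca_j = max(cells.ca_j + dt * dca_j, 1e-6)
            cells.s_i = max(cells.s_i + dt * ds_i, 0.0)
            cells.ip3_i = max(cells.ip3_i + dt * dip3_i, 0.0)
            cells.ip3_j = max(cells.ip3_j + dt * dip3_j, 0.0)
            cells.v_i += dt * dv_i
            cells.v_j += dt * dv_j
            no.nnos_act = max(no.nnos_act + dt * dnnos, 0.0)
            no.no = np.maximum(no.no + dt * dno, 0.0)
            no.cgmp = max(no.cgmp + dt * dcgmp, 0.0)
            cb.m += dt * dcb[0]
            cb.mp += dt * dcb[1]
            cb.amp += dt * dcb[2]
            cb.am += dt * dcb[3]
            wall.radius += dt * drdt

            if step % stride == 0:
                row = (t, cells.ca_i, cells.ca_j, cells.ip3_i, cells.ip3_j,
                       cells.v_i, f_r, wall.radius, no.no[0], no.no[2],
                       no.cgmp, cells.s_i)
                for k, v in zip(keys, row):
                    rec[k].append(v)
        return {k: np.asarray(v) for k, v in rec.items()}


def wall_radius_trace(t_end: float, dt: float, fr_of_t, wall_params: dict,
                      r_init: float | None = None):
    """Integrate only the Kelvin-Voigt radius ODE (vectorized over
    parameter sets).

    ``wall_params`` values may be scalars or equal-length arrays
    (dp, eta, e_act, e_pas, r0_act, r0_pas); ``fr_of_t`` is a callable
    t -> F_r (scalar).  Returns (t, R) with R shaped (n_times,) or
    (n_times, n_param_sets).
    """
    dp = np.asarray(wall_params["dp"], dtype=float)
    eta = np.asarray(wall_params["eta"], dtype=float)
    e_act = np.asarray(wall_params["e_act"], dtype=float)
    e_pas = np.asarray(wall_params["e_pas"], dtype=float)
    r0_act = np.asarray(wall_params["r0_act"], dtype=float)
    r0_pas = np.asarray(wall_params["r0_pas"], dtype=float)
    shape = np.broadcast_shapes(dp.shape, eta.shape, e_act.shape,
                                e_pas.shape, r0_act.shape, r0_pas.shape)
    n = int(round(t_end / dt))
    t = np.arange(n + 1) * dt
    r = np.broadcast_to(r0_pas if r_init is None else r_init,
                        shape).astype(float).copy()
    out = np.empty((n + 1,) + shape)
    out[0] = r
    for k in range(n):
        f_r = fr_of_t(t[k])
        e = e_pas + f_r * (e_act - e_pas)
        r0 = r0_pas + f_r * (r0_act - r0_pas)
        r = r + dt * (r0_pas / eta) * (10.0 * dp - e * (r - r0) / r0)
        out[k + 1] = r
    return t, out
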