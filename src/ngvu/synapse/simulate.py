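"""Coupled quadripartite synapse simulation.

Two presynaptic neurons (glutamatergic and GABAergic) with HH spiking and
bouton calcium, stochastic vesicle sensors and Tsodyks-Markram pools, a
shared perisynaptic astrocyte (stochastic G-ChI + three-gate gliorelease)
driven by cleft glutamate, and a passive postsynaptic membrane read-out.

Integration: RK4 at dt (default 0.025 ms) for the fast HH/channel block;
the slow block (sensors via exact SSA, pools, cleft concentrations,
astrocyte with Euler-Maruyama noise, PSP) advances every ``slow_every``
fast steps.  A single seeded generator is split into named substreams so
every stochastic component is reproducible in isolation.
"""

from __future__ import annotations

import math

import numpy as np

from . import bouton, pools as pools_mod
from .astrocyte import AstrocyteState, gchi_step, glio_release_step
from .bouton import BoutonCalciumState
from .hh import HHNeuronState, hh_step
from .params import load_params
from .pools import TransmitterPools, spontaneous_rate, tm_pool_step, \
    glio_pool_step, cleft_transmitter_rhs
from .sensor import VesicleSensorState, sensor_step

SUBSTREAMS = ("sensor_glu", "sensor_gaba", "spont_glu", "spont_gaba", "astro")


def make_rngs(seed: int) -> dict:
    seqs = np.random.SeedSequence(seed).spawn(len(SUBSTREAMS))
    return {name: np.random.default_rng(s)
            for name, s in zip(SUBSTREAMS, seqs)}


def _hh_rhs_scalar(v, n, m, h, i_app, c):
    """Scalar HH right-hand side (time in ms); mirrors hh.hh_rhs."""
    gk, gna, gl, vk, vna, vl, cm = c
    x = -v - 60.0
    an = 0.1 * (1.0 - x / 20.0) if abs(x) < 1e-6 else \
        0.01 * x / math.expm1(x / 10.0)
    bn = 0.125 * math.exp((-v - 70.0) / 80.0)
    x = -v - 45.0
    am = 1.0 * (1.0 - x / 20.0) if abs(x) < 1e-6 else \
        0.1 * x / math.expm1(x / 10.0)
    bm = 4.0 * math.exp((-v - 70.0) / 18.0)
    ah = 0.07 * math.exp((-v - 70.0) / 20.0)
    bh = 1.0 / (math.exp((-v - 40.0) / 10.0) + 1.0)
    dv = (i_app - gk * n ** 4 * (v - vk) - gna * m ** 3 * h * (v - vna)
          - gl * (v - vl)) / cm
    return (dv, an * (1.0 - n) - bn * n, am * (1.0 - m) - bm * m,
            ah * (1.0 - h) - bh * h)


def _hh_rk4_scalar(v, n, m, h, i_app, c, dt):
    k1 = _hh_rhs_scalar(v, n, m, h, i_app, c)
    k2 = _hh_rhs_scalar(v + 0.5 * dt * k1[0], n + 0.5 * dt * k1[1],
                        m + 0.5 * dt * k1[2], h + 0.5 * dt * k1[3], i_app, c)
    k3 = _hh_rhs_scalar(v + 0.5 * dt * k2[0], n + 0.5 * dt * k2[1],
                        m + 0.5 * dt * k2[2], h + 0.5 * dt * k2[3], i_app, c)
    k4 = _hh_rhs_scalar(v + dt * k3[0], n + dt * k3[1], m + dt * k3[2],
                        h + dt * k3[3], i_app, c)
    return (v + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]),
            n + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]),
            m + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]),
            h + dt / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3]))


class QuadripartiteSynapse:
    """Stateful coupled model; ``run`` integrates and records time series."""

    def __init__(self, seed: int = 0, params=None, overrides=None,
                 i_app_glu: float | None = None,
                 i_app_gaba: float | None = None):
        self.p = params or load_params(overrides=overrides)
        bouton.calibrate_rest(self.p)
        self.seed = seed
        self.rngs = make_rngs(seed)
        p = self.p
        self.i_app = {"glu": i_app_glu if i_app_glu is not None else p.hh_Iapp,
                      "gaba": i_app_gaba if i_app_gaba is not None
                      else 0.8 * p.hh_Iapp}
        self.neuron = {"glu": HHNeuronState(), "gaba": HHNeuronState()}
        self.cal = {"glu": bouton.resting_state(p),
                    "gaba": bouton.resting_state(p)}
        self.sensors = {
            "glu": VesicleSensorState(np.zeros(int(p.n_docked), dtype=int)),
            "gaba": VesicleSensorState(np.zeros(int(p.n_docked), dtype=int))}
        self.pools = {"glu": TransmitterPools("glu"),
                      "gaba": TransmitterPools("gaba")}
        self.astro = AstrocyteState()
        self.astro_pools = TransmitterPools("glu")  # gliovesicles (Glu)
        self.v_psp = p.psp_Vrest
        self._cache_constants()

    def _cache_constants(self):
        p = self.p
        self._hh_c = (p.hh_gK, p.hh_gNa, p.hh_gL, p.hh_VK, p.hh_VNa,
                      p.hh_VL, p.hh_C)
        self._v_ca = bouton.nernst_potential(p.c_ext, p.c_i_rest,
                                             p.temperature, p.z_Ca)
        self._gca_tot = p.rho_Ca * p.A_btn * p.g_Ca     # fA/mV
        from ..units import FARADAY
        self._fa_to_um = 1e6 / (p.z_Ca * FARADAY * p.V_btn)  # fA -> uM/s
        self._pmca_max = p.v_PM_Ca * p.A_btn            # fA
        self._kappa = p.buffer_kappa

    # ------------------------------------------------------------------
    def _advance_fast(self, dt_ms: float):
        p = self.p
        dt_s = dt_ms * 1e-3
        for key in ("glu", "gaba"):
            nst = self.neuron[key]
            v, n, m, h = _hh_rk4_scalar(nst.v, nst.n, nst.m, nst.h,
                                        self.i_app[key], self._hh_c, dt_ms)
            nst.v, nst.n, nst.m, nst.h = v, n, m, h
            cal = self.cal[key]
            # N-type gate: exact exponential relaxation
            m_inf = 1.0 / (1.0 + math.exp((p.V_mCa - v) / p.k_mCa))
            decay = math.exp(-dt_ms / p.tau_mCa)
            cal.m_ca = m_inf + (cal.m_ca - m_inf) * decay
            c_i = cal.c_fast + cal.c_slow
            i_ca = self._gca_tot * cal.m_ca ** 2 * (v - self._v_ca)
            j_in = -i_ca * self._fa_to_um
            j_leak = p.v_leak * (p.c_ext - c_i)
            j_pmca = self._pmca_max * c_i * c_i \
                / (c_i * c_i + p.K_PM_Ca ** 2) * self._fa_to_um
            dc_fast = (j_in + j_leak - j_pmca) / self._kappa
            cal.c_fast = max(cal.c_fast + dt_s * dc_fast,
                             -cal.c_slow + 1e-9)

    def _advance_slow(self, dt_s: float):
        p = self.p
        for key in ("glu", "gaba"):
            cal = self.cal[key]
            dc_slow, dc_er, dp_, dq = bouton.slow_calcium_rhs(
                cal, self.astro_pools.extra, p)
            cal.c_slow = max(cal.c_slow + dt_s * dc_slow, 1e-6)
            cal.c_er = max(cal.c_er + dt_s * dc_er, 1e-3)
            cal.p = max(cal.p + dt_s * dp_, 0.0)
            cal.q = min(max(cal.q + dt_s * dq, 0.0), 1.0)

            # stochastic sensor + spontaneous release
            c_i = cal.c_i
            self.sensors[key], f_r = sensor_step(
                self.sensors[key], c_i, dt_s * 1e3,
                self.rngs[f"sensor_{key}"], p)
            lam = spontaneous_rate(c_i, p.spont_a1, p.spont_a2, p.spont_a3)
            n_spont = self.rngs[f"spont_{key}"].poisson(lam * dt_s)
            if n_spont:
                f_r = min(1.0, f_r + 0.5 * n_spont)
            self.pools[key] = tm_pool_step(self.pools[key], f_r, dt_s, p)
            dg, _ = cleft_transmitter_rhs(self.pools[key], p)
            self.pools[key].cleft = max(
                self.pools[key].cleft + dt_s * dg, 0.0)

        # astrocyte driven by cleft glutamate
        g = self.pools["glu"].cleft
        self.astro = gchi_step(self.astro, g, dt_s, self.rngs["astro"], p)
        self.astro, f_r_a = glio_release_step(self.astro, dt_s, p)
        self.astro_pools = glio_pool_step(self.astro_pools, f_r_a,
                                          self.astro.c_a, dt_s, p)
        _, dga = cleft_transmitter_rhs(self.astro_pools, p)
        self.astro_pools.extra = max(self.astro_pools.extra + dt_s * dga, 0.0)
        # extrasynaptic Glu feeds back to both boutons' IP3 production
        for key in ("glu", "gaba"):
            self.pools[key].extra = self.astro_pools.extra

        # passive postsynaptic membrane
        g_glu = self.pools["glu"].cleft
        g_gaba = self.pools["gaba"].cleft
        w_a = g_glu / (p.K_m_A + g_glu)
        w_b = g_glu / (p.K_m_B + g_glu)
        g_e = p.psp_gAMPA * g_glu / (p.psp_K_AMPA + g_glu) \
            + p.psp_gNMDA * (0.63 * w_a + 11.0 * w_b) / 11.63
        g_i = p.psp_gGABA * g_gaba / (p.psp_K_GABA + g_gaba)
        v = self.v_psp
        i_syn = g_e * (v - p.psp_V_E) + g_i * (v - p.psp_V_I)
        dv = (-p.psp_gL * (v - p.psp_Vrest) - i_syn) / p.psp_C  # mV/ms
        self.v_psp = v + dt_s * 1e3 * dv
        self._epsc = g_e * (v - p.psp_V_E)
        self._ipsc = g_i * (v - p.psp_V_I)

    # ------------------------------------------------------------------
    def run(self, t_end: float, dt_ms: float = 0.025, slow_every: int = 4,
            record_every_ms: float = 1.0) -> dict:
        """Integrate to t_end [s]; returns a dict of recorded arrays."""
        n_steps = int(round(t_end / (dt_ms * 1e-3)))
        rec_stride = max(1, int(round(record_every_ms / dt_ms)))
        dt_slow = slow_every * dt_ms * 1e-3
        self._epsc = self._ipsc = 0.0
        keys = ("t_s", "V_pre_mV", "V_pre_gaba_mV", "c_i_uM", "c_ER_uM",
                "c_ER_gaba_uM", "p_uM", "g_uM", "g_gaba_uM", "g_a_uM",
                "c_a_uM", "p_a_uM", "h_a", "R_glu", "E_glu", "I_glu",
                "R_a", "E_a", "PSP_mV", "EPSC", "IPSC", "Fra")
        rec = {k: [] for k in keys}
        f_r_a = 0.0
        for step in range(n_steps):
            self._advance_fast(dt_ms)
            if (step + 1) % slow_every == 0:
                self._advance_slow(dt_slow)
            if step % rec_stride == 0:
                g = self.pools["glu"]
                gb = self.pools["gaba"]
                row = (step * dt_ms * 1e-3, self.neuron["glu"].v,
                       self.neuron["gaba"].v, self.cal["glu"].c_i,
                       self.cal["glu"].c_er, self.cal["gaba"].c_er,
                       self.cal["glu"].p, g.cleft, gb.cleft,
                       self.astro_pools.extra, self.astro.c_a,
                       self.astro.p_a, self.astro.h_a, g.r, g.e, g.i,
                       self.astro_pools.r_a, self.astro_pools.e_a,
                       self.v_psp, self._epsc, self._ipsc,
                       float(np.prod(self.astro.gates)))
                for k, v in zip(keys, row):
                    rec[k].append(v)
        return {k: np.asarray(v) for k, v in rec.items()}


def run_default(seed: int = 0, t_end: float = 10.0, **kwargs) -> dict:
    return QuadripartiteSynapse(seed=seed).run(t_end, **kwargs)
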