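"""Bouton calcium dynamics: fast N-type influx and slow ER exchange.

Concentrations in uM, time in seconds.  The fast pathway converts the
N-type single-channel current (fA per channel) into a concentration flux
through A_btn/(z F V_btn); the slow pathway is an adapted two-pool
Li-Rinzel system with a *dynamic* ER concentration (dc_ER = -dc_slow/c1)
and a glutamate-driven IP3 production term.  v1/v2 (channel and leak
rates) and the PMCA maximum are calibrated so the resting state is a fixed
point of the combined system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..units import FARADAY, R_GAS


@dataclass
class BoutonCalciumState:
    c_fast: float = 0.0
    c_slow: float = 0.1
    c_er: float = 150.0
    p: float = 0.16         # IP3 [uM]
    q: float = 0.734        # IP3R activation gate
    m_ca: float = 0.0       # N-type gate open probability

    @property
    def c_i(self) -> float:
        # Identity c_i = c_fast + c_slow holds by construction.
        return self.c_fast + self.c_slow


def nernst_potential(c_out: float, c_in: float, temperature: float,
                     z: float) -> float:
    """Nernst reversal potential in mV."""
    if c_out <= 0 or c_in <= 0:
        raise ValueError("concentrations must be positive")
    return 1e3 * R_GAS * temperature / (z * FARADAY) * np.log(c_out / c_in)


def m_ca_inf(v: float, p) -> float:
    """Boltzmann steady state of a single N-type gate."""
    return 1.0 / (1.0 + np.exp((p.V_mCa - v) / p.k_mCa))


def ntype_current(m_ca: float, v: float, p) -> float:
    """Total bouton N-type current [fA]: rho A_btn m^2 g (V - V_Ca)."""
    v_ca = nernst_potential(p.c_ext, p.c_i_rest, p.temperature, p.z_Ca)
    n_channels = p.rho_Ca * p.A_btn
    return n_channels * m_ca ** 2 * p.g_Ca * (v - v_ca)  # pS*mV = fA


def ntype_gate_rhs(m_ca: float, v: float, p) -> float:
    """dm_Ca/dt [1/s] relaxing to the Boltzmann steady state."""
    return (m_ca_inf(v, p) - m_ca) / (p.tau_mCa * 1e-3)


# Conversion of a bouton current [fA] to d[Ca]/dt [uM/s]:
# 1 fA / (z F V_btn[um^3]) = 1e-15 A / (z * 96485 C/mol * V*1e-15 L)
def _current_to_flux(i_fa: float, p) -> float:
    return i_fa / (p.z_Ca * FARADAY * p.V_btn) * 1e6  # uM/s


def pmca_current(c_i: float, p) -> float:
    """PMCA extrusion current density * area [fA]."""
    return p.v_PM_Ca * p.A_btn * c_i ** 2 / (c_i ** 2 + p.K_PM_Ca ** 2)


def fast_calcium_rhs(state: BoutonCalciumState, i_ca: float, p) -> float:
    """dc_fast/dt [uM/s]: channel influx + leak - PMCA extrusion."""
    c_i = state.c_i
    j_in = -_current_to_flux(i_ca, p)
    j_leak = p.v_leak * (p.c_ext - c_i)
    j_pmca = _current_to_flux(pmca_current(c_i, p), p)
    return j_in + j_leak - j_pmca


def _gate_rates(c_i, pp, p):
    alpha_q = p.a2 * p.d2 * (pp + p.d1) / (pp + p.d3)
    beta_q = p.a2 * c_i
    return alpha_q, beta_q


def slow_calcium_rhs(state: BoutonCalciumState, g_a: float, p):
    """(dc_slow, dc_ER, dp, dq)/dt for the adapted Li-Rinzel system."""
    c_i, c_er, pp, q = state.c_i, state.c_er, state.p, state.q
    m_inf = pp / (pp + p.d1)
    n_inf = c_i / (c_i + p.d5)
    j_chan = p.c1_ratio * p.v1 * (m_inf * n_inf * q) ** 3 * (c_i - c_er)
    j_pump = p.v3 * c_i ** 2 / (p.k3 ** 2 + c_i ** 2)
    j_leak = p.c1_ratio * p.v2 * (c_i - c_er)
    dc_slow = -j_chan - j_pump - j_leak
    dc_er = -dc_slow / p.c1_ratio
    ga = max(g_a, 0.0)
    dp = p.v_g * ga ** 0.3 / (p.k_g ** 0.3 + ga ** 0.3) - p.tau_p * (pp - p.p0)
    alpha_q, beta_q = _gate_rates(c_i, pp, p)
    dq = alpha_q * (1.0 - q) - beta_q * q
    return dc_slow, dc_er, dp, dq


def fluxes(state: BoutonCalciumState, p):
    """Diagnostic Li-Rinzel fluxes (j_chan, j_pump, j_leak) [uM/s]."""
    c_i, c_er, pp, q = state.c_i, state.c_er, state.p, state.q
    m_inf = pp / (pp + p.d1)
    n_inf = c_i / (c_i + p.d5)
    j_chan = p.c1_ratio * p.v1 * (m_inf * n_inf * q) ** 3 * (c_i - c_er)
    j_pump = p.v3 * c_i ** 2 / (p.k3 ** 2 + c_i ** 2)
    j_leak = p.c1_ratio * p.v2 * (c_i - c_er)
    return j_chan, j_pump, j_leak


def calibrate_rest(p, channel_fraction: float = 0.1):
    """Make the resting state a fixed point (updates the registry in place).

    v_PM_Ca balances the membrane leak at rest (with I_Ca = 0); v1 and v2
    split the ER pump return flux between channel and leak influx in the
    ratio ``channel_fraction`` : 1 - channel_fraction.
    """
    c_r = p.c_i_rest
    # membrane: v_leak (c_ext - c_r) = PMCA(c_r)
    j_leak = p.v_leak * (p.c_ext - c_r)
    hill = c_r ** 2 / (c_r ** 2 + p.K_PM_Ca ** 2)
    # flux [uM/s] -> current density [fA/um^2]
    v_pm = j_leak / hill / (p.A_btn / (p.z_Ca * FARADAY * p.V_btn) * 1e6)
    p.set("v_PM_Ca", float(v_pm), source="calibrated")

    # ER: J_chan + J_leak = -J_pump at rest (influx balances pump)
    j_pump = p.v3 * c_r ** 2 / (p.k3 ** 2 + c_r ** 2)
    grad = c_r - p.c_ER_rest            # negative
    m_inf = p.p0 / (p.p0 + p.d1)
    n_inf = c_r / (c_r + p.d5)
    alpha_q, beta_q = _gate_rates(c_r, p.p0, p)
    q_rest = alpha_q / (alpha_q + beta_q)
    open_prob = (m_inf * n_inf * q_rest) ** 3
    v1 = channel_fraction * j_pump / (p.c1_ratio * open_prob * (-grad))
    v2 = (1.0 - channel_fraction) * j_pump / (p.c1_ratio * (-grad))
    p.set("v1", float(v1), source="calibrated")
    p.set("v2", float(v2), source="calibrated")
    return {"v_PM_Ca": v_pm, "v1": v1, "v2": v2, "q_rest": float(q_rest)}


def resting_state(p) -> BoutonCalciumState:
    c_r = p.c_i_rest
    alpha_q, beta_q = _gate_rates(c_r, p.p0, p)
    return BoutonCalciumState(
        c_fast=0.0, c_slow=c_r, c_er=p.c_ER_rest, p=p.p0,
        q=float(alpha_q / (alpha_q + beta_q)), m_ca=0.0)
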