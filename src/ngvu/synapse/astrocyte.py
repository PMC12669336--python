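"""Astrocyte calcium (stochastic G-ChI) and gliotransmitter release gates.

Closed-cell Li-Rinzel calcium with ER concentration tied to cytosolic
calcium, c_ER,a = (c0 - c_a)/c1_a; IP3 metabolism with agonist-dependent
(cleft glutamate, Hill exponent 0.9) and agonist-independent production and
two degradation routes; the IP3R inactivation gate h_a carries multiplicative
channel noise with variance (alpha (1-h) + beta h)/N_IP3 per unit time
(Euler-Maruyama).  Gliotransmitter release requires three independent
calcium gates to be open; f_r^a = O1 O2 O3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def hill(x_pow_n, k_pow_n):
    """Generic Hill term x^n / (x^n + K^n) given the pre-raised arguments."""
    return x_pow_n / (x_pow_n + k_pow_n)


@dataclass
class AstrocyteState:
    c_a: float = 0.1
    p_a: float = 0.16
    h_a: float = 0.8
    gates: np.ndarray = field(default_factory=lambda: np.zeros(3))
    clipped_events: int = 0

    def c_er(self, p) -> float:
        return (p.c0_astro - self.c_a) / p.c1_astro


def _h_rates(c_a, p_a, p):
    alpha = p.a2 * p.d2 * (p_a + p.d1) / (p_a + p.d3)
    beta = p.a2 * c_a
    return alpha, beta


def gchi_rhs(state: AstrocyteState, g: float, p):
    """Deterministic part of (dc_a, dp_a, dh_a)/dt [uM/s, uM/s, 1/s]."""
    c_a, p_a, h_a = state.c_a, state.p_a, state.h_a
    m_inf = hill(p_a, p.d1)
    n_inf = hill(c_a, p.d5)
    store = p.c0_astro - (1.0 + p.c1_astro) * c_a
    dc = (p.r_Ca * (m_inf * n_inf * h_a) ** 3) * store \
        - p.v_ER * c_a ** 2 / (c_a ** 2 + p.K_ER ** 2) \
        + p.r_L * store
    gg = max(g, 0.0)
    k_eff = p.K_R * (1.0 + p.K_p / p.K_R * hill(c_a, p.K_pi))
    dp = p.v_beta * hill(gg ** 0.9, k_eff ** 0.9) \
        + p.v_delta / (1.0 + p_a / p.k_delta) * hill(c_a ** 2, p.K_PLCdelta ** 2) \
        - p.v_3K * hill(c_a ** 4, p.K_D ** 4) * hill(p_a, p.K_3) \
        - p.r_5Pa * p_a
    alpha, beta = _h_rates(c_a, p_a, p)
    dh = alpha * (1.0 - h_a) - beta * h_a
    return dc, dp, dh


def gchi_step(state: AstrocyteState, g: float, dt: float,
              rng: np.random.Generator, p) -> AstrocyteState:
    """Euler-Maruyama step of the stochastic G-ChI system (dt in s)."""
    dc, dp, dh = gchi_rhs(state, g, p)
    alpha, beta = _h_rates(state.c_a, state.p_a, p)
    var = max(alpha * (1.0 - state.h_a) + beta * state.h_a, 0.0) / p.N_IP3
    noise = rng.normal(0.0, np.sqrt(var * dt)) if p.N_IP3 < np.inf else 0.0
    new = AstrocyteState(
        c_a=max(state.c_a + dt * dc, 1e-6),
        p_a=max(state.p_a + dt * dp, 0.0),
        h_a=state.h_a + dt * dh + noise,
        gates=state.gates.copy(),
        clipped_events=state.clipped_events)
    if not 0.0 <= new.h_a <= 1.0:
        new.h_a = min(max(new.h_a, 0.0), 1.0)
        new.clipped_events += 1
    return new


def gate_constants(p):
    """(k_plus, k_minus) per gate from dissociation constants and closure
    time constants: k- = 1/tau, k+ = k-/Kd."""
    kd = np.array([p.gate_Kd1, p.gate_Kd2, p.gate_Kd3])
    k_minus = 1.0 / np.array([p.gate_tau1, p.gate_tau2, p.gate_tau3])
    return k_minus / kd, k_minus


def glio_release_step(state: AstrocyteState, dt: float, p):
    """Advance the three release gates; returns (new_state, f_r_a).

    dO_j/dt = k_j+ c_a - (k_j+ c_a + k_j-) O_j.
    """
    k_plus, k_minus = gate_constants(p)
    o = state.gates
    do = k_plus * state.c_a - (k_plus * state.c_a + k_minus) * o
    new = AstrocyteState(c_a=state.c_a, p_a=state.p_a, h_a=state.h_a,
                         gates=np.clip(o + dt * do, 0.0, 1.0),
                         clipped_events=state.clipped_events)
    f_r_a = float(np.prod(new.gates))
    return new, f_r_a
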