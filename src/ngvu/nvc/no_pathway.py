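"""Nitric-oxide pathway: production (nNOS/eNOS), compartment diffusion,
scavenging, cGMP formation and BK-channel modulation.

Compartments: neuron (n) <-> astrocyte (a) <-> SMC (s) <-> EC (e), with
diffusion times tau = dx^2 / (2 D_NO) between neighbouring compartments.
Production is restricted to neurons and ECs; astrocyte and SMC production
rates are zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..units import FARADAY, R_GAS


@dataclass
class NOPathwayState:
    no: np.ndarray = field(default_factory=lambda: np.zeros(4))  # [n,a,s,e] uM
    nnos_act: float = 0.0     # activated nNOS [uM]
    cgmp: float = 0.0         # SMC cGMP [uM]


def nmda_open_prob(glu_sc: float, p):
    """(w_NR2A, w_NR2B): Michaelis saturation in cleft glutamate."""
    if glu_sc < 0:
        raise ValueError("glutamate concentration must be >= 0")
    return glu_sc / (p.K_m_A + glu_sc), glu_sc / (p.K_m_B + glu_sc)


def nmda_ca_current(v_n: float, p, temperature: float = 310.0) -> float:
    """Single-channel NMDA calcium current [pA] at potential v_n [mV]."""
    rt = R_GAS * temperature
    x = 2.0 * v_n * 1e-3 * FARADAY / rt
    if abs(x) < 1e-9:
        frac = -1.0  # limit of exp(x)/(1-exp(x)) * x -> handled by caller
    else:
        frac = math.exp(x) / (1.0 - math.exp(x))
    gate = 1.0 / (1.0 + math.exp(p.alpha_v * (v_n + p.beta_v)))
    # pS * mV = fA; report pA
    return 4.0 * v_n * p.G_M * p.P_Ca_P_M * (p.Ca_ex / p.M_mono) \
        * gate * frac * 1e-3


def total_nmda_ca_current(glu_sc: float, v_n: float, p) -> float:
    """I_Ca,tot = I_Ca (0.63 w_NR2A + 11 w_NR2B) [pA]."""
    w_a, w_b = nmda_open_prob(glu_sc, p)
    return nmda_ca_current(v_n, p) * (0.63 * w_a + 11.0 * w_b)


def nnos_activation_rhs(nnos_act: float, i_ca_tot: float, p) -> float:
    """First-order activation driven by the magnitude of I_Ca,tot."""
    drive = abs(i_ca_tot)
    target = p.nNOS_max * drive / (drive + p.K_act_nNOS)
    return (target - nnos_act) / p.tau_nNOS


def no_production_neuron(nnos_act: float, p) -> float:
    """p_NO,n = V_max [nNOS_act] MM(O2) MM(L-Arg) [uM/s]."""
    return p.V_max_NO_n * nnos_act \
        * p.O2_n / (p.K_m_O2_n + p.O2_n) \
        * p.LArg_n / (p.K_m_LArg_n + p.LArg_n)


def enos_activation(ca_j: float, tau_wss: float, p) -> float:
    """Calcium- plus shear-stress-driven eNOS activation [uM].

    The shear branch is a pluggable saturating law (the cited strain-energy
    model is not printed); monotone non-decreasing in tau_wss.
    """
    ca_part = p.eNOS_ca_max * ca_j ** 2 / (p.K_eNOS_Ca ** 2 + ca_j ** 2)
    wss_part = p.eNOS_wss_max * tau_wss / (p.K_wss + max(tau_wss, 0.0))
    return ca_part + wss_part


def no_production_ec(ca_j: float, tau_wss: float, p) -> float:
    return p.V_max_NO_j * enos_activation(ca_j, tau_wss, p) \
        * p.O2_j / (p.K_m_O2_j + p.O2_j) \
        * p.LArg_j / (p.K_m_LArg_j + p.LArg_j)


def diffusion_taus(p) -> np.ndarray:
    """Pairwise diffusion times [s] for (n-a, a-s, s-e)."""
    dx = np.array([p.dx_na, p.dx_as, p.dx_se])
    return dx * dx / (2.0 * p.D_NO)


def no_transport_rhs(state: NOPathwayState, p_no_n: float, p_no_e: float,
                     p) -> np.ndarray:
    """d[NO]/dt per compartment [n, a, s, e] (uM/s)."""
    no = state.no
    taus = diffusion_taus(p)
    prod = np.array([p_no_n, 0.0, 0.0, p_no_e])
    scav = np.array([p.kC_n, p.kC_a, p.kC_s, p.kC_e]) * no
    d = np.zeros(4)
    for k, tau in enumerate(taus):
        flux = (no[k + 1] - no[k]) / tau
        d[k] += flux
        d[k + 1] -= flux
    return prod + d - scav


def wall_shear_stress(q_flow: float, radius: float, mu: float) -> float:
    """Hagen-Poiseuille WSS tau = 4 mu Q / (pi R^3) (consistent units)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return 4.0 * mu * q_flow / (math.pi * radius ** 3)


def cgmp_rhs(cgmp: float, no_s: float, p) -> float:
    """sGC-driven cGMP production minus first-order degradation [uM/s]."""
    return p.V_cGMP * no_s / (p.K_NO_sGC + no_s) - p.k_deg_cGMP * cgmp


def cgmp_bk_modulation(cgmp: float, p) -> float:
    """BK voltage-shift factor c_w,i = 1/(eps_i + alpha_i exp(gamma_i cGMP)).

    With gamma_i < 0 (default) higher cGMP gives a larger c_w,i, i.e. a
    leftward shift of the BK activation curve (more opening, dilation).
    """
    denom = p.eps_i + p.alpha_i * math.exp(p.gamma_i * cgmp)
    if denom <= 0:
        raise ValueError("eps_i + alpha_i exp(gamma_i cGMP) must be positive")
    return 1.0 / denom


def bk_open_probability(v_i: float, cgmp: float, p) -> float:
    """Sigmoidal BK activation with the cGMP-dependent voltage shift."""
    c_w = cgmp_bk_modulation(cgmp, p)
    c_w0 = 1.0 / (p.eps_i + p.alpha_i)  # reference at cGMP = 0
    shift = p.lambda_BK * (c_w - c_w0)
    x = (v_i - p.v_BK_half + shift) / p.v_BK_slope
    return 0.5 * (1.0 + math.tanh(x))
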