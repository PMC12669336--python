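"""KIR input and SMC/EC heterocellular gap-junction coupling."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class SmcEcState:
    ca_i: float = 0.25      # SMC cytosolic Ca [uM]
    ca_j: float = 0.3       # EC cytosolic Ca [uM]
    ip3_i: float = 0.3      # [uM]
    ip3_j: float = 0.6
    v_i: float = -40.0      # [mV]
    v_j: float = -45.0
    s_i: float = 1.0        # SMC SR store proxy [uM]
    k_p: float = 3.5        # perivascular potassium [mM]


def kir_reversal(k_p: float, p) -> float:
    """Linear-fit KIR reversal potential v_KIR = z1 K_p - z2 [mV]."""
    return p.z1 * k_p - p.z2


def kir_flux(v_i: float, k_p: float, p) -> float:
    """J_KIR = F_KIR g_KIR / gamma_i * (v_i - v_KIR) [mV/s]."""
    return p.F_KIR * p.g_KIR / p.gamma_conv * (v_i - kir_reversal(k_p, p))


def hetero_coupling(state: SmcEcState, p) -> dict:
    """Linearized gap-junction fluxes *into the SMC compartment* (i).

    The matching EC fluxes are the negatives (antisymmetry).
    """
    return {
        "J_Ca_cpl": -p.P_Ca * (state.ca_i - state.ca_j),
        "J_V_cpl": -p.G_v * (state.v_i - state.v_j),
        "J_IP3_cpl": -p.P_IP3 * (state.ip3_i - state.ip3_j),
    }


def sr_uptake(ca: float, p) -> float:
    """Sarcoplasmic-reticulum uptake flux B_i ca^2/(c_bi^2 + ca^2) [uM/s]."""
    return p.B_i * ca * ca / (p.c_bi ** 2 + ca * ca)
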