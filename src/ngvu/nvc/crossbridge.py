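"""Four-state cross-bridge (latch-bridge) kinetics with cGMP modulation.

States: free myosin M, phosphorylated Mp, attached phosphorylated AMp,
attached latch AM; M + Mp + AMp + AM = 1.  Calcium enters through the
phosphorylation rates K1 = K6 = gamma_cross * Ca^3; cGMP accelerates the
dephosphorylation rates K2 = K5 via the MLCP pathway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CrossBridgeState:
    m: float = 1.0
    mp: float = 0.0
    amp: float = 0.0
    am: float = 0.0
    fr_norm: float = 0.8      # (AMp+AM)_max normalization constant

    def fractions(self):
        return np.array([self.m, self.mp, self.amp, self.am])


def cgmp_mlcp_activation(cgmp: float, p) -> float:
    """R_cGMP = cGMP^2 / (K_m,mlcp^2 + cGMP^2)."""
    return cgmp * cgmp / (p.K_m_mlcp ** 2 + cgmp * cgmp)


def dephosphorylation_rate(cgmp: float, p) -> float:
    """K2c = K5c = delta_i (k_mlpc_b + k_mlpc_c R_cGMP)."""
    return p.delta_i * (p.k_mlpc_b + p.k_mlpc_c * cgmp_mlcp_activation(cgmp, p))


def crossbridge_rhs(cb: CrossBridgeState, ca_i: float, cgmp: float, p):
    """(dM, dMp, dAMp, dAM)/dt; the four derivatives sum to zero."""
    k1 = k6 = p.gamma_cross * ca_i ** 3
    k2 = k5 = dephosphorylation_rate(cgmp, p)
    m, mp, amp, am = cb.m, cb.mp, cb.amp, cb.am
    dmp = p.K4 * amp + k1 * m - (k2 + p.K3) * mp
    damp = p.K3 * mp + k6 * am - (p.K4 + k5) * amp
    dam = k5 * amp - (p.K7 + k6) * am
    dm = -(dmp + damp + dam)
    return dm, dmp, damp, dam


def crossbridge_step(cb: CrossBridgeState, ca_i: float, cgmp: float,
                     dt: float, p) -> CrossBridgeState:
    dm, dmp, damp, dam = crossbridge_rhs(cb, ca_i, cgmp, p)
    return CrossBridgeState(cb.m + dt * dm, cb.mp + dt * dmp,
                            cb.amp + dt * damp, cb.am + dt * dam,
                            cb.fr_norm)


def attached_fraction(cb: CrossBridgeState) -> float:
    """F_r = (AMp + AM) / (AMp + AM)_max."""
    if cb.fr_norm <= 0:
        raise ValueError("normalization constant must be positive")
    return (cb.amp + cb.am) / cb.fr_norm


def steady_state(ca_i: float, cgmp: float, p) -> CrossBridgeState:
    """Equilibrium fractions of the linear 4-state system."""
    k1 = k6 = p.gamma_cross * ca_i ** 3
    k2 = k5 = dephosphorylation_rate(cgmp, p)
    # solve the linear system with the conservation constraint
    a = np.array([
        [k1, -(k2 + p.K3), p.K4, 0.0],
        [0.0, p.K3, -(p.K4 + k5), k6],
        [0.0, 0.0, k5, -(p.K7 + k6)],
        [1.0, 1.0, 1.0, 1.0]])
    b = np.array([0.0, 0.0, 0.0, 1.0])
    m, mp, amp, am = np.linalg.solve(a, b)
    return CrossBridgeState(m, mp, amp, am, fr_norm=1.0)


def calibrate_fr_norm(p, ca_ref: float = 1.0, cgmp_ref: float = 0.0) -> float:
    """(AMp+AM)_max as the steady attached sum at a reference high-Ca state."""
    ss = steady_state(ca_ref, cgmp_ref, p)
    return ss.amp + ss.am
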