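"""Vesicle fusion/recycling pools and cleft/extrasynaptic transmitter.

Three-pool kinetics per transmitter: releasable R, effective E, inactive
I = 1 - R - E.  Release is event-driven: when the sensor (or the
spontaneous Poisson process) reports a ready fraction f_r > 0 and the pool
is not refractory, a fraction u_release * f_r of R transfers to E and the
release machinery locks out for the transmitter-specific refractory window
(6.34 ms Glu, 7.2 ms GABA).  Between events the pools relax with
dR/dt = I/tau_rec, dE/dt = -E/tau_inact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TransmitterPools:
    transmitter: str = "glu"
    r: float = 1.0
    e: float = 0.0
    cleft: float = 0.0          # g, uM
    extra: float = 0.0          # g_a, uM
    r_a: float = 1.0
    e_a: float = 0.0
    lockout: float = 0.0        # remaining refractory time [s]

    @property
    def i(self) -> float:
        return 1.0 - self.r - self.e

    @property
    def i_a(self) -> float:
        return 1.0 - self.r_a - self.e_a


def spontaneous_rate(c_i: float, a1: float, a2: float, a3: float) -> float:
    """Poisson rate for spontaneous vesicle release [1/s]."""
    if a2 == 0:
        raise ValueError("a2 must be non-zero")
    return a3 / (1.0 + np.exp((a1 - c_i) / a2))


def refractory_window(transmitter: str, p) -> float:
    return p.refractory_glu if transmitter == "glu" else p.refractory_gaba


def tm_pool_step(pools: TransmitterPools, f_r: float, dt: float, p
                 ) -> TransmitterPools:
    """Advance the synaptic pools by dt [s] with release fraction f_r."""
    out = TransmitterPools(**vars(pools))
    if out.lockout > 0.0:
        out.lockout = max(0.0, out.lockout - dt)
        f_r = 0.0
    if f_r > 0.0:
        released = p.u_release * f_r * out.r
        out.r -= released
        out.e += released
        out.lockout = refractory_window(out.transmitter, p)
    # relaxation between events (exact exponential updates)
    decay = np.exp(-dt / p.tau_inact)
    recovered = (1.0 - out.r - out.e) * (1.0 - np.exp(-dt / p.tau_rec))
    out.e *= decay
    out.r += recovered
    return out


def glio_pool_step(pools: TransmitterPools, f_r_a: float, c_a: float,
                   dt: float, p) -> TransmitterPools:
    """Astrocytic (gliovesicle) pool update, gated by the Ca threshold."""
    out = TransmitterPools(**vars(pools))
    theta = 1.0 if c_a > p.c_a_thresh else 0.0
    rel_rate = theta * f_r_a
    dr = (1.0 - out.r_a - out.e_a) / p.tau_rec_a - rel_rate * out.r_a
    de = -out.e_a / p.tau_inact_a + rel_rate * out.r_a
    out.r_a += dt * dr
    out.e_a += dt * de
    return out


def cleft_transmitter_rhs(pools: TransmitterPools, p):
    """(dg/dt, dg_a/dt) [uM/s] for cleft and extrasynaptic concentration."""
    g_v = p.g_v_glu if pools.transmitter == "glu" else p.g_v_gaba
    dg = p.n_v * g_v * pools.e - p.g_c * pools.cleft
    dga = p.n_a_v * p.g_a_v * pools.e_a - p.g_a_c * pools.extra
    return dg, dga
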