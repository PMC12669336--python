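"""Presynaptic Hodgkin-Huxley spiking (resting potential -70 mV).

Rates are in 1/ms for V in mV; the 0/0 forms of alpha_n and alpha_m at
V = -60 and V = -45 are evaluated by their limits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _vtrap(x, y):
    """x / (exp(x/y) - 1) with the removable singularity at x = 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-6
    out = np.where(small, y * (1.0 - x / (2.0 * y)),
                   x / np.expm1(np.where(small, 1.0, x / y)))
    return out


def hh_rates(v):
    """The six gate rate constants at membrane potential v [mV]."""
    v = np.asarray(v, dtype=float)
    alpha_n = 0.01 * _vtrap(-v - 60.0, 10.0)     # 0.01 (-V-60)/(exp((-V-60)/10)-1)
    beta_n = 0.125 * np.exp((-v - 70.0) / 80.0)
    alpha_m = 0.1 * _vtrap(-v - 45.0, 10.0)      # 0.1 (-V-45)/(exp((-V-45)/10)-1)
    beta_m = 4.0 * np.exp((-v - 70.0) / 18.0)
    alpha_h = 0.07 * np.exp((-v - 70.0) / 20.0)
    beta_h = 1.0 / (np.exp((-v - 40.0) / 10.0) + 1.0)
    out = {"alpha_n": alpha_n, "beta_n": beta_n, "alpha_m": alpha_m,
           "beta_m": beta_m, "alpha_h": alpha_h, "beta_h": beta_h}
    if np.ndim(v) == 0:
        out = {k: float(val) for k, val in out.items()}
    return out


@dataclass
class HHNeuronState:
    v: float = -70.0
    n: float = 0.3177
    m: float = 0.0529
    h: float = 0.5961

    def as_array(self):
        return np.array([self.v, self.n, self.m, self.h])


def hh_rhs(y, i_app, p):
    """Right-hand side of the 4-ODE system; y = [V, n, m, h], time in ms."""
    v, n, m, h = y
    r = hh_rates(v)
    dv = (i_app - p.hh_gK * n ** 4 * (v - p.hh_VK)
          - p.hh_gNa * m ** 3 * h * (v - p.hh_VNa)
          - p.hh_gL * (v - p.hh_VL)) / p.hh_C
    dn = r["alpha_n"] * (1.0 - n) - r["beta_n"] * n
    dm = r["alpha_m"] * (1.0 - m) - r["beta_m"] * m
    dh = r["alpha_h"] * (1.0 - h) - r["beta_h"] * h
    return np.array([dv, dn, dm, dh])


def hh_step(state: HHNeuronState, i_app: float, dt_ms: float, p) -> HHNeuronState:
    """One RK4 step of the membrane equations (dt in ms)."""
    y = state.as_array()
    k1 = hh_rhs(y, i_app, p)
    k2 = hh_rhs(y + 0.5 * dt_ms * k1, i_app, p)
    k3 = hh_rhs(y + 0.5 * dt_ms * k2, i_app, p)
    k4 = hh_rhs(y + dt_ms * k3, i_app, p)
    y = y + dt_ms / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("HH state diverged")
    return HHNeuronState(*y)


def resting_state(p, t_relax_ms: float = 200.0, dt_ms: float = 0.02
                  ) -> HHNeuronState:
    s = HHNeuronState()
    for _ in range(int(t_relax_ms / dt_ms)):
        s = hh_step(s, 0.0, dt_ms, p)
    return s
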