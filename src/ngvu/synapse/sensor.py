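"""Stochastic calcium sensor of docked vesicles (exact SSA).

Each docked vesicle carries a sensor with five sequential Ca-binding sites
plus a Ca-independent isomerization of the fully bound form; occupancy is
an integer 0..5, with 6 denoting the isomerized, release-ready state.
Transition rates (per ms):

    k -> k+1 : (5-k) alpha c_i     (k = 0..4)
    k -> k-1 : k beta              (k = 1..5)
    5 -> 6   : gamma,   6 -> 5 : delta

A vesicle in state 6 is release-ready; with two docked vesicles the
release-ready fraction f_r takes values {0, 0.5, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

READY_STATE = 6


@dataclass
class VesicleSensorState:
    occupancy: np.ndarray = field(
        default_factory=lambda: np.zeros(2, dtype=int))

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=int)
        if np.any((self.occupancy < 0) | (self.occupancy > READY_STATE)):
            raise ValueError("invalid sensor occupancy")

    @property
    def n_ready(self) -> int:
        return int(np.sum(self.occupancy == READY_STATE))


def propensities(state: int, c_i: float, p) -> list:
    """[(rate_per_ms, new_state), ...] for one vesicle."""
    out = []
    if state <= 4:
        out.append(((5 - state) * p.sensor_alpha * c_i, state + 1))
    if 1 <= state <= 5:
        out.append((state * p.sensor_beta, state - 1))
    if state == 5:
        out.append((p.sensor_gamma, READY_STATE))
    if state == READY_STATE:
        out.append((p.sensor_delta, 5))
    return out


def sensor_step(sensors: VesicleSensorState, c_i: float, dt_ms: float,
                rng: np.random.Generator, p):
    """Advance every vesicle by exact SSA over dt_ms (c_i frozen); returns
    (new_state, f_r)."""
    occ = sensors.occupancy.copy()
    for i in range(occ.size):
        t = 0.0
        s = int(occ[i])
        while True:
            props = propensities(s, c_i, p)
            total = sum(r for r, _ in props)
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t >= dt_ms:
                break
            u = rng.uniform(0.0, total)
            acc = 0.0
            for r, nxt in props:
                acc += r
                if u < acc:
                    s = nxt
                    break
        occ[i] = s
    new = VesicleSensorState(occ)
    f_r = min(1.0, 0.5 * new.n_ready)
    return new, f_r


def master_matrix(c_i: float, p) -> np.ndarray:
    """Generator matrix Q (7x7, per ms) of the single-vesicle chain.

    dP/dt = Q^T P.  Exposed for calibration; the test-suite builds its own
    independent version as an oracle.
    """
    q = np.zeros((7, 7))
    for s in range(7):
        for rate, nxt in propensities(s, c_i, p):
            q[s, nxt] += rate
            q[s, s] -= rate
    return q
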