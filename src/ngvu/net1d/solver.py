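"""Explicit solver for the nonlinear 1D blood-flow system.

Scheme: Richtmyer two-step Lax-Wendroff on the conservative form

    dA/dt + dQ/dz = 0
    dQ/dt + d/dz (Q^2/A + beta A^{3/2}) = -f Q/A,   beta = G0/(3 rho sqrt(A0))

(the beta flux integrates A/rho dP/dz for the square-root tube law), with
friction factor f = 2 (gamma_bar + 2) mu(2 R0) / rho.  Boundaries are closed
with Riemann invariants W± = u ± 4 (c - c0): half-sine inflow at the aorta,
Newton-solved junction systems (flow conservation + total-pressure
continuity + one outgoing invariant per end), and RCR Windkessel outlets.

All vessels are packed into padded (V, Nmax) arrays so a step is a handful
of vectorized operations; junctions with the same number of ends are solved
as batched dense Newton systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..units import CGS_TO_MMHG
from .vessels import (ArterialNetwork1D, FRICTION_FACTOR, inlet_flow,
                      windkessel_update, young_laplace_pressure)


@dataclass
class HemoField1D:
    """Per-vessel area/flow arrays on the padded grid at one time."""
    a: np.ndarray           # (V, Nmax) cm^2
    q: np.ndarray           # (V, Nmax) cm^3/s
    t: float = 0.0

    def copy(self):
        return HemoField1D(self.a.copy(), self.q.copy(), self.t)


class CFLError(RuntimeError):
    pass


def _char_speed(a, a0, g0, rho):
    return np.sqrt(g0 / (2.0 * rho) * np.sqrt(a / a0))


def solve_junction_system(a, u, w_out, a0, g0, c0, sigma, rho,
                          max_iter=50, tol=1e-10):
    """Batched Newton solve for junction boundary states.

    All arrays have shape (J, E): E vessel ends per junction; ``sigma`` is
    +1 where the end is a parent distal end (flow into the junction,
    outgoing invariant W+) and -1 for a child start (W-).  Returns
    (a, u, converged_mask, residual_norm).
    """
    a = a.copy()
    u = u.copy()
    J, E = a.shape
    n = 2 * E
    idx_a = np.arange(E) * 2
    idx_u = idx_a + 1
    u_scale = np.maximum(np.abs(c0).max(axis=1, keepdims=True), 1.0)
    p_scale = g0.max(axis=1, keepdims=True)
    m_scale = (a0 * c0).max(axis=1, keepdims=True)

    res_norm = np.full(J, np.inf)
    for _ in range(max_iter):
        c = _char_speed(a, a0, g0, rho)
        p = g0 * (np.sqrt(a / a0) - 1.0)
        pt = p + 0.5 * rho * u * u
        r = np.zeros((J, n))
        r[:, :E] = (u + sigma * 4.0 * (c - c0) - w_out)
        r[:, E:n - 1] = pt[:, 1:] - pt[:, :1]
        r[:, n - 1] = np.sum(sigma * a * u, axis=1)
        res_norm = np.maximum.reduce([
            np.abs(r[:, :E]).max(axis=1) / u_scale[:, 0],
            np.abs(r[:, E:n - 1]).max(axis=1) / p_scale[:, 0]
            if E > 1 else np.zeros(J),
            np.abs(r[:, n - 1]) / m_scale[:, 0]])
        if np.all(res_norm < tol):
            break

        jac = np.zeros((J, n, n))
        dp_da = g0 / (2.0 * np.sqrt(a * a0))
        # characteristic rows
        for e in range(E):
            jac[:, e, idx_a[e]] = sigma[:, e] * c[:, e] / a[:, e]
            jac[:, e, idx_u[e]] = 1.0
        # total-pressure rows (end e vs end 0)
        for e in range(1, E):
            row = E + e - 1
            jac[:, row, idx_a[e]] = dp_da[:, e]
            jac[:, row, idx_u[e]] = rho * u[:, e]
            jac[:, row, idx_a[0]] = -dp_da[:, 0]
            jac[:, row, idx_u[0]] = -rho * u[:, 0]
        # mass row
        for e in range(E):
            jac[:, n - 1, idx_a[e]] = sigma[:, e] * u[:, e]
            jac[:, n - 1, idx_u[e]] = sigma[:, e] * a[:, e]

        dx = np.linalg.solve(jac, -r[..., None])[..., 0]
        da = dx[:, idx_a]
        du = dx[:, idx_u]
        # damping: keep areas positive
        lim = np.where(da < 0, -0.9 * a / np.minimum(da, -1e-300), 1.0)
        step = np.minimum(1.0, lim.min(axis=1, keepdims=True))
        a += step * da
        u += step * du

    return a, u, res_norm < tol, res_norm


class NetworkSolver:
    """Time stepper for an :class:`ArterialNetwork1D`."""

    def __init__(self, net: ArterialNetwork1D, cfl: float = 0.85):
        self.net = net
        self.rho = net.rho
        self.cfl = cfl
        vids = sorted(net.vessels)
        self.vids = vids
        self.vidx = {vid: i for i, vid in enumerate(vids)}
        V = len(vids)
        self.n_nodes = np.array([net.vessels[v].n_cells + 1 for v in vids])
        nmax = self.n_nodes.max()
        self.nmax = nmax

        def per_vessel(fn):
            return np.array([fn(net.vessels[v]) for v in vids])

        self.a0 = per_vessel(lambda v: v.a0)
        self.g0 = per_vessel(lambda v: v.g0)
        self.dz = per_vessel(lambda v: v.dz)
        self.length = per_vessel(lambda v: v.length)
        self.c0 = _char_speed(self.a0, self.a0, self.g0, self.rho)
        self.beta = self.g0 / (3.0 * self.rho * np.sqrt(self.a0))
        mu_pas = np.array([net.viscosity_law(2.0 * net.vessels[v].r0)
                           for v in vids], dtype=float)
        self.fric = FRICTION_FACTOR * (mu_pas * 10.0) / self.rho  # poise/rho

        self.valid = np.zeros((V, nmax), dtype=bool)
        for i, nn in enumerate(self.n_nodes):
            self.valid[i, :nn] = True
        self.a0_pad = np.repeat(self.a0[:, None], nmax, axis=1)

        # stability: fixed dt with headroom for A growth and advection
        lam = 1.2 * self.c0 + 150.0
        self.dt = float(cfl * np.min(self.dz / lam))

        # junction bookkeeping grouped by end count
        self.j_groups = []
        for n_ends in sorted({len(p) + len(c) for p, c in net.junctions}):
            sel = [(p, c) for p, c in net.junctions if len(p) + len(c) == n_ends]
            vess, side, sig = [], [], []
            for parents, children in sel:
                ends = [(self.vidx[v], 1, 1.0) for v in parents] \
                    + [(self.vidx[v], 0, -1.0) for v in children]
                vess.append([e[0] for e in ends])
                side.append([e[1] for e in ends])
                sig.append([e[2] for e in ends])
            g = {
                "vess": np.array(vess), "side": np.array(side),
                "sigma": np.array(sig),
            }
            g["bcol"] = np.where(g["side"] == 1,
                                 self.n_nodes[g["vess"]] - 1, 0)
            g["ncol"] = np.where(g["side"] == 1,
                                 self.n_nodes[g["vess"]] - 2, 1)
            for key in ("a0", "g0", "c0", "dz"):
                g[key] = getattr(self, key)[g["vess"]]
            self.j_groups.append(g)

        self.inlet_idx = self.vidx[net.inlet_vessel]
        self.outlet_ids = sorted(net.outlets)
        self.out_idx = np.array([self.vidx[v] for v in self.outlet_ids])
        self.out_col = self.n_nodes[self.out_idx] - 1

    # ------------------------------------------------------------------
    def initial_field(self) -> HemoField1D:
        a = self.a0_pad.copy()
        q = np.zeros_like(a)
        return HemoField1D(a, q, 0.0)

    def pressure(self, field: HemoField1D) -> np.ndarray:
        """Pressure (CGS) on the padded grid via the tube law."""
        return self.g0[:, None] * (np.sqrt(field.a / self.a0[:, None]) - 1.0)

    def _flux(self, a, q):
        return q, q * q / a + self.beta[:, None] * a ** 1.5

    def _invariant(self, a, u, plus: bool):
        c = _char_speed(a, self.a0[:, None], self.g0[:, None], self.rho)
        s = 4.0 if plus else -4.0
        return u + s * (c - self.c0[:, None]), c

    def _foot_invariant(self, field, vess, bcol, ncol, dz, plus_mask):
        """Outgoing invariant extrapolated to the characteristic foot."""
        a_b = field.a[vess, bcol]
        a_n = field.a[vess, ncol]
        u_b = field.q[vess, bcol] / a_b
        u_n = field.q[vess, ncol] / a_n
        c_b = _char_speed(a_b, self.a0[vess], self.g0[vess], self.rho)
        c_n = _char_speed(a_n, self.a0[vess], self.g0[vess], self.rho)
        s = np.where(plus_mask, 4.0, -4.0)
        w_b = u_b + s * (c_b - self.c0[vess])
        w_n = u_n + s * (c_n - self.c0[vess])
        lam = np.abs(u_b + np.where(plus_mask, c_b, -c_b))
        frac = np.clip(lam * self.dt / dz, 0.0, 1.0)
        return w_b + (w_n - w_b) * frac

    # ------------------------------------------------------------------
    def step(self, field: HemoField1D, t_inlet_flow) -> HemoField1D:
        """Advance one dt.  ``t_inlet_flow``: callable t -> Q_in (cm^3/s)."""
        a, q, dt = field.a, field.q, self.dt
        if np.any(a[self.valid] <= 0):
            raise CFLError("non-positive area encountered")
        lam_max = np.max(np.abs(q[self.valid] / a[self.valid])) \
            + np.max(_char_speed(a[self.valid],
                                 self.a0_pad[self.valid],
                                 np.repeat(self.g0[:, None], self.nmax,
                                           axis=1)[self.valid], self.rho))
        if dt > self.cfl * np.min(self.dz) / lam_max * 1.5:
            raise CFLError(
                f"CFL violated: dt={dt:g}, max speed {lam_max:g} cm/s")

        f1, f2 = self._flux(a, q)
        r = (dt / (2.0 * self.dz))[:, None]
        ah = 0.5 * (a[:, 1:] + a[:, :-1]) - r * (f1[:, 1:] - f1[:, :-1])
        qh = 0.5 * (q[:, 1:] + q[:, :-1]) - r * (f2[:, 1:] - f2[:, :-1])
        ah = np.maximum(ah, 0.05 * self.a0_pad[:, 1:])
        fh1, fh2 = self._flux(ah, qh)
        r2 = (dt / self.dz)[:, None]
        a_new = a.copy()
        q_new = q.copy()
        a_new[:, 1:-1] = a[:, 1:-1] - r2 * (fh1[:, 1:] - fh1[:, :-1])
        q_new[:, 1:-1] = q[:, 1:-1] - r2 * (fh2[:, 1:] - fh2[:, :-1]) \
            - dt * self.fric[:, None] * q[:, 1:-1] / a[:, 1:-1]

        new = HemoField1D(a_new, q_new, field.t + dt)
        self._apply_inlet(field, new, t_inlet_flow)
        self._apply_junctions(field, new)
        self._apply_outlets(field, new)
        # refresh padding
        new.a[~self.valid] = self.a0_pad[~self.valid]
        new.q[~self.valid] = 0.0
        return new

    def _apply_inlet(self, old, new, t_inlet_flow):
        i = self.inlet_idx
        q_in = float(t_inlet_flow(new.t))
        w = self._foot_invariant(
            old, np.array([i]), np.array([0]), np.array([1]),
            np.array([self.dz[i]]), np.array([False]))[0]
        a0, g0, c0 = self.a0[i], self.g0[i], self.c0[i]
        a = max(old.a[i, 0], 0.1 * a0)
        for _ in range(30):
            c = _char_speed(a, a0, g0, self.rho)
            f = q_in / a - 4.0 * (c - c0) - w
            fp = -q_in / (a * a) - c / a
            da = -f / fp
            a = max(a + min(max(da, -0.4 * a), 0.4 * a), 0.05 * a0)
            if abs(f) < 1e-11 * c0:
                break
        new.a[i, 0] = a
        new.q[i, 0] = q_in

    def _apply_junctions(self, old, new):
        for g in self.j_groups:
            vess, bcol = g["vess"], g["bcol"]
            plus = g["side"] == 1
            w_out = self._foot_invariant(old, vess, bcol, g["ncol"],
                                         g["dz"], plus)
            a_init = old.a[vess, bcol]
            u_init = old.q[vess, bcol] / a_init
            a, u, ok, res = solve_junction_system(
                a_init, u_init, w_out, g["a0"], g["g0"], g["c0"],
                g["sigma"], self.rho)
            if not np.all(ok):
                bad = int(np.argmax(~ok))
                raise RuntimeError(
                    f"junction Newton failed (residual {res[bad]:.3e}) at "
                    f"vessels {[self.vids[v] for v in g['vess'][bad]]}")
            new.a[vess, bcol] = a
            new.q[vess, bcol] = a * u

    def _apply_outlets(self, old, new):
        vi, col = self.out_idx, self.out_col
        w = self._foot_invariant(old, vi, col, col - 1,
                                 self.dz[vi], np.ones(vi.size, bool))
        a0, g0, c0 = self.a0[vi], self.g0[vi], self.c0[vi]
        wks = [self.net.outlets[v] for v in self.outlet_ids]
        pc = np.array([wk.state_pressure for wk in wks])
        r1 = np.array([wk.r1 for wk in wks])
        a = old.a[vi, col].copy()
        for _ in range(30):
            c = _char_speed(a, a0, g0, self.rho)
            u = w - 4.0 * (c - c0)
            p = g0 * (np.sqrt(a / a0) - 1.0)
            f = a * u - (p - pc) / r1
            fp = u - c - g0 / (2.0 * np.sqrt(a * a0)) / r1
            da = np.clip(-f / fp, -0.4 * a, 0.4 * a)
            a = np.maximum(a + da, 0.05 * a0)
            if np.abs(f).max() < 1e-11 * (a0 * c0).max():
                break
        c = _char_speed(a, a0, g0, self.rho)
        u = w - 4.0 * (c - c0)
        q = a * u
        new.a[vi, col] = a
        new.q[vi, col] = q
        for wk, qi in zip(wks, q):
            windkessel_update(float(qi), wk, self.dt)


@dataclass
class PeriodicResult:
    t: np.ndarray                       # one-beat sample times [s]
    probes: dict                        # (vessel_id, z_frac) -> {"Q","P_mmHg"}
    beats: int
    converged: bool
    history: list = field(default_factory=list)   # per-beat L2 diffs

    def series(self, vessel_id, z_frac=1.0):
        return self.probes[(vessel_id, z_frac)]


def run_to_periodicity(net: ArterialNetwork1D, T: float = 1.0,
                       q_max: float = 485.0, tol: float = 1e-3,
                       beats_max: int = 30, probes=None,
                       cfl: float = 0.85,
                       sample_every: int = 10) -> PeriodicResult:
    """Beat the network from rest (A=A0, Q=0) until consecutive beats agree.

    Convergence: relative L2 difference of both P and Q between successive
    beats below ``tol`` at every monitored probe.  Raises if ``beats_max``
    is exhausted, reporting the trend.
    """
    solver = NetworkSolver(net, cfl=cfl)
    if probes is None:
        probes = [(vid, 1.0) for vid in sorted(net.outlets)] \
            + [(net.inlet_vessel, 0.0)]
    probe_idx = []
    for vid, zf in probes:
        i = solver.vidx[vid]
        col = int(round(zf * (solver.n_nodes[i] - 1)))
        probe_idx.append((vid, zf, i, col))

    field = solver.initial_field()
    inflow = lambda t: inlet_flow(t, T, q_max)
    steps_per_beat = int(np.ceil(T / solver.dt))
    prev = None
    history = []
    converged = False
    beats_done = 0
    for beat in range(beats_max):
        rec_t, rec = [], {k: ([], []) for k in range(len(probe_idx))}
        for s in range(steps_per_beat):
            field = solver.step(field, inflow)
            if s % sample_every == 0 or s == steps_per_beat - 1:
                rec_t.append(field.t)
                pr = solver.pressure(field)
                for k, (_, _, i, col) in enumerate(probe_idx):
                    rec[k][0].append(field.q[i, col])
                    rec[k][1].append(pr[i, col])
        beats_done = beat + 1
        cur = {k: (np.array(v[0]), np.array(v[1])) for k, v in rec.items()}
        if prev is not None:
            diffs = []
            for k in cur:
                for arr, parr in ((0, 0), (1, 1)):
                    x, y = cur[k][arr], prev[k][arr]
                    m = min(x.size, y.size)
                    denom = np.linalg.norm(y[:m]) + 1e-12
                    diffs.append(np.linalg.norm(x[:m] - y[:m]) / denom)
            d = max(diffs)
            history.append(d)
            if d < tol:
                converged = True
                break
        prev = cur

    if not converged:
        raise RuntimeError(
            f"no periodic state within {beats_max} beats; "
            f"beat-to-beat L2 trend: {['%.2e' % h for h in history[-5:]]}")

    t_arr = np.array(rec_t) - rec_t[0]
    out_probes = {}
    for k, (vid, zf, i, col) in enumerate(probe_idx):
        out_probes[(vid, zf)] = {
            "Q": cur[k][0],
            "P_mmHg": cur[k][1] * CGS_TO_MMHG,
        }
    return PeriodicResult(t=t_arr, probes=out_probes, beats=beats_done,
                          converged=converged, history=history)
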