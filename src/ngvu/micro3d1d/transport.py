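"""Advection-diffusion transport on the capillary graph and tissue box.

Operator splitting per step: explicit upwind advection (1D along segments,
3D on the cell grid) followed by implicit diffusion, plus a diffusive wall
exchange between each segment midpoint and its containing tissue cell.
Outer tissue boundary is homogeneous Neumann; 1D boundary conditions are
the prescribed inlet concentration (advected in with the inlet flow) and
free outflow at outlets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, eye, csc_matrix
from scipy.sparse.linalg import factorized

from .network import CapillaryGraph
from .pressure import TissueDomain

D1_DEFAULT = 1.0e3   # axial solute diffusivity in blood [um^2/s]
D3_DEFAULT = 1.8e3   # tissue diffusivity [um^2/s]
KW_DEFAULT = 3.0     # wall solute permeability [um/s]


@dataclass
class TransportState:
    c1: np.ndarray                      # per 1D node
    c3: np.ndarray                      # (nx, ny, nz)
    d1: float = D1_DEFAULT
    d3: float = D3_DEFAULT
    k_wall: float = KW_DEFAULT
    time: float = 0.0

    def copy(self) -> "TransportState":
        return TransportState(self.c1.copy(), self.c3.copy(), self.d1,
                              self.d3, self.k_wall, self.time)


class _Workspace:
    """Cached geometry/factorization reused across steps."""

    def __init__(self, graph: CapillaryGraph, tissue: TissueDomain,
                 d1: float, d3: float, dt: float):
        self.graph, self.tissue = graph, tissue
        self.lengths = graph.lengths
        self.areas = np.pi * graph.radii ** 2
        self.seg_vol = self.areas * self.lengths
        self.node_vol = np.zeros(graph.n_nodes)
        np.add.at(self.node_vol, graph.segments[:, 0], 0.5 * self.seg_vol)
        np.add.at(self.node_vol, graph.segments[:, 1], 0.5 * self.seg_vol)
        mids = 0.5 * (graph.nodes[graph.segments[:, 0]]
                      + graph.nodes[graph.segments[:, 1]])
        self.mid_cells = tissue.cell_index(mids)
        self.wall_area = 2.0 * np.pi * graph.radii * self.lengths
        self.cell_vol = float(np.prod(tissue.spacing))
        # implicit 3D diffusion operator (I - dt D3 L/V)
        n3 = tissue.n_cells
        nx, ny, nz = tissue.shape
        idx = np.arange(n3).reshape(nx, ny, nz)
        rows, cols, vals = [], [], []
        for axis, h in enumerate(tissue.spacing):
            g = d3 / (h * h)
            lo = np.take(idx, range(0, idx.shape[axis] - 1), axis=axis).ravel()
            hi = np.take(idx, range(1, idx.shape[axis]), axis=axis).ravel()
            for i, j in ((lo, hi), (hi, lo)):
                rows.extend(i)
                cols.extend(j)
                vals.extend(np.full(i.size, g))
                rows.extend(i)
                cols.extend(i)
                vals.extend(np.full(i.size, -g))
        lap = coo_matrix((vals, (rows, cols)), shape=(n3, n3)).tocsc()
        self.solve3 = factorized(csc_matrix(eye(n3)) - dt * lap)


def _advect_1d(c1, graph, ws, v_c, dt, inlet_flows, outlet_flows, inlet_conc):
    q = v_c * ws.areas  # um^3/s signed along node order
    dm = np.zeros_like(c1)  # mass change per node (um^3 * conc)
    up = np.where(q >= 0, graph.segments[:, 0], graph.segments[:, 1])
    flux = q * c1[up]
    np.add.at(dm, graph.segments[:, 0], -flux)
    np.add.at(dm, graph.segments[:, 1], flux)
    for nid, qin in (inlet_flows or {}).items():
        dm[nid] += qin * inlet_conc
    for nid, qout in (outlet_flows or {}).items():
        dm[nid] -= qout * c1[nid]
    return c1 + dt * dm / np.maximum(ws.node_vol, 1e-30)


def _advect_3d(c3, tissue, v_omega, dt):
    c = c3
    out = c.copy()
    for axis in range(3):
        h = tissue.spacing[axis]
        v = v_omega[..., axis]
        # face velocity = average of adjacent cells; upwind face value
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        vf = 0.5 * (v[tuple(sl_lo)] + v[tuple(sl_hi)])
        cf = np.where(vf >= 0, c[tuple(sl_lo)], c[tuple(sl_hi)])
        flux = vf * cf / h
        out[tuple(sl_lo)] -= dt * flux
        out[tuple(sl_hi)] += dt * flux
    return out


def solve_transport(state: TransportState, graph: CapillaryGraph,
                    tissue: TissueDomain, v_c: np.ndarray,
                    v_omega: np.ndarray, dt: float, n_steps: int = 1,
                    inlet_flows: dict | None = None,
                    outlet_flows: dict | None = None,
                    inlet_conc: float = 0.0,
                    tissue_sink_rate: float = 0.0,
                    workspace: _Workspace | None = None) -> TransportState:
    """Advance the coupled 1D/3D solute fields by ``n_steps`` of ``dt`` [s]."""
    ws = workspace or _Workspace(graph, tissue, state.d1, state.d3, dt)
    # advective CFL on graph and grid
    with np.errstate(divide="ignore"):
        cfl_1d = np.min(ws.lengths / np.maximum(np.abs(v_c), 1e-30))
        cfl_3d = np.min(tissue.spacing / max(np.abs(v_omega).max(), 1e-30))
    if dt > min(cfl_1d, cfl_3d):
        raise ValueError(
            f"advective CFL violated: dt={dt:g} > {min(cfl_1d, cfl_3d):g}")

    c1, c3 = state.c1.copy(), state.c3.copy()
    segs = graph.segments
    g_diff1 = state.d1 * ws.areas / ws.lengths
    for _ in range(n_steps):
        c1 = _advect_1d(c1, graph, ws, v_c, dt, inlet_flows, outlet_flows,
                        inlet_conc)
        c3 = _advect_3d(c3, tissue, v_omega, dt)
        # explicit 1D diffusion
        dflux = g_diff1 * (c1[segs[:, 1]] - c1[segs[:, 0]])
        dm = np.zeros_like(c1)
        np.add.at(dm, segs[:, 0], dflux)
        np.add.at(dm, segs[:, 1], -dflux)
        # wall exchange at segment midpoints
        c1_mid = 0.5 * (c1[segs[:, 0]] + c1[segs[:, 1]])
        c3_flat = c3.ravel()
        ex = state.k_wall * ws.wall_area * (c1_mid - c3_flat[ws.mid_cells])
        np.add.at(dm, segs[:, 0], -0.5 * ex)
        np.add.at(dm, segs[:, 1], -0.5 * ex)
        c1 = c1 + dt * dm / np.maximum(ws.node_vol, 1e-30)
        dm3 = np.zeros_like(c3_flat)
        np.add.at(dm3, ws.mid_cells, ex)
        c3_flat = c3_flat + dt * dm3 / ws.cell_vol
        if tissue_sink_rate:
            c3_flat = c3_flat * max(0.0, 1.0 - dt * tissue_sink_rate)
        # implicit 3D diffusion
        c3 = ws.solve3(c3_flat).reshape(tissue.shape)

    out = state.copy()
    out.c1, out.c3 = c1, c3
    out.time = state.time + n_steps * dt
    return out


def total_mass(state: TransportState, graph: CapillaryGraph,
               tissue: TissueDomain) -> float:
    ws_vol = np.pi * graph.radii ** 2 * graph.lengths
    node_vol = np.zeros(graph.n_nodes)
    np.add.at(node_vol, graph.segments[:, 0], 0.5 * ws_vol)
    np.add.at(node_vol, graph.segments[:, 1], 0.5 * ws_vol)
    cell_vol = float(np.prod(tissue.spacing))
    return float(np.sum(state.c1 * node_vol) + np.sum(state.c3) * cell_vol)
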