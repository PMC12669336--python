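"""Stationary 3D-1D coupled pressure solve.

The 1D network pressure p1 lives on graph nodes; the 3D tissue pressure p3
on a uniform cell-centered finite-volume grid.  The wall-exchange term
2 pi R Lp (p1 - <p3>) is assembled by sampling each segment's centerline at
M quadrature points, coupling the interpolated p1 to the containing grid
cell; the matching distributional source enters the 3D equations, giving a
symmetric coupled system.  Units: um, s, mmHg; flows in um^3/s.

Both inlets and outlets carry Neumann (flow) data, so one gauge constraint
is required: the solve pins one interior 1D node, then shifts the whole
field uniformly so the length-weighted mean network pressure matches the
configured gauge (default 30 mmHg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import spsolve

from .network import CapillaryGraph

K3_DEFAULT = 1.0     # tissue hydraulic conductivity [um^2/(mmHg s)]
GAUGE_DEFAULT = 30.0  # mmHg


@dataclass
class TissueDomain:
    box: tuple = (150.0, 160.0, 140.0)
    shape: tuple = (20, 20, 20)
    k3: float = K3_DEFAULT
    gauge_mmhg: float = GAUGE_DEFAULT

    def __post_init__(self):
        self.box = tuple(float(v) for v in self.box)
        self.shape = tuple(int(v) for v in self.shape)
        if min(self.shape) < 4:
            raise ValueError("grid resolution must be >= 4 cells per axis")
        if self.k3 <= 0:
            raise ValueError("K3 must be positive")

    @property
    def spacing(self) -> np.ndarray:
        return np.array(self.box) / np.array(self.shape)

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def cell_index(self, points: np.ndarray) -> np.ndarray:
        """Flat cell index containing each point (points clipped to the box)."""
        pts = np.atleast_2d(points)
        idx = np.floor(pts / self.spacing).astype(int)
        idx = np.clip(idx, 0, np.array(self.shape) - 1)
        nx, ny, nz = self.shape
        return (idx[:, 0] * ny + idx[:, 1]) * nz + idx[:, 2]


@dataclass
class PressureSolution:
    p1: np.ndarray                   # mmHg per 1D node
    p3: np.ndarray                   # mmHg per 3D cell (nx, ny, nz)
    exchange: np.ndarray             # um^3/s per segment (vessel -> tissue)
    residual: float                  # relative residual of the full system
    graph: CapillaryGraph = field(repr=False)
    tissue: TissueDomain = field(repr=False)


def _segment_conductance(graph: CapillaryGraph) -> np.ndarray:
    return np.pi * graph.radii ** 2 * graph.k1 / graph.lengths


def _coupling_samples(graph: CapillaryGraph, tissue: TissueDomain,
                     samples_per_segment: int | None = None):
    """Per-sample (segment, node weights, cell index, Lp*area weight)."""
    h_min = tissue.spacing.min()
    recs = []
    for s, (a, b) in enumerate(graph.segments):
        length = graph.lengths[s]
        m = samples_per_segment or max(2, int(np.ceil(length / h_min)))
        xi = (np.arange(m) + 0.5) / m
        pts = graph.nodes[a] + xi[:, None] * (graph.nodes[b] - graph.nodes[a])
        cells = tissue.cell_index(pts)
        w = 2.0 * np.pi * graph.radii[s] * graph.lp[s] * length / m
        for x, c in zip(xi, cells):
            recs.append((s, a, b, 1.0 - x, x, int(c), w))
    return recs


def assemble(graph: CapillaryGraph, tissue: TissueDomain,
             samples_per_segment: int | None = None):
    """Symmetric coupled matrix (3D block first, then 1D nodes)."""
    n3, n1 = tissue.n_cells, graph.n_nodes
    nx, ny, nz = tissue.shape
    hx, hy, hz = tissue.spacing
    vol_faces = ((hy * hz / hx), (hx * hz / hy), (hx * hy / hz))

    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    # 3D Laplacian, homogeneous Neumann at the box boundary
    idx = np.arange(n3).reshape(nx, ny, nz)
    for axis, g_face in enumerate(vol_faces):
        g = tissue.k3 * g_face
        lo = np.take(idx, range(0, idx.shape[axis] - 1), axis=axis).ravel()
        hi = np.take(idx, range(1, idx.shape[axis]), axis=axis).ravel()
        for i, j in ((lo, hi), (hi, lo)):
            add_arr = np.full(i.size, -g)
            rows.extend(i)
            cols.extend(j)
            vals.extend(add_arr)
            rows.extend(i)
            cols.extend(i)
            vals.extend(-add_arr)

    # 1D axial conductances
    g_seg = _segment_conductance(graph)
    for (a, b), g in zip(graph.segments, g_seg):
        ia, ib = n3 + a, n3 + b
        add(ia, ia, g)
        add(ib, ib, g)
        add(ia, ib, -g)
        add(ib, ia, -g)

    # wall exchange (Galerkin assembly of Lp (p1 - p3) pairing)
    samples = _coupling_samples(graph, tissue, samples_per_segment)
    for s, a, b, wa, wb, cell, w in samples:
        ia, ib = n3 + a, n3 + b
        add(ia, ia, w * wa * wa)
        add(ib, ib, w * wb * wb)
        add(ia, ib, w * wa * wb)
        add(ib, ia, w * wa * wb)
        add(ia, cell, -w * wa)
        add(ib, cell, -w * wb)
        add(cell, ia, -w * wa)
        add(cell, ib, -w * wb)
        add(cell, cell, w)

    mat = coo_matrix((vals, (rows, cols)), shape=(n3 + n1, n3 + n1)).tocsr()
    return mat, samples


def _gauge_node(graph: CapillaryGraph) -> int:
    """Largest-radius interior node (degree >= 2), id tie-break."""
    deg = np.bincount(graph.segments.ravel(), minlength=graph.n_nodes)
    best, best_r = None, -1.0
    for s, (a, b) in enumerate(graph.segments):
        for n in (a, b):
            if deg[n] >= 2 and graph.radii[s] > best_r:
                best, best_r = n, graph.radii[s]
    if best is None:  # fall back to the first inlet's neighbor
        best = int(graph.segments[0, 1])
    return int(best)


def solve_pressure_3d1d(graph: CapillaryGraph, tissue: TissueDomain,
                        inlet_flows: dict, outlet_flows: dict,
                        samples_per_segment: int | None = None,
                        rtol: float = 1e-8) -> PressureSolution:
    """Solve the coupled system for prescribed nodal in/outflows [um^3/s].

    ``inlet_flows``/``outlet_flows`` map node id -> flow magnitude; inflow
    counts positive into the network, outflow positive out of it.  The data
    must satisfy the Neumann compatibility sum(in) == sum(out).
    """
    n3, n1 = tissue.n_cells, graph.n_nodes
    rhs = np.zeros(n3 + n1)
    for nid, q in inlet_flows.items():
        rhs[n3 + nid] += q
    for nid, q in outlet_flows.items():
        rhs[n3 + nid] -= q
    imbalance = rhs.sum()
    scale = max(sum(abs(q) for q in inlet_flows.values()), 1e-30)
    if abs(imbalance) > 1e-9 * scale:
        raise ValueError(
            "Neumann solvability violated: inlet and outlet flows differ "
            f"by {imbalance:g} um^3/s")

    mat, samples = assemble(graph, tissue, samples_per_segment)

    pin = n3 + _gauge_node(graph)
    mat_pinned = mat.tolil()
    mat_pinned.rows[pin] = [pin]
    mat_pinned.data[pin] = [1.0]
    rhs_pinned = rhs.copy()
    rhs_pinned[pin] = 0.0
    sol = spsolve(csr_matrix(mat_pinned), rhs_pinned)

    # residual of the original singular system (pinned row is redundant
    # under compatible data, so this checks conservation everywhere)
    res_vec = mat @ sol - rhs
    res_scale = max(scale, float(np.abs(mat @ sol).max()), 1e-30)
    residual = float(np.abs(res_vec).max() / res_scale)
    if residual > rtol:
        raise RuntimeError(f"pressure solve residual {residual:g} > {rtol:g}")

    p3 = sol[:n3]
    p1 = sol[n3:]

    # uniform shift to the gauge: length-weighted mean of midpoint p1
    w = graph.lengths
    mid = 0.5 * (p1[graph.segments[:, 0]] + p1[graph.segments[:, 1]])
    shift = tissue.gauge_mmhg - float(np.sum(w * mid) / w.sum())
    p1 = p1 + shift
    p3 = p3 + shift

    exchange = np.zeros(graph.n_segments)
    for s, a, b, wa, wb, cell, wgt in samples:
        exchange[s] += wgt * (wa * p1[a] + wb * p1[b] - p3[cell])

    return PressureSolution(
        p1=p1, p3=p3.reshape(tissue.shape), exchange=exchange,
        residual=residual, graph=graph, tissue=tissue)


def compute_velocities(sol: PressureSolution):
    """(v_c, v_omega): per-segment 1D velocity and per-cell 3D velocity.

    v_c = -K1 dp1/ds signed along each segment's node order [um/s];
    v_omega = -K3 grad p3 as an (nx, ny, nz, 3) array [um/s].
    """
    g = sol.graph
    dp = sol.p1[g.segments[:, 1]] - sol.p1[g.segments[:, 0]]
    v_c = -g.k1 * dp / g.lengths
    hx, hy, hz = sol.tissue.spacing
    grads = np.gradient(sol.p3, hx, hy, hz, edge_order=1)
    v_omega = -sol.tissue.k3 * np.stack(grads, axis=-1)
    return v_c, v_omega
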