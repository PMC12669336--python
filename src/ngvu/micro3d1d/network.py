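"""Capillary network container, ASCII I/O and a synthetic generator.

ASCII dialect (one record per line, '#' starts a comment):

    <n_nodes> <n_segments>
    <node_id> <x_um> <y_um> <z_um>          (n_nodes lines)
    <seg_id> <node1> <node2> <radius_um>    (n_segments lines)
    INLET <node_id>
    OUTLET <node_id>

Node and segment ids are 0-based and must be contiguous.  All lengths are
micrometres; segment lengths are the Euclidean node distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..units import MMHG_TO_PA
from ..viscosity import ConstantViscosity, ViscosityLaw

LP_DEFAULT = 0.05  # wall hydraulic conductivity [um / (mmHg s)]


def k1_poiseuille(radius_um, mu_pas) -> np.ndarray:
    """Axial permeability K1 = R^2/(8 mu) in um^2/(mmHg s).

    With this constitutive choice the 1D flux R^2 pi K1 dp/ds is the
    Hagen-Poiseuille volumetric flow.
    """
    r = np.asarray(radius_um, dtype=float)
    return r * r / (8.0 * np.asarray(mu_pas, dtype=float)) * MMHG_TO_PA


class NetworkFormatError(ValueError):
    """Parse/validation failure; carries the offending line number."""


@dataclass
class CapillaryGraph:
    """1D capillary centerline graph with per-segment radii.

    nodes : (N, 3) coordinates in um.
    segments : (S, 2) node-index pairs.
    radii : (S,) segment radii in um.
    inlets/outlets : node indices with prescribed boundary flows.
    k1/lp : per-segment axial and wall permeabilities (um^2/(mmHg s),
        um/(mmHg s)); defaulted from Poiseuille / LP_DEFAULT when omitted.
    """

    nodes: np.ndarray
    segments: np.ndarray
    radii: np.ndarray
    inlets: list = field(default_factory=list)
    outlets: list = field(default_factory=list)
    k1: np.ndarray | None = None
    lp: np.ndarray | None = None
    viscosity_law: ViscosityLaw = field(default_factory=ConstantViscosity)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.segments = np.asarray(self.segments, dtype=int).reshape(-1, 2)
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        if self.k1 is None:
            mu = self.viscosity_law(self.radii * 2e-4)  # diameter in cm
            self.k1 = k1_poiseuille(self.radii, mu)
        else:
            self.k1 = np.asarray(self.k1, dtype=float).ravel()
        if self.lp is None:
            self.lp = np.full(self.n_segments, LP_DEFAULT)
        else:
            self.lp = np.asarray(self.lp, dtype=float).ravel()
        self.validate()

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def lengths(self) -> np.ndarray:
        d = self.nodes[self.segments[:, 1]] - self.nodes[self.segments[:, 0]]
        return np.linalg.norm(d, axis=1)

    def boundary_nodes(self) -> np.ndarray:
        deg = np.bincount(self.segments.ravel(), minlength=self.n_nodes)
        return np.flatnonzero(deg == 1)

    def validate(self):
        if np.any(self.radii <= 0):
            raise NetworkFormatError("non-positive segment radius")
        if self.segments.size and (self.segments.min() < 0
                                   or self.segments.max() >= self.n_nodes):
            raise NetworkFormatError("segment references unknown node")
        if np.any(self.segments[:, 0] == self.segments[:, 1]):
            raise NetworkFormatError("degenerate segment (self loop)")
        if np.any(self.lengths <= 0):
            raise NetworkFormatError("zero-length segment")
        for nid in list(self.inlets) + list(self.outlets):
            if not 0 <= nid < self.n_nodes:
                raise NetworkFormatError(f"marker references unknown node {nid}")
        # connectivity via union-find
        parent = np.arange(self.n_nodes)

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b in self.segments:
            parent[find(a)] = find(b)
        roots = {find(i) for i in range(self.n_nodes)}
        if len(roots) > 1:
            raise NetworkFormatError(
                f"graph is disconnected ({len(roots)} components)")


def read_capillary_network(stream) -> CapillaryGraph:
    """Parse the documented ASCII dialect; errors name the offending line."""
    if isinstance(stream, str):
        with open(stream) as fh:
            return read_capillary_network(fh)
    lines = stream.read().splitlines()
    records = [(i + 1, ln.split("#", 1)[0].strip())
               for i, ln in enumerate(lines)]
    records = [(no, ln) for no, ln in records if ln]
    if not records:
        raise NetworkFormatError("empty network file")

    def fail(no, msg):
        raise NetworkFormatError(f"line {no}: {msg}")

    no, header = records[0]
    try:
        n_nodes, n_segments = (int(v) for v in header.split())
    except ValueError:
        fail(no, f"bad header {header!r}, expected '<n_nodes> <n_segments>'")
    body = records[1:]
    if len(body) < n_nodes + n_segments:
        raise NetworkFormatError("file truncated")

    nodes = np.zeros((n_nodes, 3))
    for no, ln in body[:n_nodes]:
        parts = ln.split()
        if len(parts) != 4:
            fail(no, "node line must be 'id x y z'")
        idx = int(parts[0])
        if not 0 <= idx < n_nodes:
            fail(no, f"node id {idx} out of range")
        nodes[idx] = [float(v) for v in parts[1:]]

    segments = np.zeros((n_segments, 2), dtype=int)
    radii = np.zeros(n_segments)
    for no, ln in body[n_nodes:n_nodes + n_segments]:
        parts = ln.split()
        if len(parts) != 4:
            fail(no, "segment line must be 'id n1 n2 radius_um'")
        idx = int(parts[0])
        if not 0 <= idx < n_segments:
            fail(no, f"segment id {idx} out of range")
        segments[idx] = [int(parts[1]), int(parts[2])]
        radii[idx] = float(parts[3])
        if radii[idx] <= 0:
            fail(no, f"non-positive radius {radii[idx]}")

    inlets, outlets = [], []
    for no, ln in body[n_nodes + n_segments:]:
        parts = ln.split()
        if len(parts) != 2 or parts[0] not in ("INLET", "OUTLET"):
            fail(no, f"unrecognized record {ln!r}")
        (inlets if parts[0] == "INLET" else outlets).append(int(parts[1]))

    return CapillaryGraph(nodes=nodes, segments=segments, radii=radii,
                          inlets=inlets, outlets=outlets)


def write_capillary_network(graph: CapillaryGraph, stream) -> None:
    if isinstance(stream, str):
        with open(stream, "w") as fh:
            write_capillary_network(graph, fh)
            return
    stream.write("# capillary network ASCII v1\n")
    stream.write(f"{graph.n_nodes} {graph.n_segments}\n")
    for i, (x, y, z) in enumerate(graph.nodes):
        stream.write(f"{i} {x:.6g} {y:.6g} {z:.6g}\n")
    for i, ((a, b), r) in enumerate(zip(graph.segments, graph.radii)):
        stream.write(f"{i} {a} {b} {r:.6g}\n")
    for nid in graph.inlets:
        stream.write(f"INLET {nid}\n")
    for nid in graph.outlets:
        stream.write(f"OUTLET {nid}\n")


def generate_synthetic_network(seed: int = 0, levels: int = 3,
                               box=(150.0, 160.0, 140.0),
                               root_radii=(4.5, 4.0),
                               gamma: float = 3.0) -> CapillaryGraph:
    """Deterministic stand-in for a reconstructed capillary block.

    Two feeding vessels enter the box at x=0; each spawns a binary tree of
    ``levels`` bifurcations whose child radii shrink by 2^(-1/gamma) per
    level.  Matching terminal branches of the two trees are joined by
    anastomoses, and the terminal nodes nearest the far face are marked
    outlets.  The two root nodes carry the largest radii and are marked
    inlets.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    box = np.asarray(box, dtype=float)
    depth_step = box[0] / (levels + 2)
    if depth_step < 1.0:
        raise ValueError("box too small for requested levels")
    rng = np.random.default_rng(seed)
    shrink = 2.0 ** (-1.0 / gamma)

    nodes, segments, radii = [], [], []

    def add_node(p):
        nodes.append(np.clip(p, 1e-3, box - 1e-3))
        return len(nodes) - 1

    def add_seg(a, b, r):
        segments.append((a, b))
        radii.append(r)

    inlets, leaf_tips = [], []
    for k, r0 in enumerate(root_radii):
        y0 = box[1] * (k + 1) / (len(root_radii) + 1)
        root = add_node(np.array([0.0, y0, box[2] / 2]))
        inlets.append(root)
        trunk_end = add_node(np.array([depth_step, y0, box[2] / 2]))
        add_seg(root, trunk_end, r0)
        frontier = [(trunk_end, r0)]
        for lvl in range(1, levels + 1):
            nxt = []
            spread = box[1] / (2.0 ** (lvl + 1.5))
            for parent, r in frontier:
                r_child = r * shrink
                for sgn in (-1.0, 1.0):
                    jitter = rng.uniform(-0.2, 0.2, size=3) * depth_step
                    p = nodes[parent] + np.array(
                        [depth_step, sgn * spread, sgn * 0.3 * spread]) + jitter
                    child = add_node(p)
                    add_seg(parent, child, r_child)
                    nxt.append((child, r_child))
            frontier = nxt
        leaf_tips.append(frontier)

    # anastomoses joining the two trees' terminal generations
    r_leaf = root_radii[0] * shrink ** levels
    n_join = max(1, len(leaf_tips[0]) // 2)
    for (a, _), (b, _) in list(zip(leaf_tips[0], leaf_tips[-1]))[:n_join]:
        add_seg(a, b, 0.8 * r_leaf)

    # outlets: push the remaining terminals to the far face
    outlets = []
    for tips in leaf_tips:
        for node, r in tips[n_join:]:
            p = nodes[node].copy()
            p[0] = box[0] - 1e-3
            out = add_node(p)
            add_seg(node, out, r)
            outlets.append(out)
    if not outlets:  # degenerate small tree: make the joined leaves outlets
        for node, r in leaf_tips[0][:1]:
            p = nodes[node].copy()
            p[0] = box[0] - 1e-3
            out = add_node(p)
            add_seg(node, out, r)
            outlets.append(out)

    return CapillaryGraph(nodes=np.array(nodes), segments=np.array(segments),
                          radii=np.array(radii), inlets=inlets,
                          outlets=outlets)


def apply_radius_modulation(graph: CapillaryGraph, factors,
                            conductance_power: float = 2.0) -> CapillaryGraph:
    """Scale segment radii and rescale K1 by the conductance law.

    Default power 2 keeps K1 ∝ R^2 (Poiseuille), so with the R^2 pi
    prefactor the segment conductance scales as R^4.
    """
    factors = np.broadcast_to(np.asarray(factors, dtype=float),
                              (graph.n_segments,))
    if np.any(factors <= 0):
        raise ValueError("radius factors must be positive")
    return CapillaryGraph(
        nodes=graph.nodes.copy(), segments=graph.segments.copy(),
        radii=graph.radii * factors,
        inlets=list(graph.inlets), outlets=list(graph.outlets),
        k1=graph.k1 * factors ** conductance_power,
        lp=graph.lp.copy(), viscosity_law=graph.viscosity_law)
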