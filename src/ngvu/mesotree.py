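"""Murray-law surrogate tree linking the macrovascular outlet to capillary inlets.

The tree is symmetric: every vessel bifurcates into two identical children
whose radii obey r_l = 2^(1/gamma) * r_{l+1}.  Only the algebraic flow
relations are modeled — the intermediate geometry (lengths, angles) is never
constructed.  The number of levels is generally non-integer and is not
rounded, because only the radius-ratio power law is used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GAMMA_MIN, GAMMA_MAX = 2.0, 3.5
GAMMA_DEFAULT = 3.0


@dataclass
class SurrogateTree:
    """Symmetric bifurcating tree between a root vessel and capillary leaves.

    Parameters
    ----------
    root_radius : float
        Radius of the feeding vessel (cm); by convention the reference
        radius of Vessel 37.
    leaf_radii : sequence of float
        Radii (cm) of the capillary inlets fed by the tree.
    gamma : float
        Murray exponent, restricted to [2, 3.5].
    root_flow : float
        Period-averaged flow (cm^3/s) entering the tree root.
    """

    root_radius: float
    leaf_radii: list = field(default_factory=list)
    gamma: float = GAMMA_DEFAULT
    root_flow: float = 0.0

    def __post_init__(self):
        if not GAMMA_MIN <= self.gamma <= GAMMA_MAX:
            raise ValueError(
                f"gamma={self.gamma} outside [{GAMMA_MIN}, {GAMMA_MAX}]")
        if self.root_radius <= 0:
            raise ValueError("root_radius must be positive")
        if any(r > self.root_radius for r in self.leaf_radii):
            raise ValueError("leaf radii must not exceed the root radius")
        if self.root_flow < 0:
            raise ValueError("root_flow must be non-negative")

    def levels(self, leaf_radius: float) -> float:
        return tree_levels(self.root_radius, leaf_radius, self.gamma)

    def leaf_flows(self) -> np.ndarray:
        return np.array([
            leaf_inflow(self.root_flow, r, self.root_radius, self.gamma)
            for r in self.leaf_radii])

    def leaf_velocities(self) -> np.ndarray:
        return np.array([
            inlet_velocity(q, r)
            for q, r in zip(self.leaf_flows(), self.leaf_radii)])


def average_period_flow(t: np.ndarray, q: np.ndarray, T: float) -> float:
    """Time-weighted mean (1/T) * int Q dt over one period.

    ``t`` must cover exactly one period [t0, t0+T] (within 1% of T).
    """
    t = np.asarray(t, dtype=float)
    q = np.asarray(q, dtype=float)
    if t.size < 2 or t.size != q.size:
        raise ValueError("need matching time/flow series with >= 2 samples")
    span = t[-1] - t[0]
    if not np.isclose(span, T, rtol=1e-2):
        raise ValueError(f"series spans {span:g} s, expected one period T={T:g} s")
    return float(np.trapezoid(q, t) / T)


def tree_levels(r0: float, rn: float, gamma: float = GAMMA_DEFAULT) -> float:
    """Number of bifurcation levels n = gamma * log2(r0/rn).

    This is the inversion of r0 = 2^(n/gamma) rn.  The result is real-valued;
    no rounding is applied.
    """
    if rn <= 0 or r0 <= 0:
        raise ValueError("radii must be positive")
    if rn > r0:
        raise ValueError("leaf radius exceeds root radius")
    return gamma * np.log2(r0 / rn)


def leaf_inflow(q0: float, r_c: float, r0: float,
                gamma: float = GAMMA_DEFAULT) -> float:
    """Flow delivered to a leaf of radius r_c: Q0 * (r_c / r0)^gamma."""
    if q0 < 0 or r_c <= 0 or r0 <= 0:
        raise ValueError("inputs must be positive (q0 >= 0)")
    return q0 * (r_c / r0) ** gamma


def distribute_outflow(q_in: float, outlet_areas) -> np.ndarray:
    """Split a total outflow over outlets proportionally to section areas."""
    areas = np.asarray(outlet_areas, dtype=float)
    if areas.size == 0:
        raise ValueError("empty outlet set")
    if np.any(areas <= 0):
        raise ValueError("outlet areas must be positive")
    flows = q_in * areas / areas.sum()
    # enforce exact conservation against floating point drift
    flows[-1] = q_in - flows[:-1].sum()
    return flows


def inlet_velocity(q: float, r: float) -> float:
    """Mean velocity Q / (pi r^2) in a circular vessel."""
    if r <= 0:
        raise ValueError("radius must be positive")
    return q / (np.pi * r * r)


def couple(q_series_t, q_series_q, T, inlet_radii, root_radius,
           gamma: float = GAMMA_DEFAULT) -> dict:
    """Full meso coupling record: averaged root flow, per-inlet flow/velocity."""
    q0 = average_period_flow(q_series_t, q_series_q, T)
    tree = SurrogateTree(root_radius=root_radius, leaf_radii=list(inlet_radii),
                         gamma=gamma, root_flow=q0)
    flows = tree.leaf_flows()
    vels = tree.leaf_velocities()
    return {
        "Q0": q0,
        "gamma": gamma,
        "root_radius": root_radius,
        "inlets": [
            {"radius": float(r), "Q": float(q), "v": float(v)}
            for r, q, v in zip(inlet_radii, flows, vels)
        ],
    }
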