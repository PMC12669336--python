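"""Vessel data structures, the elastic tube law and Windkessel outlets.

Internal computation is CGS (cm, g, s, dyn); the vessel table carries E in
Pa and pressures are reported in mmHg.  The tube law is

    P(A) = G0 (sqrt(A/A0) - 1),   G0 = sqrt(pi) h0 E / ((1 - nu^2) sqrt(A0))

with Poisson ratio nu = 1/2, and the characteristic wave speed is
c(A) = sqrt(G0/(2 rho) * sqrt(A/A0)).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from ..units import MMHG_TO_CGS, PA_TO_CGS
from ..viscosity import ConstantViscosity, ViscosityLaw

NU_POISSON = 0.5
GAMMA_PROFILE = 9.0           # velocity-profile shape parameter
RHO_DEFAULT = 1.028           # g/cm^3 (see warnings: printed value is 1e-3 x)
RHO_PRINTED = 1.028e-3
FRICTION_FACTOR = 2.0 * (GAMMA_PROFILE + 2.0)   # = 22

MAP_TARGET_MMHG = 93.0
VENOUS_MMHG = 5.0
WK_DECAY_S = 1.3


def stiffness_g0(h0_cm: float, e_pa: float, a0_cm2: float) -> float:
    """G0 in CGS (dyn/cm^2)."""
    return math.sqrt(math.pi) * h0_cm * (e_pa * PA_TO_CGS) \
        / ((1.0 - NU_POISSON ** 2) * math.sqrt(a0_cm2))


def young_laplace_pressure(a, a0, g0):
    """Tube-law pressure (same unit as g0); strictly increasing in a."""
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0) or np.any(np.asarray(a0) <= 0) or np.any(np.asarray(g0) <= 0):
        raise ValueError("areas and stiffness must be positive")
    out = g0 * (np.sqrt(a / a0) - 1.0)
    return float(out) if np.ndim(a) == 0 else out


def wave_speed(a, a0, g0, rho=RHO_DEFAULT):
    """c(A) = sqrt(G0/(2 rho) * sqrt(A/A0)) [cm/s for CGS inputs]."""
    out = np.sqrt(g0 / (2.0 * rho) * np.sqrt(np.asarray(a, dtype=float) / a0))
    return float(out) if np.ndim(a) == 0 else out


def inlet_flow(t, T, q_max):
    """Half-sine cardiac inflow: Qmax sin(pi t / 0.3T) on [0, 0.3T], else 0."""
    if q_max < 0:
        raise ValueError("Qmax must be non-negative")
    if T <= 0:
        raise ValueError("period must be positive")
    tt = np.mod(np.asarray(t, dtype=float), T)
    out = np.where(tt <= 0.3 * T,
                   q_max * np.sin(np.pi * tt / (0.3 * T)), 0.0)
    out = np.maximum(out, 0.0)  # guard the sin tail at exactly 0.3T
    return float(out) if np.ndim(t) == 0 else out


@dataclass
class Vessel1D:
    id: int
    length: float            # cm
    r0: float                # cm
    h0: float                # cm
    e_pa: float              # Pa
    n_cells: int = 2
    name: str = ""
    source: str = "literature"

    def __post_init__(self):
        if min(self.length, self.r0, self.h0, self.e_pa) <= 0:
            raise ValueError(f"vessel {self.id}: non-positive geometry")
        if self.n_cells < 2:
            raise ValueError(f"vessel {self.id}: n_cells must be >= 2")
        self.a0 = math.pi * self.r0 ** 2
        self.g0 = stiffness_g0(self.h0, self.e_pa, self.a0)

    @property
    def dz(self) -> float:
        return self.length / self.n_cells


@dataclass
class Windkessel0D:
    """RCR outlet: proximal R1, compliance C, distal R2 (CGS units)."""
    r1: float
    r2: float
    c: float
    state_pressure: float = VENOUS_MMHG * MMHG_TO_CGS
    venous_pressure: float = VENOUS_MMHG * MMHG_TO_CGS

    def __post_init__(self):
        if min(self.r1, self.r2, self.c) <= 0:
            raise ValueError("Windkessel parameters must be positive")


def windkessel_update(q_out: float, wk: Windkessel0D, dt: float) -> float:
    """Advance the RC state one step; return the 1D outlet pressure (CGS).

    dPc/dt = (Q - (Pc - Pven)/R2) / C;  P_outlet = Pc + Q R1.
    """
    pc = wk.state_pressure
    pc += dt / wk.c * (q_out - (pc - wk.venous_pressure) / wk.r2)
    wk.state_pressure = pc
    return pc + q_out * wk.r1


@dataclass
class ArterialNetwork1D:
    vessels: dict                      # id -> Vessel1D
    junctions: list                    # list of (parent_ids, child_ids)
    inlet_vessel: int = 1
    outlet_ids: list = field(default_factory=list)
    outlets: dict = field(default_factory=dict)   # id -> Windkessel0D
    rho: float = RHO_DEFAULT
    gamma_profile: float = GAMMA_PROFILE
    viscosity_law: ViscosityLaw = field(default_factory=ConstantViscosity)
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        if self.inlet_vessel not in self.vessels:
            raise ValueError("inlet vessel missing from table")
        if abs(self.rho - RHO_PRINTED) < 1e-12:
            self.warnings.append(
                "rho = 1.028e-3 g/cm^3 is dimensionally implausible for "
                "blood in CGS; the default is 1.028 g/cm^3")
        self._validate_topology()

    def _validate_topology(self):
        outlet_ids = set(self.outlet_ids) | set(self.outlets)
        seen_ends, seen_starts = set(), set()
        for parents, children in self.junctions:
            if len(parents) + len(children) < 2:
                raise ValueError("junction with < 2 vessel ends")
            for p in parents:
                if p in seen_ends:
                    raise ValueError(f"vessel {p} distal end in two junctions")
                seen_ends.add(p)
            for c in children:
                if c in seen_starts:
                    raise ValueError(f"vessel {c} start in two junctions")
                seen_starts.add(c)
        for vid in self.vessels:
            is_outlet = vid in outlet_ids
            if vid != self.inlet_vessel and vid not in seen_starts:
                raise ValueError(f"vessel {vid} has no feeding junction")
            if not is_outlet and vid not in seen_ends:
                raise ValueError(f"non-outlet vessel {vid} end unconnected")
        # connectivity
        adj = {}
        for parents, children in self.junctions:
            group = list(parents) + list(children)
            for a in group:
                adj.setdefault(a, set()).update(g for g in group if g != a)
        stack, seen = [self.inlet_vessel], {self.inlet_vessel}
        while stack:
            for nb in adj.get(stack.pop(), ()):
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if seen != set(self.vessels):
            raise ValueError("network graph is not connected")


def _parse_ids(cell) -> list:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return []
    cell = str(cell).strip()
    return [int(v) for v in cell.split(";") if v.strip()] if cell else []


def load_vessel_table(path_or_buf, dz_target: float = 0.5,
                      rho: float = RHO_DEFAULT,
                      viscosity_law: ViscosityLaw | None = None,
                      ) -> ArterialNetwork1D:
    """Build a network from the CSV table.

    Columns: id, parent_ids, child_ids (';'-separated), L_cm, R0_cm, h0_cm,
    E_Pa, outlet_flag; optional name, source.  ``dz_target`` controls the
    spatial resolution (n_cells = max(2, round(L/dz_target))).
    """
    df = pd.read_csv(path_or_buf)
    vessels, child_map, parent_map, outlets = {}, {}, {}, []
    for _, row in df.iterrows():
        vid = int(row["id"])
        vessels[vid] = Vessel1D(
            id=vid, length=float(row["L_cm"]), r0=float(row["R0_cm"]),
            h0=float(row["h0_cm"]), e_pa=float(row["E_Pa"]),
            n_cells=max(2, round(float(row["L_cm"]) / dz_target)),
            name=str(row.get("name", "")),
            source=str(row.get("source", "literature")))
        child_map[vid] = _parse_ids(row.get("child_ids"))
        parent_map[vid] = _parse_ids(row.get("parent_ids"))
        if int(row.get("outlet_flag", 0)):
            outlets.append(vid)

    # cross-check parent/child mirrors
    for vid, children in child_map.items():
        for c in children:
            if vid not in parent_map.get(c, []):
                raise ValueError(f"table inconsistency: {vid}->{c} not mirrored")

    # junctions = connected components of the parent-end/child-start relation
    links = {}
    for vid, children in child_map.items():
        for c in children:
            links.setdefault(("end", vid), set()).add(("start", c))
            links.setdefault(("start", c), set()).add(("end", vid))
    seen, junctions = set(), []
    for key in links:
        if key in seen:
            continue
        stack, comp = [key], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(links[k])
        seen |= comp
        parents = sorted(v for kind, v in comp if kind == "end")
        children = sorted(v for kind, v in comp if kind == "start")
        junctions.append((parents, children))

    net = ArterialNetwork1D(
        vessels=vessels, junctions=junctions, inlet_vessel=1,
        outlet_ids=outlets, outlets={}, rho=rho,
        viscosity_law=viscosity_law or ConstantViscosity())
    calibrate_windkessels(net, outlet_ids=outlets)
    return net


def default_network(**kwargs) -> ArterialNetwork1D:
    """The bundled 37-vessel table (literature values + the printed Table)."""
    data = resources.files("ngvu.net1d").joinpath("data/vessels37.csv")
    return load_vessel_table(io.StringIO(data.read_text()), **kwargs)


def calibrate_windkessels(net: ArterialNetwork1D, outlet_ids,
                          q_max: float = 485.0, T: float = 1.0,
                          map_target_mmhg: float = MAP_TARGET_MMHG,
                          venous_mmhg: float = VENOUS_MMHG,
                          decay_s: float = WK_DECAY_S) -> None:
    """Calibrate RCR outlets.

    Total peripheral resistance from the target mean aortic pressure and
    the mean of the half-sine inflow; distributed over outlets by
    outlet-area weighting; R1 set to the characteristic impedance
    rho c(A0)/A0; C from the configured pressure-decay time.
    """
    q_mean = 0.3 * 2.0 / math.pi * q_max      # time average of Eq-5 inflow
    dp = (map_target_mmhg - venous_mmhg) * MMHG_TO_CGS
    r_total = dp / q_mean
    areas = {vid: net.vessels[vid].a0 for vid in outlet_ids}
    a_sum = sum(areas.values())
    net.outlets = {}
    for vid in outlet_ids:
        v = net.vessels[vid]
        r_i = r_total * a_sum / areas[vid]
        z_c = net.rho * wave_speed(v.a0, v.a0, v.g0, net.rho) / v.a0
        r1 = min(z_c, 0.2 * r_i)
        r2 = r_i - r1
        net.outlets[vid] = Windkessel0D(
            r1=r1, r2=r2, c=decay_s / r2,
            state_pressure=0.9 * map_target_mmhg * MMHG_TO_CGS,
            venous_pressure=venous_mmhg * MMHG_TO_CGS)
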