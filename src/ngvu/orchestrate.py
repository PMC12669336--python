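"""Workflow orchestration: macro -> meso -> per-beat cellular/micro loop.

Sequence per run: (1) the 1D-0D macrovascular model is beaten to a periodic
state once and its period-averaged vessel-37 outlet flow feeds the
surrogate-tree coupling; (2) per heartbeat, the 0D cellular chain (synapse
+ NVC wall) advances continuously, the beat-end radius modulates the
capillary radii, and the stationary 3D-1D pressure/velocity problem is
re-solved (quasi-static); transport advances over the beat.  Coupling is
one-way macro -> micro.  A manifest records seeds, parameter provenance,
warnings and per-stage timings, and is written before any stage output.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np

from . import mesotree
from .export import (write_timeseries_csv, write_vtk_polylines,
                     write_vtk_structured)
from .micro3d1d import (TissueDomain, apply_radius_modulation,
                        compute_velocities, generate_synthetic_network,
                        read_capillary_network, solve_pressure_3d1d,
                        solve_transport, TransportState)
from .net1d import default_network, load_vessel_table, run_to_periodicity
from .nvc import NVCSimulator, drive_from_synapse
from .synapse import QuadripartiteSynapse

CM3_TO_UM3 = 1.0e12

DEFAULT_CONFIG = {
    "seed": 0,
    "T": 1.0,
    "Qmax": 485.0,
    "n_beats": 3,
    "gamma": 3.0,
    "root_vessel_id": 37,
    "n_inlets": 2,
    "grid": [12, 12, 12],
    "levels": 3,
    "gauge_mmHg": 30.0,
    "macro": {"enabled": False, "tol": 1e-3, "beats_max": 30,
              "dz_target": 0.5, "vessels_csv": None},
    "Q0_override": 0.46,
    "radius_feedback": True,
    "network_file": None,
    "outdir": "ngvu_out",
    "overrides": {},
}


def _merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in (extra or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) \
            and isinstance(base.get(k), dict) else v
    return out


def select_inlets(graph, n_inlets: int = 2):
    """Boundary vessels with the largest radii (deterministic id tie-break).

    Returns [(node_id, radius_um), ...] sorted by decreasing radius.
    """
    boundary = set(graph.boundary_nodes()) | set(graph.inlets)
    cand = []
    for s, (a, b) in enumerate(graph.segments):
        for n in (a, b):
            if n in boundary:
                cand.append((-graph.radii[s], n))
    cand.sort()
    picked, seen = [], set()
    for neg_r, n in cand:
        if n not in seen:
            picked.append((n, -neg_r))
            seen.add(n)
        if len(picked) == n_inlets:
            break
    return picked


def run_full_simulation(config: dict | None = None) -> dict:
    cfg = _merge(DEFAULT_CONFIG, config or {})
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": cfg, "seed": cfg["seed"], "stages": {}, "warnings": [],
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.time()
                return self

            def __exit__(self, et, ev, tb):
                manifest["stages"][name] = {
                    "seconds": round(time.time() - self.t0, 3),
                    "failed": et is not None}
                manifest_path.write_text(
                    json.dumps(manifest, indent=2, default=str))
                return False
        return _T()

    # ---- macro stage -------------------------------------------------
    with stage("macro"):
        mc = cfg["macro"]
        if mc["enabled"]:
            net = (load_vessel_table(mc["vessels_csv"],
                                     dz_target=mc["dz_target"])
                   if mc["vessels_csv"] else
                   default_network(dz_target=mc["dz_target"]))
            manifest["warnings"] += net.warnings
            manifest["viscosity_law"] = net.viscosity_law.name
            res = run_to_periodicity(net, T=cfg["T"], q_max=cfg["Qmax"],
                                     tol=mc["tol"], beats_max=mc["beats_max"])
            s37 = res.series(cfg["root_vessel_id"], 1.0)
            q0 = mesotree.average_period_flow(res.t, s37["Q"], cfg["T"])
            write_timeseries_csv(
                {"t_s": res.t, "Q_cm3s": s37["Q"], "P_mmHg": s37["P_mmHg"]},
                outdir / "macro_outlet37.csv")
            root_r0 = net.vessels[cfg["root_vessel_id"]].r0
        else:
            q0 = cfg["Q0_override"]
            root_r0 = 0.08
            manifest["warnings"].append(
                "macro stage disabled; using configured Q0")
    manifest["Q0_cm3s"] = q0

    # ---- capillary network ------------------------------------------
    with stage("network"):
        if cfg["network_file"]:
            graph = read_capillary_network(cfg["network_file"])
        else:
            graph = generate_synthetic_network(
                seed=cfg["seed"], levels=cfg["levels"], gamma=cfg["gamma"])
        tissue = TissueDomain(shape=tuple(cfg["grid"]),
                              gauge_mmhg=cfg["gauge_mmHg"])

    # ---- meso coupling ----------------------------------------------
    with stage("meso"):
        inlets = select_inlets(graph, cfg["n_inlets"])
        inlet_radii_cm = [r * 1e-4 for _, r in inlets]
        flows = [mesotree.leaf_inflow(q0, rc, root_r0, cfg["gamma"])
                 for rc in inlet_radii_cm]
        meso = {
            "Q0": q0, "gamma": cfg["gamma"], "root_radius_cm": root_r0,
            "inlets": [
                {"node": int(n), "radius_cm": rc, "Q_cm3s": q,
                 "v_cms": mesotree.inlet_velocity(q, rc)}
                for (n, _), rc, q in zip(inlets, inlet_radii_cm, flows)],
        }
        (outdir / "meso.json").write_text(json.dumps(meso, indent=2))

    # ---- per-beat cellular + micro loop ------------------------------
    with stage("beats"):
        inlet_nodes = [n for n, _ in inlets]
        inflow_um3 = {n: q * CM3_TO_UM3 for n, q
                      in zip(inlet_nodes, flows)}
        q_total = sum(inflow_um3.values())
        out_areas = []
        for n in graph.outlets:
            segs = [s for s, (a, b) in enumerate(graph.segments)
                    if n in (a, b)]
            out_areas.append(graph.radii[segs[0]] ** 2)
        out_flows = mesotree.distribute_outflow(q_total, out_areas)
        outlet_um3 = dict(zip(graph.outlets, out_flows))

        syn = QuadripartiteSynapse(seed=cfg["seed"],
                                   overrides=cfg["overrides"].get("synapse"))
        nvc = NVCSimulator(overrides=cfg["overrides"].get("nvc"))
        transport = TransportState(
            c1=np.full(graph.n_nodes, 1.0),
            c3=np.zeros(tuple(cfg["grid"])))
        r_baseline = None
        beat_rows = []
        for beat in range(cfg["n_beats"]):
            cell = syn.run(cfg["T"], record_every_ms=5.0)
            nvc_out = nvc.run(drive_from_synapse(cell), record_every=5e-2)
            radius = float(nvc_out["R_um"][-1])
            if r_baseline is None:
                r_baseline = radius
            factor = radius / r_baseline if cfg["radius_feedback"] else 1.0
            mod = apply_radius_modulation(graph, factor)
            sol = solve_pressure_3d1d(mod, tissue, inflow_um3, outlet_um3)
            v_c, v_om = compute_velocities(sol)
            dt_t = 0.5 * float(np.min(mod.lengths)
                               / max(np.abs(v_c).max(), 1e-12))
            n_tr = max(1, min(50, int(cfg["T"] / dt_t)))
            transport = solve_transport(
                transport, mod, tissue, v_c, v_om, dt=cfg["T"] / n_tr
                if cfg["T"] / n_tr < dt_t else dt_t, n_steps=n_tr,
                inlet_flows=inflow_um3, outlet_flows=outlet_um3,
                inlet_conc=1.0)
            inlet_seg = [s for s, (a, b) in enumerate(graph.segments)
                         if inlet_nodes[0] in (a, b)][0]
            beat_rows.append({
                "beat": beat, "R_um": radius, "factor": factor,
                "v_inlet_um_s": float(abs(v_c[inlet_seg])),
                "Fr": float(nvc_out["Fr"][-1]),
                "c_a_uM": float(cell["c_a_uM"][-1]),
                "p1_mean_mmHg": float(np.mean(sol.p1)),
            })
        write_timeseries_csv(
            {k: np.array([r[k] for r in beat_rows]) for k in beat_rows[0]},
            outdir / "beats.csv")

    # ---- exports ----------------------------------------------------
    with stage("export"):
        export_fields({"p3": sol.p3, "c3": transport.c3, "tissue": tissue,
                       "graph": graph, "p1": sol.p1, "c1": transport.c1,
                       "v_c": v_c}, "vtk", outdir)
        manifest["field_ranges"] = {
            "p3_mmHg": [float(sol.p3.min()), float(sol.p3.max())],
            "p1_mmHg": [float(sol.p1.min()), float(sol.p1.max())],
            "c3": [float(transport.c3.min()), float(transport.c3.max())],
        }
        write_timeseries_csv(
            {k: cell[k] for k in ("t_s", "V_pre_mV", "c_i_uM", "c_ER_uM",
                                  "p_uM", "g_uM", "g_a_uM", "c_a_uM",
                                  "p_a_uM", "PSP_mV")},
            outdir / "cell_lastbeat.csv")
        write_timeseries_csv(
            {k: nvc_out[k] for k in ("t_s", "Ca_SMC_uM", "Ca_EC_uM",
                                     "IP3_SMC_uM", "IP3_EC_uM", "Fr",
                                     "R_um", "NO_s_uM", "cGMP_uM")},
            outdir / "nvc_lastbeat.csv")

    manifest["beats"] = beat_rows
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return {"manifest": manifest, "outdir": str(outdir), "meso": meso,
            "beats": beat_rows}


def export_fields(results: dict, fmt: str, outdir) -> list:
    """Write tissue/network fields; returns the list of files written."""
    outdir = Path(outdir)
    if fmt not in ("vtk", "csv"):
        raise ValueError(f"unknown format {fmt!r}; supported: vtk, csv")
    written = []
    tissue = results["tissue"]
    graph = results["graph"]
    if fmt == "vtk":
        for name in ("p3", "c3"):
            path = outdir / f"{name}.vtk"
            write_vtk_structured(results[name], tissue.spacing, path, name)
            written.append(path)
        seg_vals = {"radius_um": graph.radii}
        if "v_c" in results:
            seg_vals["v_c_um_s"] = results["v_c"]
        path = outdir / "network.vtk"
        write_vtk_polylines(graph.nodes, graph.segments, seg_vals, path)
        written.append(path)
    else:
        for name in ("p1", "c1"):
            path = outdir / f"{name}.csv"
            write_timeseries_csv({"node": np.arange(graph.n_nodes),
                                  name: results[name]}, path)
            written.append(path)
    return [str(p) for p in written]


def cellular_baseline(seed: int = 0, t_end: float = 60.0,
                      overrides: dict | None = None) -> dict:
    """One coupled synapse+NVC run; returns the NVC output dict."""
    ov = overrides or {}
    syn = QuadripartiteSynapse(seed=seed, overrides=ov.get("synapse"))
    cell = syn.run(t_end, record_every_ms=2.0)
    nvc = NVCSimulator(overrides=ov.get("nvc"))
    out = nvc.run(drive_from_synapse(cell), record_every=1e-2,
                  warm_start=True)
    out["_cell"] = cell
    return out


def make_wall_runner(nvc_out: dict, dt: float = 1.0e-3,
                     overrides: dict | None = None):
    """Sensitivity model runner over the wall parameters (dp, E_act, E_pas).

    Freezes the neuro-glial drive F_r(t) from a baseline coupled run and
    re-integrates only the Kelvin-Voigt radius ODE per parameter sample
    (the probed parameters enter the wall law only; damping eta is held
    fixed).  Returns (runner, baseline_params).
    """
    from .nvc import load_nvc_params
    from .nvc.simulate import wall_radius_trace

    p = load_nvc_params(overrides=overrides)
    t_fr = nvc_out["t_s"]
    fr = nvc_out["Fr"]
    t_end = float(t_fr[-1])
    scale = (t_fr.size - 1) / t_end

    def fr_of_t(t):
        return float(fr[min(int(t * scale), fr.size - 1)])

    baseline = {"dp": p.dp_wall, "E_act": p.E_act, "E_pas": p.E_pas}

    def runner(params: dict):
        wp = {"dp": params.get("dp", p.dp_wall),
              "eta": p.eta_wall,
              "e_act": params.get("E_act", p.E_act),
              "e_pas": params.get("E_pas", p.E_pas),
              "r0_act": p.R0_act, "r0_pas": p.R0_pas}
        t, r = wall_radius_trace(t_end, dt, fr_of_t, wp)
        return t, r

    return runner, baseline
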