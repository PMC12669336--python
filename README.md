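# ngvu — multiscale neuro-glial-vascular unit simulator

`ngvu` couples three scales of the cerebral circulation into one workflow:

* **net1d** — nonlinear 1D blood flow on a 37-vessel arterial network
  (aorta → circle of Willis → vertebral/PICA branches) with a half-sine
  cardiac inflow, total-pressure/mass-conserving junction coupling and
  calibrated RCR Windkessel outlets, run from rest to a periodic state.
* **mesotree** — a symmetric Murray-law surrogate tree that converts the
  period-averaged outlet flow of the feeding vessel into capillary inlet
  flows and velocities.
* **micro3d1d** — a stationary 3D-1D coupled pressure solve on a capillary
  centerline graph embedded in a tissue box (wall exchange assembled as a
  symmetric sparse system), velocity extraction and upwind/implicit
  advection-diffusion solute transport; includes a documented ASCII network
  format and a deterministic synthetic network generator.
* **synapse** — a 0D quadripartite synapse: Hodgkin-Huxley presynaptic
  spiking (Glu and GABA neurons), bouton fast/slow calcium with a dynamic
  ER pool, an exact-SSA five-site vesicle sensor, Tsodyks-Markram vesicle
  pools with transmitter-specific refractory windows, cleft/extrasynaptic
  transmitter concentrations, and a stochastic astrocyte (Li-Rinzel-type
  calcium + IP3 metabolism, channel-noise gating, three-gate
  gliotransmitter release).
* **nvc** — neurovascular coupling from the cellular signals to vessel
  radius: KIR input, SMC/EC compartments with gap-junction coupling,
  four-state cross-bridge kinetics with cGMP-modulated dephosphorylation,
  a Kelvin-Voigt viscoelastic wall, and the NO production/diffusion/
  scavenging/cGMP pathway.
* **sensitivity** — post-transient radius metrics, one-at-a-time sweeps,
  Latin hypercube sampling with partial rank correlation coefficients and
  symmetric local elasticities.
* **orchestrate / cli** — the full workflow (macro → meso → per-beat
  cellular advance with radius feedback → micro re-solve → exports) with
  a JSON manifest, tidy CSV time series and legacy-ASCII VTK fields.

Parameters live in provenance-tagged YAML registries
(`src/ngvu/synapse/params/`, `src/ngvu/nvc/params/`): every entry records
value, units and source (`paper` / `literature` / `calibrated`); several
rates are re-calibrated at startup so the resting state is a fixed point.
The 37-vessel table ships as an editable CSV with per-row provenance
(`src/ngvu/net1d/data/vessels37.csv`).

## Command line

```sh
ngvu macro --t 1.0 --qmax 485 --tol 1e-3 --probe 37:1.0 --out macro.csv
ngvu meso  --q0 0.46 --inlet-radii 4.5e-4,4.0e-4
ngvu micro --grid 20,20,20 --gauge-mmhg 30 --outdir micro_out
ngvu cell  --t-end 10 --seed 1 --out cell.csv
ngvu sens  --mode lhs --n 200 --seed 42 --out sens.csv
ngvu run   --config run.yaml       # full workflow; see ngvu.orchestrate
```

`ngvu run` accepts a YAML config mirroring
`ngvu.orchestrate.DEFAULT_CONFIG` (beat period, heartbeat count, grid,
synthetic-network depth, seed, per-module `overrides`, and an optional
`macro: {enabled: true}` block to derive the coupling flow from the full
1D-0D simulation instead of the configured value).

## Capillary network ASCII format

```
<n_nodes> <n_segments>
<node_id> <x_um> <y_um> <z_um>        # one line per node
<seg_id> <node1> <node2> <radius_um>  # one line per segment
INLET <node_id>
OUTLET <node_id>
```

`#` starts a comment; ids are 0-based and contiguous; segment lengths are
the Euclidean node distances.
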