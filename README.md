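# cerebdev

Agent-based simulation of early cerebellar development: granule cell
migration along Bergmann glia, parallel fiber growth, Purkinje dendritic
tree growth, and competing rules for selecting the single primary
dendritic tree.

## The problem

During the first two postnatal weeks, a mouse Purkinje cell grows several
dendritic trees and then retracts all but one.  Which tree wins, and what
information drives the choice — a fixed developmental clock, tree size,
synapse count, or afferent network activity?  Direct observation is
nearly impossible because the presynaptic partners, the granule cells, are
migrating en masse through the same volume at the same time.  `cerebdev`
rebuilds this system *in silico* for researchers in developmental and
computational neuroscience who want to compare selection rules under a
shared, physically constrained growth environment.

## The model

Everything is made of *fronts* — spheres (somata) and short cylinders
(neurites) — growing in discrete cycles (1 cycle ≈ 2.2 h, cycle = 10 ×
postnatal day) inside a fixed 3D volume, under a hard no-overlap
constraint: a front is only created where its capsule does not intersect
any other.  The simulation layers, in order: a Bergmann glia scaffold
(radial processes climbing to z = 131 μm); granule cells born in 12
bottom-to-top phases that migrate horizontally to a glia process, then
descend along it to the internal granular layer (z ≤ −15 μm), leaving a
descending axon that bifurcates into two parallel-fiber branches running
±y (a T-junction); and Purkinje cells that activate at cycle 65, grow five
dendritic roots, and extend tips toward nearby synapse-free parallel
fibers, continuing perpendicular to each contacted fiber — which is what
flattens the mature tree into the plane orthogonal to the fibers.  Granule
cells fire at uniform 0–0.2 events/cycle while migrating and 0–10 after
arrival; each tree integrates Σ presynaptic rates per cycle as its input
signal.

Seven scenarios decide the winner tree: three controls (**RandomRetract**,
**NoRetract**, **NoGranCells** — growth in an empty volume) and four
two-phase retraction rules triggered by fixed cycles (**FixedRetract**),
total front count (**SizeRetract**), total synapse count
(**SynapseRetract**) or integrated signal (**InputRetract**), each keeping
the trees that rank highest on its metric.

See `docs/methods.md` for the full rule set, parameters and limitations.

## Worked example

`examples/03_tree_selection.py` runs one desk-scale SizeRetract simulation
(reduced volume, every mechanism intact) and prints each cell's retraction
history and the winner morphometrics:

```
  cell  8 cycle  87 first  retracted trees [0, 4] (front counts {0: 16, 1: 109, 2: 127, 3: 47, 4: 8})
  cell  8 cycle  96 winner retracted trees [1, 3] (front counts {1: 171, 2: 175, 3: 61})
  ...
winner trees: {'Zero': 0, 'One': 6, 'Two': 0, 'More than 2': 0}
mean winner fronts      : 391.8
mean winner synapses    : 14.0
mean winner max path    : 275.7 um
mean winner x/y extent  : 44.3 / 33.7 um (narrow y = the flat plane perpendicular to the parallel fibers)
```

Reading: cell 8 crossed the 300-front total at cycle 87 and shed its two
runt trees (16 and 8 fronts), then crossed 400 at cycle 96 and kept the
largest (175 fronts).  All six analyzed cells end with exactly one primary
tree, and winner trees are narrower along y (the fiber axis) than along x
— the planar shape the real cells acquire.  The other examples cover the
growth engine (`01`), granule migration bookkeeping (`02`) and the
morphometrics/statistics toolkit (`04`).

Programmatic use follows the same shape:

```python
from cerebdev import Simulation, desk_config, scenario_summary
sim = Simulation(desk_config("SynapseRetract", seed=1)).run()
print(scenario_summary(sim))
```

A thin CLI wraps the same calls: `cerebdev run --scenario size --preset
desk --seed 1 --out runs/size1`, plus `cerebdev sweep` for threshold
matrices and `cerebdev analyze` for aggregating finished runs.  Outputs
are SWC morphologies per analyzed cell, CSVs (per-tree metrics, migration
report, retraction events) and a JSON summary.

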