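# Methods

`cerebdev` simulates the first two postnatal weeks (P1–P14) of a small
patch of murine cerebellar cortex as an agent-based growth model, and uses
it to compare rules by which a Purkinje cell selects its single primary
dendritic tree.  This note documents the model, its assumptions, the
parameters that matter, and the limits of what the simulations show.

## The front-based growth model

Every structure is built from *fronts*: spheres (somata, stationary fiber
sources) and short cylinders (all neurites).  Development proceeds in
discrete cycles; one cycle corresponds to ≈2.2 h, so cycle = 10 × postnatal
day and a run of 140 cycles spans P0–P14.  Each cycle, active fronts may
extend (one child), branch (two children) or terminate.  The central
constraint is *space*: a new front is only created where its capsule does
not overlap any coexisting front (axis-to-axis distance ≥ sum of radii
minus a 0.01 μm tolerance; parent–child and branching siblings touching at
their shared endpoint are exempt).  Overlap is tested against a uniform
10 μm voxel grid index; the all-pairs audit in the test-suite confirms the
index misses nothing.

Geometry: x is the sagittal plane, y the long axis of the folium (the
direction parallel fibers run), z the cortical depth.  The main volume is
(−20,−20,−20)–(180,160,140) μm at full scale, flanked by two y-wings
(total (−20,−160,−20)–(180,300,140)) from which foreign parallel fibers
grow in.  The volume is fixed: tissue expansion is not modeled, and the
upward birth schedule below is its proxy.

Blocked moves use two bounded searches rather than failing outright:

* `solve_collision` — for migrating somata: candidate positions on rings
  around the blocked direction (20 probes), accepted only if collision-free
  and closer to the goal.  Soma moves are swept-sphere checks: the entire
  path from old to new center must be clear, not just the endpoint.
* `alternate_location` — for fiber and dendrite extensions: lateral
  displacements around the intended heading, capped per structure type
  (2 μm for leading processes and dendrites; 0.4 μm for parallel fibers so
  each fiber front stays within ~5° of the y-axis).

## Bergmann glia

Each glia soma (radius 5 μm, z = 0 plane) grows seven root processes
(radius 0.8 μm, 4 μm long) fanned ±60° in the x–z plane, which then climb
in 4 μm steps, steering into vertical lanes offset along x, until z =
131 μm (the molecular-layer width at ~P11), reached by cycle 35.  Glia grow
first, so their placement is uncontested.  Lane offsets tile the glia
grid spacing so neighboring scaffolds never overlap.  Glia are placed on an
interleaved grid between Purkinje somata — (nx−1)×(ny−1) cells — which
keeps every granule birth position within 30 μm of a process.

## Granule cells

About 250 cells per phase (full scale) are born in 12 consecutive phases,
phase k starting at cycle 10k + 5 (anchored so phase 6 begins at cycle 65)
in an 11 μm z-band: phase 1 at the bottom (z 0–11), phase 12 at the top
(z 121–132).  Bottom-to-top birth emulates the molecular layer expanding
under the external granular layer.  Each cell:

1. targets the horizontally nearest glia process and migrates toward it at
   4 μm/cycle by extending a leading process; the soma follows one front
   behind, absorbing the leading fronts it passes;
2. on contact (surface gap ≤ 2 μm) turns downward, planting a short
   trailing axon whose distal end becomes the T-junction;
3. descends at 5 μm/cycle hugging the glia process — the soma may slide to
   any azimuth around the process but keeps its surface within the 3 μm
   tether — depositing one descending-axon front per step; below the soma
   layer (z < 14 μm, where the glial guide ends) it steers into the gaps
   between the large Purkinje and glia somata; arrival is z ≤ −15 μm (the
   internal granular layer);
4. the trailing axon bifurcates into two parallel-fiber branches running
   ±y (5 μm/cycle, per-branch cap 150 μm so a fiber never exceeds the
   300 μm the volume allows); a side that cannot be placed after lifting
   the junction a few μm over ≤5 cycles leaves a single-branch fiber and a
   failed T-junction.

A cell blocked for 3 consecutive cycles fails permanently and remains in
place as an obstacle.  Partial failure is a *feature* of the regime: the
crowded fiber mat makes some migrations genuinely impossible, and the
reported success rates quantify it.  The migrating soma radius is 1.2 μm,
standing in for the real cell's ability to squeeze through narrow gaps
(physical deformation is outside the model); with substantially larger
values the accumulated fiber mat becomes impassable and migration collapses
entirely rather than partially.

Firing rates are redrawn each cycle: uniform 0–0.2 events/cycle before
arrival, 0–10 after; failed cells keep the low range.  Ingrowing fiber
sources (850/phase at full scale, placed in the wings in the same z-band)
grow a single fiber toward and through the main volume and switch to the
high rate at a per-fiber arrival cycle mimicking the migration their cell
would have had.

## Purkinje cells

Somata (radius 7 μm) sit on a grid in the z = 0 plane; the inner block
(6×4 = 24 cells at full scale) is analyzed, border cells only contribute
dendritic repulsion.  At cycle 65 each soma grows five dendritic roots on
its upper hemisphere (~72° apart in azimuth).  Each cycle, every dendritic
tip:

* seeks the nearest synapse-free parallel-fiber front within 10 μm and
  grows toward it (5 ± 0.5 μm steps);
* on contact (≤1.5 μm) forms a synapse — at most one per front on either
  side — and continues perpendicular to the fiber's axis (y-component of
  the heading suppressed), the mechanism that flattens trees into the x–z
  plane;
* without a target, drifts along its heading with a small upward bias
  (weight 0.08) plus directional noise (weight 0.45);
* is repelled along y from the nearest dendrite front of any *other* tree
  (own or foreign, same kernel) with strength exp(−|Δy|/5 μm);
* branches at random with probability 0.05/tip/cycle, or toward its target
  fiber when the target direction deviates >60° from the heading;
* terminates at z ≥ 100 μm or after 3 blocked cycles; a living tree whose
  tips are all exhausted may re-activate up to three dormant terminals.

Simultaneous tips per tree are capped (40 full scale, 10 desk) as a
resource constraint; it bounds growth rate, not final size.  Per-tree
synaptic input is integrated as a plain running sum of presynaptic firing
rates, with no decay; selection thresholds are scaled to that definition.

The bias/noise/branching constants are code-level parameters chosen to
produce sustained, wandering, branching growth — trees of order a few
hundred fronts at desk scale with ~5 μm fronts — rather than straight
races to the ceiling; all are exposed in the run config.

## Selection scenarios

All scenarios share the two-phase structure observed in vivo: prune the
five candidates to ~2, then select the single winner.

| scenario | trigger | metric | defaults (full scale) |
|---|---|---|---|
| RandomRetract | cycle 72 | uniform random | — |
| NoRetract | never | — | — |
| NoGranCells | cycles 30 / 37 | tree front count | 250 / 60 / 400 |
| FixedRetract | cycles 90 / 97 | synapse count (keep 2, then 1) | — |
| SizeRetract | total-front thresholds | tree front count | 300 / 20 / 400 |
| SynapseRetract | total-synapse thresholds | tree synapse count | 90 / 30 / 180 |
| InputRetract | integrated-signal thresholds | per-tree signal | 500 / 1200 |

Ties keep all tied trees (hence occasional two-winner cells); a first phase
where every tree is below the tree threshold retracts them all (zero-winner
cells); cells that never reach a threshold never retract.  NoGranCells
grows in an empty volume with activation at cycle 5 and no synapses.

## Presets and scaling

The `full` preset is the published problem size (~3,000 granule cells,
~10,000 ingrowing fibers, 48 Purkinje cells); a single run is hours of
one-CPU compute.  The `desk` preset preserves every mechanism at
interactive cost: 100×90 μm footprint with ±70 μm wings, 24 granule cells
and 60 ingrowing fibers per phase, 5×4 Purkinje grid (6 analyzed), 10 tips
per tree.  Threshold-type scenario parameters scale with the desk volume's
smaller trees and sparser fiber supply (NoGranCells 100/20/130,
SynapseRetract 8/3/16, InputRetract 300/900; SizeRetract is reachable
unchanged), calibrated once so both retraction phases trigger inside the
simulated window as they do at full scale.  Fixed-cycle parameters are
unchanged.  The test-suite's scenario comparisons run the desk preset for
130 cycles (≈P13) with five seeds per condition.

What desk runs do and do not show: they exercise every rule —
non-overlap, guided migration, T-junctions, fiber extension, targeted
growth, synapse uniqueness, two-phase selection — and reproduce the model's
qualitative findings (fiber-induced planarity, informed selection beating
random selection, signal-based selection penalized by input
heterogeneity).  They do not reproduce the full-scale magnitudes: a desk
winner tree carries tens of synapses, not hundreds, and the desk radial
success rate (~0.4–0.6) sits below the full-scale ~0.8 — partly because
late-phase cells cannot reach the granular layer before the run ends
(phase 12 is born at cycle 125 with a ≥26-cycle descent ahead of it) and
partly because the desk mat is proportionally denser around each glia
lane.

## Numerical choices

* Collision tolerance 0.01 μm; grid voxel 10 μm; distance kernels are
  numba-compiled with a pure-numpy fallback.
* Determinism: every cell owns an RNG substream seeded by
  `(run_seed, neuron_id)` and cells are processed in id order, so results
  are independent of any incidental iteration reordering; identical
  (config, seed) gives byte-identical outputs.
* Ties (nearest glia process, nearest free fiber, equal selection metrics)
  break to the lowest front id / keep all tied trees.
* Checkpoints are versioned binary snapshots of the full scene (fronts,
  synapses, cell states, RNG states); a saved migration stage can seed
  several scenarios, which then share the identical environment up to the
  save point.
* Sample statistics use the n−1 standard deviation; pairwise comparisons
  use Welch's t-test with Welch–Satterthwaite degrees of freedom; the
  dendrite/fiber volume correlation is Pearson's r on per-cell summed
  cylinder volumes, fiber fronts clipped to the cell's bounding box
  (z restricted to 17–100 μm).

## Known limitations

No tissue expansion, front diameters fixed for life, no inhibitory
interneurons, climbing or mossy fibers, no granule proliferation or zonal
patterning, no Purkinje apoptosis or soma repositioning, no spiny/smooth
dendrite distinction, no synapses on descending axons, and development
stops at P14.  Parallel fibers extend only after horizontal migration
(in vivo they extend during it).  The collision-resolution searches are
this package's own bounded-probe designs; only their existence and purpose,
not their internals, are constrained by the biology.
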