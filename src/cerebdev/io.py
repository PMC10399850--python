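"""Writers: SWC morphologies, migration/metrics CSV, run summaries.

SWC files use the standard seven columns (id, type, x, y, z, radius,
parent) with 1-based ids in topological order (parent before child), the
soma as type 1 with parent −1 and dendrites as type 3.  Retracted trees are
absent.  Coordinates are μm.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DENDRITE, Scene
from .metrics import RunMetrics, scenario_summary, success_rates, tree_stats


def export_swc(scene: Scene, cell, path) -> int:
    """Write one Purkinje cell (soma + living dendritic trees) as SWC.

    Returns the number of lines written.
    """
    rows = []
    id_map = {}

    def swc_id(fid):
        return id_map[fid]

    soma = cell.soma_id
    id_map[soma] = 1
    c = scene.orig[soma]
    rows.append((1, 1, c[0], c[1], c[2], float(scene.radii[soma]), -1))
    # BFS per living tree so parents always precede children
    for tree in cell.living_trees():
        ids = scene.tree_front_ids(cell.neuron_id, tree)
        idset = set(int(i) for i in ids)
        roots = [i for i in idset if int(scene.parents[i]) not in idset]
        stack = list(sorted(roots))
        while stack:
            fid = stack.pop(0)
            id_map[fid] = len(id_map) + 1
            parent = int(scene.parents[fid])
            pid = id_map[parent] if parent in id_map else 1
            e = scene.end[fid]
            rows.append((id_map[fid], 3, e[0], e[1], e[2],
                         float(scene.radii[fid]), pid))
            stack.extend(sorted(k for k in scene.children[fid] if k in idset))
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for r in rows:
            fh.write(f"{r[0]} {r[1]} {r[2]:.4f} {r[3]:.4f} {r[4]:.4f} "
                     f"{r[5]:.4f} {r[6]}\n")
    return len(rows)


def read_swc(path) -> pd.DataFrame:
    """Read an SWC file into a DataFrame (columns per the standard)."""
    return pd.read_csv(
        path, sep=r"\s+", comment="#",
        names=["id", "type", "x", "y", "z", "radius", "parent"],
    )


def migration_report(sim) -> pd.DataFrame:
    """Per-phase migration bookkeeping: born / arrived / failed / T-junctions."""
    from .granule import ARRIVED, FAILED

    rows = []
    for k in range(1, sim.cfg.n_phases + 1):
        cells = [g for g in sim.granule if g.birth_phase == k]
        rows.append({
            "phase": k,
            "born": len(cells),
            "arrived": sum(1 for g in cells if g.state == ARRIVED),
            "failed": sum(1 for g in cells if g.state == FAILED),
            "in_transit": sum(1 for g in cells
                              if g.state not in (ARRIVED, FAILED)),
            "t_junction_ok": sum(1 for g in cells if g.tjunction == "ok"),
        })
    return pd.DataFrame(rows)


def tree_table(sim) -> pd.DataFrame:
    """Per-living-tree morphometrics over all analyzed cells."""
    rows = []
    for pc in sim.analyzed_cells:
        for t in pc.living_trees():
            s = tree_stats(sim.scene, pc.neuron_id, t)
            rows.append({"neuron_id": pc.neuron_id, "tree": t,
                         **s.__dict__})
    return pd.DataFrame(rows)


def events_table(sim) -> pd.DataFrame:
    rows = []
    for ev in sim.events:
        rows.append({
            "neuron_id": ev["neuron_id"],
            "cycle": ev["cycle"],
            "phase": ev["phase"],
            "scenario": ev["scenario"],
            "metric": json.dumps(ev["metric"], sort_keys=True),
            "retracted": json.dumps(ev["retracted"]),
        })
    return pd.DataFrame(rows)


def write_run_outputs(sim, outdir) -> dict:
    """Write the canonical artifact set for one finished run.

    ``metrics.csv`` (per-tree morphometrics), ``migration.csv``,
    ``events.csv`` (retraction decisions), ``summary.json`` (aggregates),
    ``config.yaml`` and one SWC per analyzed Purkinje cell.  Returns the
    summary dict.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tree_table(sim).to_csv(out / "metrics.csv", index=False)
    migration_report(sim).to_csv(out / "migration.csv", index=False)
    events_table(sim).to_csv(out / "events.csv", index=False)
    sim.cfg.to_yaml(out / "config.yaml")
    summary = {
        "scenario": sim.cfg.scenario,
        "seed": sim.cfg.seed,
        "cycle": sim.scene.cycle,
        **scenario_summary(sim),
    }
    if sim.granule or sim.ingrowing:
        summary["run_metrics"] = success_rates(sim).__dict__
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    swcdir = out / "swc"
    swcdir.mkdir(exist_ok=True)
    for pc in sim.analyzed_cells:
        export_swc(sim.scene, pc, swcdir / f"purkinje_{pc.neuron_id:03d}.swc")
    return summary
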