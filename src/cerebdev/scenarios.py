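"""Dendritic tree selection: three control and four retraction scenarios.

All selection rules implement the same two-phase structure observed in
vivo: a first retraction prunes the five candidate trees down to about two,
a second selects the single winner.  Scenarios differ in what triggers the
phases and which per-tree metric ranks the trees:

=================  ==========================  ===============================
scenario           trigger                     selection metric
=================  ==========================  ===============================
RandomRetract      fixed cycle (72)            uniform random single winner
NoRetract          never                       — (all five trees kept)
NoGranCells        fixed cycles (30 / 37)      tree front count (empty volume)
FixedRetract       fixed cycles (90 / 97)      synapse count (keep 2, then 1)
SizeRetract        total-front thresholds      tree front count
SynapseRetract     total-synapse thresholds    tree synapse count
InputRetract       integrated-signal           per-tree integrated signal
                   thresholds
=================  ==========================  ===============================

Ties on the selection metric retain all tied trees, which is why a cell can
occasionally finish with two primary trees.  In the threshold scenarios a
first phase where *every* tree is below the tree threshold retracts them
all (a cell can end with zero trees).  Cells that never reach a threshold
simply never retract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Scene
from .purkinje import PurkinjeCell, retract

SCENARIOS = (
    "RandomRetract",
    "NoRetract",
    "NoGranCells",
    "FixedRetract",
    "SizeRetract",
    "SynapseRetract",
    "InputRetract",
)

DEFAULT_PARAMS = {
    "RandomRetract": {"random_retract_cycle": 72},
    "NoRetract": {},
    "NoGranCells": {"cycle_1": 30, "whole_1st": 250, "tree_th": 60,
                    "cycle_2": 37, "whole_2nd": 400},
    "FixedRetract": {"cycle_1": 90, "cycle_2": 97},
    "SizeRetract": {"whole_1st": 300, "tree_th": 20, "whole_2nd": 400},
    "SynapseRetract": {"whole_1st": 90, "tree_th": 30, "whole_2nd": 180},
    "InputRetract": {"whole_1st": 500, "whole_2nd": 1200},
}


@dataclass
class ScenarioParams:
    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}")
        merged = dict(DEFAULT_PARAMS[self.name])
        merged.update(self.params)
        self.params = merged
        two_phase = [("whole_1st", "whole_2nd"), ("cycle_1", "cycle_2")]
        for a, b in two_phase:
            if a in self.params and b in self.params:
                if self.params[b] < self.params[a]:
                    raise ValueError(f"{b} must be >= {a}")


def _metric(cell: PurkinjeCell, kind: str) -> dict:
    """Per-living-tree value of the scenario's selection metric."""
    if kind == "fronts":
        return {t: cell.front_count[t] for t in cell.living_trees()}
    if kind == "synapses":
        return {t: cell.synapse_count(t) for t in cell.living_trees()}
    if kind == "signal":
        return {t: cell.integrated_signal[t] for t in cell.living_trees()}
    raise ValueError(kind)


def _keep_top(scene: Scene, cell: PurkinjeCell, metric: dict, k: int) -> list:
    """Retract every tree outside the top-``k`` by metric (ties kept)."""
    if len(metric) <= k:
        return []
    cutoff = sorted(metric.values(), reverse=True)[k - 1]
    losers = [t for t, v in metric.items() if v < cutoff]
    for t in losers:
        retract(scene, cell, t)
    return losers


def _retract_below(scene: Scene, cell: PurkinjeCell, metric: dict,
                   threshold: float) -> list:
    losers = [t for t, v in metric.items() if v < threshold]
    for t in losers:
        retract(scene, cell, t)
    return losers


def random_winner(scene: Scene, cell: PurkinjeCell,
                  rng: np.random.Generator) -> int:
    """Keep one uniformly chosen living tree, retract the rest."""
    living = cell.living_trees()
    winner = living[int(rng.integers(len(living)))]
    for t in living:
        if t != winner:
            retract(scene, cell, t)
    cell.phase = "finished"
    return winner


def evaluate_cell(scene: Scene, cell: PurkinjeCell, scenario: ScenarioParams,
                  events: list | None = None) -> None:
    """Apply one scenario's selection rule to one cell for this cycle.

    Called once per cell per cycle after growth.  Appends an event record
    (cycle, phase, metric snapshot, retracted trees) for every retraction
    decision when ``events`` is given.
    """
    name, p = scenario.name, scenario.params
    if cell.phase == "finished" or not cell.roots:
        return

    def log(phase, metric, losers):
        if events is not None:
            events.append({
                "neuron_id": cell.neuron_id,
                "cycle": scene.cycle,
                "phase": phase,
                "scenario": name,
                "metric": dict(metric),
                "retracted": list(losers),
            })

    if name == "NoRetract":
        return

    if name == "RandomRetract":
        if scene.cycle == p["random_retract_cycle"]:
            metric = {t: 1 for t in cell.living_trees()}
            winner = random_winner(scene, cell, cell.rng)
            log("winner", metric, [t for t in metric if t != winner])
        return

    if name == "FixedRetract":
        if scene.cycle == p["cycle_1"] and cell.phase == "growing":
            metric = _metric(cell, "synapses")
            losers = _keep_top(scene, cell, metric, 2)
            cell.phase = "after_first"
            log("first", metric, losers)
        elif scene.cycle == p["cycle_2"] and cell.phase == "after_first":
            metric = _metric(cell, "synapses")
            losers = _keep_top(scene, cell, metric, 1)
            cell.phase = "finished"
            log("winner", metric, losers)
        return

    if name == "NoGranCells":
        if scene.cycle == p["cycle_1"] and cell.phase == "growing":
            metric = _metric(cell, "fronts")
            if sum(metric.values()) > p["whole_1st"]:
                losers = _retract_below(scene, cell, metric, p["tree_th"])
                cell.phase = "after_first"
                log("first", metric, losers)
        elif scene.cycle == p["cycle_2"] and cell.phase != "finished":
            metric = _metric(cell, "fronts")
            if sum(metric.values()) >= p["whole_2nd"]:
                losers = _keep_top(scene, cell, metric, 1)
                cell.phase = "finished"
                log("winner", metric, losers)
        return

    if name in ("SizeRetract", "SynapseRetract"):
        kind = "fronts" if name == "SizeRetract" else "synapses"
        metric = _metric(cell, kind)
        total = sum(metric.values())
        if cell.phase == "growing" and total >= p["whole_1st"]:
            losers = _retract_below(scene, cell, metric, p["tree_th"])
            cell.phase = "after_first"
            log("first", metric, losers)
        elif cell.phase == "after_first" and total >= p["whole_2nd"]:
            losers = _keep_top(scene, cell, metric, 1)
            cell.phase = "finished"
            log("winner", metric, losers)
        return

    if name == "InputRetract":
        metric = _metric(cell, "signal")
        total = sum(metric.values())
        if cell.phase == "growing" and total >= p["whole_1st"]:
            losers = _keep_top(scene, cell, metric, 2)
            cell.phase = "after_first"
            log("first", metric, losers)
        elif cell.phase == "after_first" and total >= p["whole_2nd"]:
            losers = _keep_top(scene, cell, metric, 1)
            cell.phase = "finished"
            log("winner", metric, losers)
        return
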