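"""Bergmann glia scaffold.

Bergmann glia are the first structures to grow.  Each soma sits in the
Purkinje cell layer (z = 0 plane) and sends seven radial processes upward
through the molecular layer; granule cells later use these processes as
guides for their inward radial migration.  Each process starts as a 4 μm
root fanned out along the x-axis and then climbs in 4 μm steps, steering
into a vertical lane at a fixed x-offset from the soma, until it reaches
the top of the molecular layer at z = 131 μm (reached by cycle 35).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GLIA_PROCESS, SOMA, SPHERE, Scene

GLIA_TOP_Z = 131.0
GLIA_STEP = 4.0
ROOT_LENGTH = 4.0
LANE_OFFSETS = (-12.0, -8.0, -4.0, 0.0, 4.0, 8.0, 12.0)
# equal-angle fan in the x–z plane; ±60° keeps sibling roots clear of each
# other at the soma surface for the 0.8 μm process radius
FAN_ANGLES_DEG = (-60.0, -40.0, -20.0, 0.0, 20.0, 40.0, 60.0)


@dataclass
class BergmannGlia:
    neuron_id: int
    soma_id: int
    # per process: current tip front id, target lane x, done flag
    tips: list = field(default_factory=list)
    lanes: list = field(default_factory=list)
    done: list = field(default_factory=list)

    @property
    def process_tips(self):
        return list(self.tips)


def init_bergmann(scene: Scene, soma_center, neuron_id: int,
                  soma_radius: float = 5.0,
                  process_radius: float = 0.8,
                  lane_offsets=LANE_OFFSETS) -> BergmannGlia:
    """Create a Bergmann glia soma with its seven 4 μm root processes.

    Roots are fanned in the x–z plane from the upper soma surface; glia grow
    before anything else so root placement is not collision-checked.
    """
    c = np.asarray(soma_center, dtype=float)
    soma_id = scene.add_front(neuron_id, c, c, soma_radius, SOMA,
                              shape=SPHERE, active=False)
    glia = BergmannGlia(neuron_id=neuron_id, soma_id=soma_id)
    for ang_deg, lane_dx in zip(FAN_ANGLES_DEG, lane_offsets):
        ang = np.deg2rad(ang_deg)
        d = np.array([np.sin(ang), 0.0, np.cos(ang)])
        orig = c + soma_radius * d
        end = orig + ROOT_LENGTH * d
        fid = scene.add_front(neuron_id, orig, end, process_radius,
                              GLIA_PROCESS, parent=soma_id)
        glia.tips.append(fid)
        glia.lanes.append(c[0] + lane_dx)
        glia.done.append(False)
    return glia


def extend_glia_processes(scene: Scene, glia: BergmannGlia,
                          process_radius: float = 0.8):
    """One cycle of upward growth for every unfinished process.

    Each step is GLIA_STEP μm within a small cone of +z, drifting toward the
    process's x-lane; the final step is clamped so the tip ends exactly at
    z = GLIA_TOP_Z, after which the process terminates.
    """
    for i, tip in enumerate(glia.tips):
        if glia.done[i]:
            continue
        tip_end = scene.end[tip]
        if tip_end[2] >= GLIA_TOP_Z - 1e-9:
            glia.done[i] = True
            scene.active[tip] = False
            continue
        dx = float(np.clip(glia.lanes[i] - tip_end[0], -1.0, 1.0))
        d = np.array([dx, 0.0, GLIA_STEP])
        d *= GLIA_STEP / np.linalg.norm(d)
        new_end = tip_end + d
        if new_end[2] > GLIA_TOP_Z:
            # clamp: shorter final segment ending exactly at the ceiling
            scale = (GLIA_TOP_Z - tip_end[2]) / d[2]
            new_end = tip_end + scale * d
            new_end[2] = GLIA_TOP_Z
        child = scene.add_front(glia.neuron_id, tip_end, new_end,
                                process_radius, GLIA_PROCESS, parent=tip)
        scene.active[tip] = False
        glia.tips[i] = child
        if new_end[2] >= GLIA_TOP_Z - 1e-9:
            glia.done[i] = True
            scene.active[child] = False
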