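"""Purkinje cell dendritic growth.

Each Purkinje soma activates (cycle 65 by default, once early granule cell
migration is done) and grows five dendritic roots on its upper hemisphere.
Every cycle each dendritic tip:

* seeks the nearest synapse-free parallel-fiber segment within a search
  radius and grows toward it;
* on contact forms a synapse and continues perpendicular to the fiber's
  axis (y-component of the heading suppressed), which is what ultimately
  flattens the tree into the x–z plane;
* without a target, continues along its heading with a small upward bias
  and some directional noise;
* is repelled along y by the nearest dendrite front of a different tree
  (own or other cell), with strength decaying exponentially in |Δy|;
* may branch at random with a small probability, or branch toward its
  target fiber when the target direction deviates strongly from the
  current heading;
* terminates on reaching z = 100 μm or after repeated blocked cycles.

Synaptic input is integrated per tree as a running sum over cycles of the
presynaptic granule cells' firing rates; the InputRetract selection
scenario reads this signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    CYLINDER,
    DENDRITE,
    PARALLEL_FIBER,
    SOMA,
    SPHERE,
    CollisionError,
    OutOfBoundsError,
    Scene,
)
from .geometry import unit

N_ROOTS = 5
_RING_ANGLES = np.linspace(0.0, 2 * np.pi, 8, endpoint=False)


@dataclass
class PurkinjeParams:
    """Code-level growth constants (μm, cycles); exposed in the run config."""

    soma_radius: float = 7.0
    root_length: float = 5.0
    dendrite_radius: float = 0.8
    pf_search_radius: float = 10.0
    contact_distance: float = 1.5
    upward_bias: float = 0.08
    repulsion_strength: float = 1.0
    repulsion_lambda: float = 5.0     # decay length of the y-repulsion kernel
    noise_weight: float = 0.45
    p_branch: float = 0.05            # random branching prob / tip / cycle
    theta_dev_deg: float = 60.0       # directed-branch deviation threshold
    step: float = 5.0
    step_jitter: float = 0.5          # fronts end up 5 ± 0.5 μm
    ceiling_z: float = 100.0
    max_tips_per_tree: int = 40       # resource cap on simultaneous tips
    retry_budget: int = 3


@dataclass
class DendriteTip:
    front: int
    heading: np.ndarray
    blocked: int = 0
    just_synapsed: bool = False
    target_pf: int = -1          # cached target fiber front (revalidated)


@dataclass
class PurkinjeCell:
    neuron_id: int
    soma_id: int
    rng: np.random.Generator
    analyzed: bool = True
    roots: list = field(default_factory=list)
    tree_alive: list = field(default_factory=list)
    tips: dict = field(default_factory=dict)          # tree -> [DendriteTip]
    front_count: list = field(default_factory=list)   # per tree, incl. root
    integrated_signal: list = field(default_factory=list)
    syn_pre: dict = field(default_factory=dict)       # tree -> [(pre_fid, pre_nid)]
    phase: str = "growing"                            # growing|after_first|finished

    def living_trees(self):
        return [t for t in range(len(self.roots)) if self.tree_alive[t]]

    def synapse_count(self, tree: int) -> int:
        return len(self.syn_pre.get(tree, ()))

    def total_fronts(self) -> int:
        return sum(self.front_count[t] for t in self.living_trees())

    def total_synapses(self) -> int:
        return sum(self.synapse_count(t) for t in self.living_trees())

    def total_signal(self) -> float:
        return float(sum(self.integrated_signal[t] for t in self.living_trees()))


def activate_purkinje(scene: Scene, cell: PurkinjeCell,
                      params: PurkinjeParams) -> list:
    """Grow the five dendritic roots on the soma's upper hemisphere.

    Roots are spread ~72° apart in azimuth (random common offset) at a
    random upper-hemisphere elevation, collision-checked with a few retry
    rotations.  A cell that ends up with fewer than five roots is excluded
    from analysis.
    """
    c = scene.orig[cell.soma_id]
    base_az = cell.rng.uniform(0.0, 2 * np.pi)
    for i in range(N_ROOTS):
        placed = -1
        for attempt in range(8):
            az = base_az + i * (2 * np.pi / N_ROOTS) + attempt * np.deg2rad(9)
            polar = np.deg2rad(cell.rng.uniform(25.0, 60.0))
            d = np.array([np.sin(polar) * np.cos(az),
                          np.sin(polar) * np.sin(az),
                          np.cos(polar)])
            end = c + (params.soma_radius + params.root_length) * d
            try:
                placed = scene.grow_front(cell.soma_id, end,
                                          params.dendrite_radius, DENDRITE,
                                          tree_index=i)
                break
            except (CollisionError, OutOfBoundsError):
                continue
        # tree slot i is positional: a failed root leaves a dead slot so the
        # scene's tree_index always matches the cell's bookkeeping
        cell.roots.append(placed)
        cell.tree_alive.append(placed >= 0)
        cell.front_count.append(1 if placed >= 0 else 0)
        cell.integrated_signal.append(0.0)
        cell.syn_pre[i] = []
        cell.tips[i] = ([DendriteTip(front=placed, heading=d.copy())]
                        if placed >= 0 else [])
        if placed >= 0:
            scene.active[cell.soma_id] = True  # soma stays the tree anchor
    if sum(1 for r in cell.roots if r >= 0) < N_ROOTS:
        cell.analyzed = False
    return [r for r in cell.roots if r >= 0]


def find_target_pf(scene: Scene, pos: np.ndarray, params: PurkinjeParams):
    """Nearest synapse-free parallel-fiber front within the search radius.

    Returns ``(front_id, closest_point, distance)`` or ``None``; equidistant
    candidates break ties to the lowest front id.
    """
    ids = scene.query_neighbors(pos, params.pf_search_radius,
                                tags=PARALLEL_FIBER)
    if ids.size == 0:
        return None
    ids = ids[~scene.has_synapse[ids]]
    if ids.size == 0:
        return None
    a = scene.orig[ids]
    ab = scene.end[ids] - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.einsum("ij,ij->i", pos[None, :] - a, ab)
    t = np.clip(np.where(denom > 1e-12, t / np.maximum(denom, 1e-12), 0.0), 0, 1)
    pts = a + t[:, None] * ab
    d = np.linalg.norm(pts - pos[None, :], axis=1)
    order = np.lexsort((ids, np.round(d, 9)))[0]
    return int(ids[order]), pts[order], float(d[order])


def elongation_direction(scene: Scene, cell: PurkinjeCell, tip: DendriteTip,
                         target, params: PurkinjeParams) -> np.ndarray:
    """Blend target attraction / heading persistence, upward bias,
    y-repulsion from the nearest foreign dendrite, and noise.

    ``target`` is the tuple from :func:`find_target_pf` or ``None``.  After
    a synapse, growth is restricted to the plane perpendicular to the
    contacted fiber (fibers run along y, so the y-component is dropped).
    """
    pos = scene.end[tip.front]
    if target is not None:
        base = unit(target[1] - pos)
    else:
        base = unit(tip.heading + params.upward_bias * np.array([0.0, 0.0, 1.0]))
    vec = base.copy()
    # y-repulsion from nearest dendrite front of a different tree
    tree = int(scene.tree_indices[tip.front])
    ids = scene.query_neighbors(pos, 0.8 * params.pf_search_radius, tags=DENDRITE)
    if ids.size:
        foreign = ~((scene.neuron_ids[ids] == cell.neuron_id)
                    & (scene.tree_indices[ids] == tree))
        ids = ids[foreign]
    if ids.size:
        mid = 0.5 * (scene.orig[ids] + scene.end[ids])
        d = np.linalg.norm(mid - pos[None, :], axis=1)
        nearest = mid[np.argmin(d)]
        dy = nearest[1] - pos[1]
        mag = params.repulsion_strength * np.exp(-abs(dy) / params.repulsion_lambda)
        vec = vec + mag * np.array([0.0, -np.sign(dy), 0.0])
    if params.noise_weight > 0:
        n = cell.rng.normal(size=3)
        vec = vec + params.noise_weight * unit(n)
    if tip.just_synapsed:
        vec[1] = 0.0
    return unit(vec)


def _try_grow(scene: Scene, parent: int, end: np.ndarray,
              heading: np.ndarray, step: float,
              params: PurkinjeParams, rng=None):
    """Grow a dendrite front, searching for a detour when blocked.

    The detour search first probes laterally around the intended heading,
    then (in a crowded pocket) samples a few random escape directions with
    a slight upward tilt.
    """
    try:
        return scene.grow_front(parent, end, params.dendrite_radius, DENDRITE)
    except OutOfBoundsError:
        pass
    except CollisionError:
        pass
    if rng is None:
        return None
    start = scene.end[parent] if scene.shapes[parent] == CYLINDER \
        else scene.orig[parent]
    # one batched fan: a lateral ring around the intended heading plus a few
    # random escape directions with a slight upward tilt
    heading = unit(heading)
    ref = np.array([0.0, 0.0, 1.0]) if abs(heading[2]) < 0.9 \
        else np.array([1.0, 0.0, 0.0])
    u = np.cross(heading, ref)
    u /= np.linalg.norm(u)
    v = np.cross(heading, u)
    ring = [end + 1.6 * (np.cos(a) * u + np.sin(a) * v) for a in _RING_ANGLES]
    esc = [start + step * unit(heading + rng.normal(size=3)
                               + np.array([0.0, 0.0, 0.3]))
           for _ in range(6)]
    ends = np.asarray(ring + esc)
    ok = scene.free_segments(np.broadcast_to(start, ends.shape), ends,
                             params.dendrite_radius, exclude_ids=(parent,),
                             shared_point=start)
    for i in range(len(ends)):
        if not ok[i]:
            continue
        try:
            return scene.grow_front(parent, ends[i],
                                    params.dendrite_radius, DENDRITE)
        except (CollisionError, OutOfBoundsError):
            continue
    return None


def grow_cell_cycle(scene: Scene, cell: PurkinjeCell,
                    params: PurkinjeParams) -> None:
    """One growth cycle for every living tree of one Purkinje cell."""
    theta_dev = np.deg2rad(params.theta_dev_deg)
    for tree in cell.living_trees():
        tips = cell.tips[tree]
        if not tips:
            continue
        new_tips: list[DendriteTip] = []
        for tip in tips:
            pos = scene.end[tip.front]
            # revalidate the cached target fiber before searching anew
            target = None
            tf = tip.target_pf
            if tf >= 0 and scene.alive[tf] and not scene.has_synapse[tf]:
                a, b = scene.orig[tf], scene.end[tf]
                ab = b - a
                denom = float(ab @ ab)
                t = float(np.clip((pos - a) @ ab / denom, 0, 1)) if denom > 1e-12 else 0.0
                pt = a + t * ab
                dist = float(np.linalg.norm(pt - pos))
                if dist <= params.pf_search_radius:
                    target = (tf, pt, dist)
            if target is None:
                target = find_target_pf(scene, pos, params)
                tip.target_pf = target[0] if target is not None else -1
            # synaptic contact
            if (target is not None and target[2] <= params.contact_distance
                    and not scene.has_synapse[tip.front]):
                rec = scene.synapses.add(scene, pre=target[0], post=tip.front)
                if rec is not None:
                    cell.syn_pre[tree].append(
                        (target[0], int(scene.neuron_ids[target[0]])))
                    tip.just_synapsed = True
                    target = None
                    tip.target_pf = -1
            direction = elongation_direction(scene, cell, tip, target, params)
            tip.just_synapsed = False
            headings = [direction]
            # directed branch toward a strongly off-heading target
            if target is not None:
                to_t = unit(target[1] - pos)
                cosang = float(np.clip(np.dot(unit(tip.heading), to_t), -1, 1))
                if np.arccos(cosang) > theta_dev:
                    headings.append(to_t)
            # random branching: two divergent children instead of one
            if len(headings) == 1 and cell.rng.random() < params.p_branch:
                perp = unit(np.cross(direction, cell.rng.normal(size=3)))
                ang = np.deg2rad(20.0)
                headings = [
                    unit(np.cos(ang) * direction + np.sin(ang) * perp),
                    unit(np.cos(ang) * direction - np.sin(ang) * perp),
                ]
            grew = False
            for k, h in enumerate(headings):
                if k > 0 and len(new_tips) + len(headings) - 1 > params.max_tips_per_tree:
                    break
                L = params.step + cell.rng.uniform(-params.step_jitter,
                                                   params.step_jitter)
                child = _try_grow(scene, tip.front, pos + L * h, h, L, params,
                                  rng=cell.rng)
                if child is None:
                    continue
                grew = True
                cell.front_count[tree] += 1
                endz = scene.end[child][2]
                if endz >= params.ceiling_z:
                    scene.active[child] = False      # reached the ceiling
                elif len(new_tips) < params.max_tips_per_tree:
                    new_tips.append(DendriteTip(
                        front=child, heading=h,
                        target_pf=tip.target_pf if k == 0 else -1))
                else:
                    scene.active[child] = False
            if not grew:
                tip.blocked += 1
                if tip.blocked < params.retry_budget:
                    new_tips.append(tip)             # retry next cycle
                else:
                    scene.active[tip.front] = False  # terminal
        if not new_tips:
            # all tips exhausted: let a few dormant terminals resume growth
            ids = scene.tree_front_ids(cell.neuron_id, tree)
            cand = [int(i) for i in ids
                    if not scene.children[i] and scene.end[i][2] < params.ceiling_z]
            if cand:
                pick = cell.rng.choice(len(cand), size=min(3, len(cand)),
                                       replace=False)
                for j in np.atleast_1d(pick):
                    fid = cand[int(j)]
                    h = unit(scene.end[fid] - scene.orig[fid])
                    new_tips.append(DendriteTip(front=fid, heading=h))
        cell.tips[tree] = new_tips


def integrate_signal(cell: PurkinjeCell, rates: dict) -> None:
    """Accumulate per-tree synaptic signal: Σ presynaptic firing rates.

    A pure running sum (no decay); ``rates`` maps granule neuron id to the
    cell's current firing rate.  Synapses whose presynaptic neuron is gone
    contribute zero.
    """
    for tree in cell.living_trees():
        s = 0.0
        for _pre_fid, pre_nid in cell.syn_pre[tree]:
            s += rates.get(pre_nid, 0.0)
        cell.integrated_signal[tree] += s


def retract(scene: Scene, cell: PurkinjeCell, tree: int) -> int:
    """Retract one dendritic tree and clear the cell's bookkeeping."""
    n = scene.retract_tree(cell.neuron_id, tree)
    cell.tree_alive[tree] = False
    cell.tips[tree] = []
    cell.front_count[tree] = 0
    cell.syn_pre[tree] = []
    return n
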