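"""Granule cell migration and parallel fiber growth.

Granule cells are born in 12 consecutive phases in z-bands from the bottom
to the top of the (future) molecular layer, emulating the upward push of
the external granular layer as the tissue expands.  Each cell:

1. migrates horizontally toward the nearest Bergmann glia process by
   extending a cylindrical leading process, the soma following behind;
2. on contact, turns downward (radial migration) hugging the glia process,
   leaving a short trailing axon at the turning point;
3. descends, depositing a descending-axon front per step, until it reaches
   the internal granular layer at z = −15 μm;
4. meanwhile the trailing axon bifurcates into two parallel-fiber branches
   running along ±y (the T-junction), each extending 5 μm per cycle until a
   volume wall, the per-branch length cap, or an unresolvable collision.

Granule cells fire at a low random rate (uniform 0–0.2 events/cycle) until
their soma arrives in the granular layer, after which the rate jumps to
uniform 0–10 (the cells can now receive mossy fiber input).  Cells whose
migration failed keep the low range.

Ingrowing parallel fibers represent granule cells of neighboring volumes:
a stationary source sphere in one of the two y-wings grows a single fiber
toward and through the main volume.  Their firing rate follows the same
two-level rule, switching at a per-fiber arrival cycle drawn to mimic the
migration duration the source cell would have had at its birth z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    DESCENDING_AXON,
    GLIA_PROCESS,
    LEADING_PROCESS,
    PARALLEL_FIBER,
    SOMA,
    SPHERE,
    CollisionError,
    OutOfBoundsError,
    Scene,
)

BORN = "born"
HORIZONTAL = "horizontal"
RADIAL = "radial"
ARRIVED = "arrived"
FAILED = "failed"

ARRIVAL_Z = -15.0
RATE_LOW = 0.2      # events/cycle, pre-arrival upper bound
RATE_HIGH = 10.0    # events/cycle, post-arrival upper bound


@dataclass
class PFBranch:
    tip: int                 # current tip front id
    sign: int                # +1 or -1 along y
    length: float = 0.0
    done: bool = False
    reason: str = ""         # "wall" | "cap" | "blocked"


@dataclass
class GranuleCell:
    neuron_id: int
    soma_id: int
    birth_phase: int
    rng: np.random.Generator
    state: str = BORN
    target_front: int = -1
    target_xy: np.ndarray | None = None
    leading_tip: int = -1
    axon_root: int = -1
    axon_tip: int = -1
    branches: list = field(default_factory=list)
    tjunction: str = "pending"   # pending | ok | failed
    junction: int = -1           # front whose distal end is the T-junction
    tj_attempts: int = 0
    firing_rate: float = 0.0
    blocked: int = 0
    descent_start_z: float = np.nan
    fail_site: str = ""  # set when state becomes FAILED


@dataclass
class IngrowingPF:
    neuron_id: int
    source_id: int
    sign: int                # growth direction along y (toward the main volume)
    arrival_cycle: int
    rng: np.random.Generator = None
    branch: PFBranch | None = None
    firing_rate: float = 0.0
    _arrived: bool = False


# --------------------------------------------------------------------- kinetics


def select_target_process(scene: Scene, gc: GranuleCell,
                          search_radius: float = 30.0) -> int:
    """Pick the closest Bergmann glia process in the horizontal plane.

    Among glia-process fronts within ``search_radius`` of the soma the one
    with the smallest horizontal (x, y) distance wins; ties break to the
    lowest front id.  No process in range ⇒ the cell fails.
    """
    soma = scene.orig[gc.soma_id]
    ids = scene.query_neighbors(soma, search_radius, tags=GLIA_PROCESS)
    if ids.size == 0:
        gc.state = FAILED
        gc.fail_site = "no_glia"
        return -1
    mid = 0.5 * (scene.orig[ids] + scene.end[ids])
    d = np.hypot(mid[:, 0] - soma[0], mid[:, 1] - soma[1])
    best = ids[np.lexsort((ids, np.round(d, 9)))][0]
    gc.target_front = int(best)
    m = 0.5 * (scene.orig[best] + scene.end[best])
    gc.target_xy = np.array([m[0], m[1]])
    gc.state = HORIZONTAL
    return int(best)


def horizontal_step(scene: Scene, gc: GranuleCell, *,
                    step: float = 4.0,
                    contact: float = 2.0,
                    leading_radius: float = 0.6,
                    retry_budget: int = 3) -> str:
    """One cycle of horizontal migration at constant z.

    Extends the leading process one step toward the target glia process and
    lets the soma follow one front behind.  ``contact`` is a surface gap:
    the cell switches to radial migration once the gap between the soma
    surface and the glia process surface is at most ``contact``.
    """
    soma = scene.orig[gc.soma_id]
    glia_r = float(scene.radii[gc.target_front])
    soma_r = float(scene.radii[gc.soma_id])
    off = gc.target_xy - soma[:2]
    if np.hypot(*off) <= contact + soma_r + glia_r:
        gc.state = RADIAL
        gc.blocked = 0
        return "reached"
    heading = np.array([off[0], off[1], 0.0])
    heading /= np.linalg.norm(heading)
    parent = gc.leading_tip if gc.leading_tip >= 0 else gc.soma_id
    start = scene.end[parent] if parent != gc.soma_id else soma
    # never drive the leading tip into the glia process itself
    tip_gap = float(np.hypot(*(gc.target_xy - start[:2])))
    this_step = min(step, max(tip_gap - (leading_radius + glia_r + 0.2), 0.0))
    if this_step > 0.1:
        try:
            child = scene.grow_front(parent, start + this_step * heading,
                                     leading_radius, LEADING_PROCESS)
        except (CollisionError, OutOfBoundsError):
            pos = scene.alternate_location(parent, heading, this_step,
                                           leading_radius, max_lateral=2.0)
            if pos is None:
                gc.blocked += 1
                if gc.blocked >= retry_budget:
                    gc.state = FAILED
                    gc.fail_site = "horizontal_extend"
                    return "failed"
                return "progressed"
            child = scene.grow_front(parent, pos, leading_radius,
                                     LEADING_PROCESS)
        gc.blocked = 0
        prev_tip = gc.leading_tip
        gc.leading_tip = child
        # soma follows along the deposited leading path, one front behind,
        # absorbing the leading fronts it passes
        if prev_tip >= 0:
            moved = scene.migrate_soma(gc.soma_id, scene.orig[child])
            if moved is not None:
                scene.remove_front(prev_tip)
        return "progressed"
    # tip is parked at the process; walk the soma toward the lane, stopping
    # where its surface just clears the glia process
    min_off = soma_r + glia_r + 0.3
    d = float(np.hypot(*off))
    stop = gc.target_xy - off * (min_off / d) if d > min_off else soma[:2]
    approach = np.array([stop[0], stop[1], soma[2]])
    gap = np.linalg.norm(approach - soma)
    if gap > step:
        approach = soma + (approach - soma) * (step / gap)
    pos = scene.migrate_soma(gc.soma_id, approach)
    if pos is None:
        gc.blocked += 1
        if gc.blocked >= retry_budget:
            gc.state = FAILED
            gc.fail_site = "horizontal_follow"
            return "failed"
    return "progressed"


def begin_radial(scene: Scene, gc: GranuleCell, *,
                 axon_length: float = 3.0,
                 axon_radius: float = 0.5,
                 leading_radius: float = 0.6) -> None:
    """Switch from horizontal to radial migration (idempotent).

    A short trailing axon is planted at the soma's pre-descent position --
    its distal end is the future T-junction -- and the leading process is
    reoriented downward along the glia process.
    """
    if gc.axon_root >= 0:
        return
    soma = scene.orig[gc.soma_id]
    gc.descent_start_z = float(soma[2])
    try:
        gc.axon_root = scene.grow_front(
            gc.soma_id, soma + np.array([0.0, 0.0, axon_length]),
            axon_radius, DESCENDING_AXON)
        gc.axon_tip = gc.axon_root
    except (CollisionError, OutOfBoundsError):
        gc.axon_root = -1
        gc.tjunction = "failed"
    # the soma absorbs the remaining leading process and from here on
    # descends with its own (implicit) leading tip hugging the glia
    if gc.leading_tip >= 0:
        scene.remove_front(gc.leading_tip)
        gc.leading_tip = -1


def radial_step(scene: Scene, gc: GranuleCell, *,
                step: float = 5.0,
                tether: float = 3.0,
                retry_budget: int = 3) -> str:
    """One cycle of downward migration along the glia process.

    The soma descends one step, hugging the glia lane: its lateral surface
    gap to the process stays within ``tether`` (a collision bypass may widen
    it transiently; the drift pulls it back the next cycle).  The glial
    guide ends at the soma layer, so below z ≈ 10 μm the cell descends
    freely toward the granular layer.  Each successful step deposits one
    descending-axon front spanning old → new soma center.  Arrival is
    soma z ≤ −15 μm.
    """
    soma = scene.orig[gc.soma_id].copy()
    if soma[2] <= ARRIVAL_Z:
        gc.state = ARRIVED
        return "arrived"
    glia_r = float(scene.radii[gc.target_front])
    soma_r = float(scene.radii[gc.soma_id])
    min_off = soma_r + glia_r + 0.3   # soma surface just clear of the process
    max_off = tether + soma_r + glia_r
    guided = soma[2] > 14.0           # below this the guide has ended
    nid = gc.neuron_id
    pos = None
    if guided:
        # ring search: the soma may slide to any azimuth around the glia
        # process while descending, preferring its current side and the
        # tightest radial offset
        off = soma[:2] - gc.target_xy
        az0 = float(np.arctan2(off[1], off[0])) if np.hypot(*off) > 1e-9 else 0.0
        d_az = np.array([0.0, 0.4, -0.4, 0.8, -0.8, 1.2, -1.2, 1.7, -1.7,
                         2.2, -2.2, 2.7, -2.7, np.pi])
        cands = []
        for dz in (step, 0.66 * step, 0.33 * step):
            z = max(soma[2] - dz, ARRIVAL_Z)
            for rad in (min_off, 0.5 * (min_off + max_off), max_off,
                        max_off + 2.0, max_off + 4.0):
                for da in d_az:
                    az = az0 + da
                    cands.append((gc.target_xy[0] + rad * np.cos(az),
                                  gc.target_xy[1] + rad * np.sin(az), z))
        cands = np.asarray(cands)
        # swept-sphere check from the current position to each candidate:
        # sliding around the glia happens gradually, never through obstacles
        starts = np.broadcast_to(soma, cands.shape)
        ok = scene.free_segments(starts, cands, soma_r,
                                 exclude_ids=(gc.soma_id,),
                                 exclude_neuron=nid)
        hit = np.nonzero(ok)[0]
        if hit.size:
            pos = cands[hit[0]]
    else:
        # crossing the soma layer: steer laterally into the gaps between the
        # large Purkinje and glia somata
        txy = soma[:2].copy()
        near = scene.query_neighbors(soma, 14.0, tags=SOMA)
        if near.size:
            near = near[scene.radii[near] >= 4.0]
        push = np.zeros(2)
        for ob in near:
            delta = soma[:2] - scene.orig[ob][:2]
            dd = float(np.hypot(*delta))
            needed = float(scene.radii[ob]) + soma_r + 1.0
            if dd < needed + 2.0:
                u = delta / dd if dd > 1e-9 else np.array([1.0, 0.0])
                push += u * (needed + 2.0 - dd)
        pn = float(np.hypot(*push))
        if pn > 3.0:
            push *= 3.0 / pn
        txy += push
        for frac in (1.0, 0.5):
            target = np.array([txy[0], txy[1],
                               max(soma[2] - frac * step, ARRIVAL_Z)])
            pos = scene.migrate_soma(gc.soma_id, target)
            if pos is not None:
                break
    if pos is not None and guided:
        scene.migrate_soma(gc.soma_id, pos)  # position is free: direct move
    if pos is None:
        gc.blocked += 1
        if gc.blocked >= retry_budget:
            gc.state = FAILED
            gc.fail_site = "radial"
            return "failed"
        return "progressed"
    gc.blocked = 0
    if gc.axon_tip >= 0:
        # the soma just vacated this corridor, so the trail cannot overlap
        tip = scene.add_front(gc.neuron_id, soma, pos,
                              scene.radii[gc.axon_tip], DESCENDING_AXON,
                              parent=gc.axon_tip, active=False)
        gc.axon_tip = tip
    if pos[2] <= ARRIVAL_Z:
        gc.state = ARRIVED
        return "arrived"
    return "progressed"


# ----------------------------------------------------------------- parallel fibers


def bifurcate_pf(scene: Scene, gc: GranuleCell, *,
                 step: float = 5.0,
                 pf_radius: float = 0.5,
                 max_lateral: float = 0.4) -> str:
    """Form the T-junction: two parallel-fiber branches at the axon root.

    Both children head ±y, perpendicular to the descending axon, at the
    axon root's z.  A side that cannot be placed (collision even after the
    lateral search) is dropped; the T-junction counts as successful only
    when both sides exist.
    """
    if gc.tjunction != "pending":
        return gc.tjunction
    if gc.axon_root < 0:
        gc.tjunction = "failed"
        return "failed"
    if gc.junction < 0:
        gc.junction = gc.axon_root
    base = scene.end[gc.junction]

    def side_end(sign):
        heading = np.array([0.0, float(sign), 0.0])
        for s in (step, 0.5 * step):
            hits = scene.collision_ids(base, base + s * heading, pf_radius,
                                       exclude_ids=(gc.junction,),
                                       shared_point=base)
            if hits.size == 0 and scene.volume.contains(base + s * heading):
                return base + s * heading
            pos = scene.alternate_location(gc.junction, heading, s,
                                           pf_radius, max_lateral=max_lateral)
            if pos is not None:
                return pos
        return None

    ends = {sign: side_end(sign) for sign in (1, -1)}
    if all(e is not None for e in ends.values()) or gc.tj_attempts >= 5:
        # place whatever is feasible; success requires both sides
        ok = 0
        for sign in (1, -1):
            if ends[sign] is None:
                continue
            try:
                tip = scene.grow_front(gc.junction, ends[sign], pf_radius,
                                       PARALLEL_FIBER)
            except (CollisionError, OutOfBoundsError):
                continue
            gc.branches.append(PFBranch(tip=tip, sign=sign, length=step))
            ok += 1
        gc.tjunction = "ok" if ok == 2 else "failed"
        scene.active[gc.junction] = False
        return gc.tjunction
    # one side blocked: let the axon grow a little (upward, with a small
    # lateral jitter to slip past fibers at this exact x) and retry
    gc.tj_attempts += 1
    jit = gc.rng.uniform(-1.2, 1.2, size=2)
    lift = scene.end[gc.junction] + np.array([jit[0], jit[1], 1.5])
    try:
        gc.junction = scene.grow_front(gc.junction, lift,
                                       scene.radii[gc.axon_root],
                                       DESCENDING_AXON)
    except (CollisionError, OutOfBoundsError):
        pass
    return "pending"


def extend_pf(scene: Scene, branch: PFBranch, *,
              step: float = 5.0,
              pf_radius: float = 0.5,
              branch_cap: float = 150.0,
              max_lateral: float = 0.4) -> str:
    """Extend one parallel-fiber branch by one step along its ±y heading.

    Terminates at the full-volume y wall, at the per-branch length cap, or
    when even the lateral search cannot place a child.  The small lateral
    allowance keeps every fiber front within ~5° of the y-axis.
    """
    if branch.done:
        return branch.reason
    if branch.length >= branch_cap:
        branch.done = True
        branch.reason = "cap"
        scene.active[branch.tip] = False
        return "cap"
    tip_end = scene.end[branch.tip]
    lo_y, hi_y = scene.volume.full_lo[1], scene.volume.full_hi[1]
    wall = hi_y if branch.sign > 0 else lo_y
    remaining = (wall - tip_end[1]) * branch.sign
    this_step = min(step, branch_cap - branch.length, max(remaining, 0.0))
    if this_step < 1e-6:
        branch.done = True
        branch.reason = "wall"
        scene.active[branch.tip] = False
        return "wall"
    heading = np.array([0.0, float(branch.sign), 0.0])
    try:
        child = scene.grow_front(branch.tip, tip_end + this_step * heading,
                                 pf_radius, PARALLEL_FIBER)
    except (CollisionError, OutOfBoundsError):
        pos = scene.alternate_location(branch.tip, heading, this_step,
                                       pf_radius, max_lateral=max_lateral)
        if pos is None:
            branch.done = True
            branch.reason = "blocked"
            scene.active[branch.tip] = False
            return "blocked"
        child = scene.grow_front(branch.tip, pos, pf_radius, PARALLEL_FIBER)
    branch.length += float(np.linalg.norm(scene.end[child] - scene.orig[child]))
    branch.tip = child
    if this_step < step or branch.length >= branch_cap:
        branch.done = True
        branch.reason = "wall" if this_step < step else "cap"
        scene.active[child] = False
    return "progressed"


def make_ingrowing_pf(scene: Scene, neuron_id: int, position, sign: int,
                      arrival_cycle: int, rng=None, *,
                      source_radius: float = 1.0) -> IngrowingPF:
    """Create a stationary ingrowing-fiber source sphere (no migration)."""
    p = np.asarray(position, dtype=float)
    sid = scene.add_front(neuron_id, p, p, source_radius, SOMA,
                          shape=SPHERE, active=False)
    return IngrowingPF(neuron_id=neuron_id, source_id=sid, sign=sign,
                       arrival_cycle=arrival_cycle, rng=rng)


def start_ingrowing_fiber(scene: Scene, pf: IngrowingPF, *,
                          step: float = 5.0, pf_radius: float = 0.5,
                          max_lateral: float = 0.4) -> bool:
    """Sprout the single fiber of an ingrowing source toward the main volume."""
    if pf.branch is not None:
        return True
    heading = np.array([0.0, float(pf.sign), 0.0])
    base = scene.orig[pf.source_id]
    try:
        tip = scene.grow_front(pf.source_id, base + step * heading,
                               pf_radius, PARALLEL_FIBER)
    except (CollisionError, OutOfBoundsError):
        pos = scene.alternate_location(pf.source_id, heading, step,
                                       pf_radius, max_lateral=max_lateral)
        if pos is None:
            pf.branch = PFBranch(tip=-1, sign=pf.sign, done=True,
                                 reason="blocked")
            return False
        tip = scene.grow_front(pf.source_id, pos, pf_radius, PARALLEL_FIBER)
    pf.branch = PFBranch(tip=tip, sign=pf.sign, length=step)
    return True


# ----------------------------------------------------------------- firing rates


def update_firing_rate(cell, rng=None, force_high: bool = False) -> float:
    """Per-cycle uniform firing-rate draw.

    Granule cells draw from U[0, 0.2] before arrival in the granular layer
    and from U[0, 10] after; failed cells keep the low range.  For ingrowing
    sources ``arrived`` means the simulation cycle has passed the fiber's
    drawn arrival cycle.  ``force_high`` puts every cell in the post-arrival
    range (used to probe the role of input heterogeneity).
    """
    rng = rng if rng is not None else cell.rng
    if force_high:
        hi = RATE_HIGH
    elif isinstance(cell, GranuleCell):
        hi = RATE_HIGH if cell.state == ARRIVED else RATE_LOW
    else:
        hi = RATE_HIGH if getattr(cell, "_arrived", False) else RATE_LOW
    cell.firing_rate = float(rng.uniform(0.0, hi))
    return cell.firing_rate
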