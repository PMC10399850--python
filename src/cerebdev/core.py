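"""Cycle-driven simulation kernel.

The universal agent is the *front*: a sphere (soma) or a short cylinder
(neurite segment).  Development proceeds in discrete cycles (one cycle is
roughly 2.2 h; cycle = 10 × postnatal day).  Each cycle, active fronts may
extend, branch or terminate; new fronts are only created where they do not
overlap any coexisting front.  The scene keeps all fronts in
structure-of-arrays storage with a uniform-grid spatial index so collision
queries are vectorised.

Fronts are addressed by integer id.  A :class:`Front` proxy gives attribute
access to a single front's fields for inspection and tests; hot paths work
on ids and arrays directly.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np

from ._kernels import seg_seg_dist_many, segments_free
from .geometry import point_segment_distance, segment_segment_distance

# structure tags
SOMA = 0
GLIA_PROCESS = 1
LEADING_PROCESS = 2
DESCENDING_AXON = 3
PARALLEL_FIBER = 4
DENDRITE = 5

TAG_NAMES = {
    SOMA: "soma",
    GLIA_PROCESS: "glia_process",
    LEADING_PROCESS: "leading_process",
    DESCENDING_AXON: "descending_axon",
    PARALLEL_FIBER: "parallel_fiber",
    DENDRITE: "dendrite",
}

SPHERE = 0
CYLINDER = 1

CHECKPOINT_MAGIC = b"CEREBDEV-CKPT-1\n"


class OutOfBoundsError(ValueError):
    """Proposed position lies outside the full simulation volume."""


class CollisionError(RuntimeError):
    """Proposed front overlaps existing structures.

    ``ids`` lists the colliding front ids.
    """

    def __init__(self, ids):
        self.ids = np.asarray(ids, dtype=np.int64)
        super().__init__(f"collision with fronts {self.ids.tolist()}")


class UnknownTreeError(KeyError):
    pass


class CheckpointError(IOError):
    pass


@dataclass(frozen=True)
class SimVolume:
    """Simulation volume: a central cube flanked by two wings along y.

    The main volume holds Purkinje and glia somata and granule cell births;
    the wings are origin sites of ingrowing parallel fibers.  Default bounds
    are the full-scale values in μm.
    """

    main_lo: tuple = (-20.0, -20.0, -20.0)
    main_hi: tuple = (180.0, 160.0, 140.0)
    full_lo: tuple = (-20.0, -160.0, -20.0)
    full_hi: tuple = (180.0, 300.0, 140.0)

    def __post_init__(self):
        ml, mh = np.asarray(self.main_lo), np.asarray(self.main_hi)
        fl, fh = np.asarray(self.full_lo), np.asarray(self.full_hi)
        if not (np.all(fl <= ml) and np.all(mh <= fh)):
            raise ValueError("main bounds must lie within full bounds")

    def contains(self, p) -> bool:
        p = np.asarray(p)
        return bool(np.all(p >= self.full_lo) and np.all(p <= self.full_hi))

    def in_main(self, p) -> bool:
        p = np.asarray(p)
        return bool(np.all(p >= self.main_lo) and np.all(p <= self.main_hi))


class Front:
    """Read-only proxy for a single front's fields."""

    __slots__ = ("scene", "id")

    def __init__(self, scene: "Scene", fid: int):
        self.scene = scene
        self.id = int(fid)

    @property
    def neuron_id(self):
        return int(self.scene.neuron_ids[self.id])

    @property
    def shape(self):
        return "sphere" if self.scene.shapes[self.id] == SPHERE else "cylinder"

    @property
    def orig(self):
        return self.scene.orig[self.id].copy()

    @property
    def end(self):
        return self.scene.end[self.id].copy()

    @property
    def radius(self):
        return float(self.scene.radii[self.id])

    @property
    def parent_id(self):
        p = int(self.scene.parents[self.id])
        return None if p < 0 else p

    @property
    def child_ids(self):
        return list(self.scene.children[self.id])

    @property
    def tree_index(self):
        t = int(self.scene.tree_indices[self.id])
        return None if t < 0 else t

    @property
    def structure_tag(self):
        return TAG_NAMES[int(self.scene.tags[self.id])]

    @property
    def birth_cycle(self):
        return int(self.scene.birth_cycles[self.id])

    @property
    def active(self):
        return bool(self.scene.active[self.id])

    @property
    def alive(self):
        return bool(self.scene.alive[self.id])

    @property
    def has_synapse(self):
        return bool(self.scene.has_synapse[self.id])

    @property
    def length(self):
        return float(np.linalg.norm(self.scene.end[self.id] - self.scene.orig[self.id]))

    def __repr__(self):
        return (f"Front(id={self.id}, tag={self.structure_tag}, "
                f"orig={self.orig.round(2).tolist()}, end={self.end.round(2).tolist()})")


@dataclass
class SynapseRecord:
    pre: int          # parallel-fiber front id
    post: int         # dendrite front id
    cycle_formed: int


class SynapseRegistry:
    """Registry of parallel-fiber → dendrite contacts.

    Each front can carry at most one synapse, so both ``pre`` and ``post``
    ids are unique across records.
    """

    def __init__(self):
        self.by_pre: dict[int, SynapseRecord] = {}
        self.by_post: dict[int, SynapseRecord] = {}

    def __len__(self):
        return len(self.by_pre)

    def records(self):
        return list(self.by_pre.values())

    def add(self, scene: "Scene", pre: int, post: int) -> SynapseRecord | None:
        if pre in self.by_pre or post in self.by_post:
            return None
        if scene.has_synapse[pre] or scene.has_synapse[post]:
            return None
        rec = SynapseRecord(int(pre), int(post), int(scene.cycle))
        self.by_pre[rec.pre] = rec
        self.by_post[rec.post] = rec
        scene.has_synapse[pre] = True
        scene.has_synapse[post] = True
        return rec

    def remove_front(self, scene: "Scene", fid: int):
        rec = self.by_pre.get(fid) or self.by_post.get(fid)
        if rec is None:
            return
        del self.by_pre[rec.pre]
        del self.by_post[rec.post]
        scene.has_synapse[rec.pre] = False
        scene.has_synapse[rec.post] = False

    def count_for_tree(self, scene: "Scene", neuron_id: int, tree_index: int) -> int:
        return sum(
            1
            for rec in self.by_post.values()
            if scene.neuron_ids[rec.post] == neuron_id
            and scene.tree_indices[rec.post] == tree_index
        )


class Scene:
    """All fronts, the spatial index, the synapse registry and the clock."""

    def __init__(
        self,
        volume: SimVolume | None = None,
        seed: int = 0,
        voxel: float = 10.0,
        tolerance: float = 0.01,
        capacity: int = 4096,
    ):
        self.volume = volume or SimVolume()
        self.seed = int(seed)
        self.voxel = float(voxel)
        self.tolerance = float(tolerance)
        self.cycle = 0
        self.rng = np.random.default_rng(self.seed)

        self.n = 0
        self._cap = capacity
        self.orig = np.zeros((capacity, 3))
        self.end = np.zeros((capacity, 3))
        self.radii = np.zeros(capacity)
        self.neuron_ids = np.full(capacity, -1, dtype=np.int32)
        self.parents = np.full(capacity, -1, dtype=np.int32)
        self.tags = np.zeros(capacity, dtype=np.int8)
        self.shapes = np.zeros(capacity, dtype=np.int8)
        self.tree_indices = np.full(capacity, -1, dtype=np.int8)
        self.birth_cycles = np.zeros(capacity, dtype=np.int16)
        self.active = np.zeros(capacity, dtype=bool)
        self.alive = np.zeros(capacity, dtype=bool)
        self.has_synapse = np.zeros(capacity, dtype=bool)

        self.children: list[list[int]] = []
        self.grid: dict[tuple, list[int]] = {}
        self._voxel_keys: list[tuple] = []   # (klo, khi) per front for removal
        self.synapses = SynapseRegistry()
        self.neurons: list = []              # cell objects, appended by builders

    # ---------------------------------------------------------------- storage

    def _ensure(self, extra: int = 1):
        if self.n + extra <= self._cap:
            return
        new_cap = max(self._cap * 2, self.n + extra)
        for name in ("orig", "end"):
            arr = getattr(self, name)
            new = np.zeros((new_cap, 3))
            new[: self.n] = arr[: self.n]
            setattr(self, name, new)
        for name, fill, dt in (
            ("radii", 0.0, float),
            ("neuron_ids", -1, np.int32),
            ("parents", -1, np.int32),
            ("tags", 0, np.int8),
            ("shapes", 0, np.int8),
            ("tree_indices", -1, np.int8),
            ("birth_cycles", 0, np.int16),
            ("active", False, bool),
            ("alive", False, bool),
            ("has_synapse", False, bool),
        ):
            arr = getattr(self, name)
            new = np.full(new_cap, fill, dtype=dt)
            new[: self.n] = arr[: self.n]
            setattr(self, name, new)
        self._cap = new_cap

    # ------------------------------------------------------------ spatial index

    def _voxel_range(self, lo, hi):
        klo = np.floor(np.asarray(lo) / self.voxel).astype(int)
        khi = np.floor(np.asarray(hi) / self.voxel).astype(int)
        return klo, khi

    def _index_insert(self, fid: int):
        r = self.radii[fid]
        lo = np.minimum(self.orig[fid], self.end[fid]) - r
        hi = np.maximum(self.orig[fid], self.end[fid]) + r
        klo, khi = self._voxel_range(lo, hi)
        self._voxel_keys.append((tuple(klo), tuple(khi)))
        for i in range(klo[0], khi[0] + 1):
            for j in range(klo[1], khi[1] + 1):
                for k in range(klo[2], khi[2] + 1):
                    self.grid.setdefault((i, j, k), []).append(fid)

    def _index_remove(self, fid: int):
        klo, khi = self._voxel_keys[fid]
        for i in range(klo[0], khi[0] + 1):
            for j in range(klo[1], khi[1] + 1):
                for k in range(klo[2], khi[2] + 1):
                    cell = self.grid.get((i, j, k))
                    if cell is not None:
                        try:
                            cell.remove(fid)
                        except ValueError:
                            pass

    def _index_update(self, fid: int):
        self._index_remove(fid)
        r = self.radii[fid]
        lo = np.minimum(self.orig[fid], self.end[fid]) - r
        hi = np.maximum(self.orig[fid], self.end[fid]) + r
        klo, khi = self._voxel_range(lo, hi)
        self._voxel_keys[fid] = (tuple(klo), tuple(khi))
        for i in range(klo[0], khi[0] + 1):
            for j in range(klo[1], khi[1] + 1):
                for k in range(klo[2], khi[2] + 1):
                    self.grid.setdefault((i, j, k), []).append(fid)

    def _candidates(self, lo, hi) -> np.ndarray:
        """Alive front ids whose inflated AABB may overlap box [lo, hi]."""
        klo, khi = self._voxel_range(lo, hi)
        out: list[int] = []
        grid = self.grid
        for i in range(klo[0], khi[0] + 1):
            for j in range(klo[1], khi[1] + 1):
                for k in range(klo[2], khi[2] + 1):
                    cell = grid.get((i, j, k))
                    if cell:
                        out.extend(cell)
        if not out:
            return np.empty(0, dtype=np.int64)
        ids = np.fromiter(set(out), dtype=np.int64)
        ids.sort()
        return ids[self.alive[ids]]

    # -------------------------------------------------------------- primitives

    def add_front(
        self,
        neuron_id: int,
        orig,
        end,
        radius: float,
        tag: int,
        parent: int = -1,
        tree_index: int = -1,
        shape: int = CYLINDER,
        active: bool = True,
    ) -> int:
        """Insert a front without collision checking (trusted construction)."""
        self._ensure(1)
        fid = self.n
        self.n += 1
        self.orig[fid] = orig
        self.end[fid] = end
        self.radii[fid] = radius
        self.neuron_ids[fid] = neuron_id
        self.parents[fid] = parent
        self.tags[fid] = tag
        self.shapes[fid] = shape
        self.tree_indices[fid] = tree_index
        self.birth_cycles[fid] = self.cycle
        self.active[fid] = active
        self.alive[fid] = True
        self.has_synapse[fid] = False
        self.children.append([])
        if parent >= 0:
            self.children[parent].append(fid)
        self._index_insert(fid)
        return fid

    def collision_ids(
        self,
        p0,
        p1,
        radius: float,
        exclude_ids=(),
        exclude_neuron: int | None = None,
        shared_point=None,
    ) -> np.ndarray:
        """Front ids overlapping the capsule ``p0→p1`` of given radius.

        ``exclude_ids`` are never reported (parent, self during moves);
        fronts that share endpoint ``shared_point`` (branching siblings of
        the same neuron) are exempt, as is any front of ``exclude_neuron``.
        """
        p0 = np.asarray(p0, dtype=float)
        p1 = np.asarray(p1, dtype=float)
        pad = radius + self.tolerance
        lo = np.minimum(p0, p1) - pad
        hi = np.maximum(p0, p1) + pad
        ids = self._candidates(lo, hi)
        if ids.size == 0:
            return ids
        mask = np.ones(ids.size, dtype=bool)
        for ex in exclude_ids:
            mask &= ids != ex
        if exclude_neuron is not None:
            mask &= self.neuron_ids[ids] != exclude_neuron
        ids = ids[mask]
        if ids.size == 0:
            return ids
        d = seg_seg_dist_many(p0, p1, np.ascontiguousarray(self.orig[ids]),
                              np.ascontiguousarray(self.end[ids]))
        hit = d < (radius + self.radii[ids] - self.tolerance)
        ids = ids[hit]
        if ids.size and shared_point is not None:
            sp = np.asarray(shared_point, dtype=float)
            near_o = np.linalg.norm(self.orig[ids] - sp, axis=1) < 1e-6
            near_e = np.linalg.norm(self.end[ids] - sp, axis=1) < 1e-6
            ids = ids[~(near_o | near_e)]
        return ids

    def free_segments(self, starts, ends, radius: float,
                      exclude_ids=(), exclude_neuron: int | None = None,
                      shared_point=None) -> np.ndarray:
        """Batched collision test: which proposed capsules are placeable.

        ``starts``/``ends`` are (K, 3); returns a boolean (K,) array, False
        where the capsule would overlap an obstacle or leave the volume.
        Obstacles are gathered once for the union bounding box, so testing a
        probe fan costs one grid gather plus one kernel call.
        """
        starts = np.atleast_2d(np.asarray(starts, dtype=float))
        ends = np.atleast_2d(np.asarray(ends, dtype=float))
        inb = (np.all(ends >= self.volume.full_lo, axis=1)
               & np.all(ends <= self.volume.full_hi, axis=1)
               & np.all(starts >= self.volume.full_lo, axis=1)
               & np.all(starts <= self.volume.full_hi, axis=1))
        pad = radius + self.tolerance
        lo = np.minimum(starts.min(axis=0), ends.min(axis=0)) - pad
        hi = np.maximum(starts.max(axis=0), ends.max(axis=0)) + pad
        ids = self._candidates(lo, hi)
        if ids.size:
            mask = np.ones(ids.size, dtype=bool)
            for ex in exclude_ids:
                mask &= ids != ex
            if exclude_neuron is not None:
                mask &= self.neuron_ids[ids] != exclude_neuron
            ids = ids[mask]
        if ids.size and shared_point is not None:
            sp = np.asarray(shared_point, dtype=float)
            near_o = np.linalg.norm(self.orig[ids] - sp, axis=1) < 1e-6
            near_e = np.linalg.norm(self.end[ids] - sp, axis=1) < 1e-6
            ids = ids[~(near_o | near_e)]
        if ids.size == 0:
            return inb
        ok = segments_free(
            np.ascontiguousarray(starts), np.ascontiguousarray(ends),
            float(radius),
            np.ascontiguousarray(self.orig[ids]),
            np.ascontiguousarray(self.end[ids]),
            np.ascontiguousarray(self.radii[ids]), self.tolerance)
        return ok & inb

    # --------------------------------------------------------------- operations

    def grow_front(
        self,
        parent: int,
        proposed_end,
        radius: float,
        tag: int,
        tree_index: int | None = None,
    ) -> int:
        """Grow a child cylinder from ``parent``'s distal point to ``proposed_end``.

        On success the child is linked and active and the parent is
        deactivated (fronts are usually active during one cycle only).
        Raises :class:`OutOfBoundsError` or :class:`CollisionError` (scene
        unchanged, colliding ids reported).
        """
        proposed_end = np.asarray(proposed_end, dtype=float)
        if not self.volume.contains(proposed_end):
            raise OutOfBoundsError(f"{proposed_end.tolist()} outside full bounds")
        start = self.end[parent] if self.shapes[parent] == CYLINDER else self.orig[parent]
        if tree_index is None:
            tree_index = int(self.tree_indices[parent])
        hits = self.collision_ids(
            start, proposed_end, radius,
            exclude_ids=(parent,), shared_point=start,
        )
        if hits.size:
            raise CollisionError(hits)
        fid = self.add_front(
            int(self.neuron_ids[parent]), start, proposed_end, radius, tag,
            parent=parent, tree_index=tree_index,
        )
        self.active[parent] = False
        return fid

    def query_neighbors(self, point, radius: float, tags=None) -> np.ndarray:
        """Ids of alive fronts whose axis segment lies within ``radius`` of ``point``."""
        if radius <= 0:
            return np.empty(0, dtype=np.int64)
        point = np.asarray(point, dtype=float)
        ids = self._candidates(point - radius, point + radius)
        if ids.size == 0:
            return ids
        if tags is not None:
            tagset = {tags} if np.isscalar(tags) else set(tags)
            mask = np.isin(self.tags[ids], list(tagset))
            ids = ids[mask]
            if ids.size == 0:
                return ids
        d = point_segment_distance(point, self.orig[ids], self.end[ids])
        return ids[d <= radius]

    def solve_collision(self, mover: int, target, exclude_neuron=None,
                        max_probes: int = 20, step: float = 1.0):
        """Bypass search for a blocked move.

        Probes up to ``max_probes`` candidate positions on an outward spiral
        around the blocked direction (1 μm radial step per turn); returns the
        first collision-free position that reduces the distance to ``target``,
        or ``None``.  If the direct move is actually free, returns ``target``.
        """
        target = np.asarray(target, dtype=float)
        r = float(self.radii[mover])
        cur = self.orig[mover] if self.shapes[mover] == SPHERE else self.end[mover]
        d0 = float(np.linalg.norm(target - cur))
        axis = target - cur
        nrm = np.linalg.norm(axis)
        axis = axis / nrm if nrm > 1e-12 else np.array([0.0, 0.0, 1.0])
        # two vectors orthogonal to the blocked direction
        ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(axis, ref)
        u /= np.linalg.norm(u)
        v = np.cross(axis, u)
        golden = 2.399963229728653  # radians; spreads probes evenly in angle
        cands = [target]
        for i in range(max_probes):
            rad = step * (1 + i // 4)
            ang = golden * i
            cand = target + rad * (np.cos(ang) * u + np.sin(ang) * v)
            if np.linalg.norm(cand - target) < d0:  # progress toward target
                cands.append(cand)
        cands = np.asarray(cands)
        # a migrating sphere must sweep a clear capsule from its current
        # position to the candidate, not merely fit at the endpoint
        starts = np.broadcast_to(cur, cands.shape)
        ok = self.free_segments(starts, cands, r, exclude_ids=(mover,),
                                exclude_neuron=exclude_neuron)
        for i in range(len(cands)):
            if ok[i]:
                return cands[i]
        return None

    def alternate_location(self, parent: int, heading, step: float,
                           radius: float, max_lateral: float = 2.0):
        """Alternative end position for a blocked fiber extension.

        Searches laterally around the intended heading (≤ ``max_lateral`` μm
        displacement, heading preserved) and returns a collision-free end
        position, or ``None`` when the whole search cone is blocked.  An
        unblocked call returns the straight-ahead position.
        """
        heading = np.asarray(heading, dtype=float)
        heading = heading / np.linalg.norm(heading)
        start = self.end[parent] if self.shapes[parent] == CYLINDER else self.orig[parent]
        straight = start + step * heading
        ref = np.array([0.0, 0.0, 1.0]) if abs(heading[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        u = np.cross(heading, ref)
        u /= np.linalg.norm(u)
        v = np.cross(heading, u)
        ends = [straight]
        for frac in (0.35, 0.7, 1.0):
            off = frac * max_lateral
            for ang in np.linspace(0, 2 * np.pi, 8, endpoint=False):
                ends.append(straight + off * (np.cos(ang) * u + np.sin(ang) * v))
        ends = np.asarray(ends)
        starts = np.broadcast_to(start, ends.shape)
        ok = self.free_segments(starts, ends, radius, exclude_ids=(parent,),
                                shared_point=start)
        for i in range(len(ends)):
            if ok[i]:
                return ends[i]
        return None

    def migrate_soma(self, soma: int, new_center, exclude_neuron_own: bool = True):
        """Move a spherical soma, bypassing obstacles if needed.

        The whole path from the old to the new center is collision-checked
        (swept sphere).  The soma's own neuron's fronts are exempt: a
        migrating soma slides along its own leading process and trailing
        axon.  Returns the final center on success or ``None`` when blocked.
        """
        new_center = np.asarray(new_center, dtype=float)
        if not self.volume.contains(new_center):
            return None
        nid = int(self.neuron_ids[soma]) if exclude_neuron_own else None
        r = float(self.radii[soma])
        hits = self.collision_ids(self.orig[soma], new_center, r,
                                  exclude_ids=(soma,), exclude_neuron=nid)
        pos = new_center
        if hits.size:
            pos = self.solve_collision(soma, new_center, exclude_neuron=nid,
                                       step=2.0)
            if pos is None:
                return None
        self.orig[soma] = pos
        self.end[soma] = pos
        self._index_update(soma)
        return pos

    def remove_front(self, fid: int):
        """Delete a single front (e.g. a leading-process front absorbed by
        the migrating soma).  Children are re-parented to the front's parent."""
        p = int(self.parents[fid])
        for c in self.children[fid]:
            self.parents[c] = p
            if p >= 0:
                self.children[p].append(c)
        self.children[fid] = []
        if p >= 0 and fid in self.children[p]:
            self.children[p].remove(fid)
        self.alive[fid] = False
        self.active[fid] = False
        self.synapses.remove_front(self, fid)
        self._index_remove(fid)

    def tree_front_ids(self, neuron_id: int, tree_index: int) -> np.ndarray:
        ids = np.nonzero(
            self.alive[: self.n]
            & (self.neuron_ids[: self.n] == neuron_id)
            & (self.tree_indices[: self.n] == tree_index)
        )[0]
        return ids

    def retract_tree(self, neuron_id: int, tree_index: int) -> int:
        """Remove an entire dendritic tree (all fronts with that tree index).

        Deletes the fronts from scene and index, removes their synapses and
        returns the number of fronts removed.  Max path length of a retracted
        tree is 0 afterwards.
        """
        ids = self.tree_front_ids(neuron_id, tree_index)
        if ids.size == 0:
            raise UnknownTreeError((neuron_id, tree_index))
        for fid in ids:
            fid = int(fid)
            self.alive[fid] = False
            self.active[fid] = False
            self.synapses.remove_front(self, fid)
            self._index_remove(fid)
            p = int(self.parents[fid])
            if p >= 0 and fid in self.children[p]:
                self.children[p].remove(fid)
        return int(ids.size)

    # -------------------------------------------------------------- checkpoint

    def save_checkpoint(self, path):
        """Serialise the full scene (fronts, synapses, neurons, RNG, cycle).

        The file is a versioned pickle container; loading a file whose magic
        header does not match raises :class:`CheckpointError`.  Round-trips
        are bit-exact, so a saved migration stage can seed several scenarios.
        """
        payload = self.__dict__.copy()
        with open(path, "wb") as fh:
            fh.write(CHECKPOINT_MAGIC)
            pickle.dump(payload, fh, protocol=pickle.HIGHEST_PROTOCOL)

    @classmethod
    def load_checkpoint(cls, path) -> "Scene":
        with open(path, "rb") as fh:
            magic = fh.read(len(CHECKPOINT_MAGIC))
            if magic != CHECKPOINT_MAGIC:
                raise CheckpointError(f"{path}: not a cerebdev checkpoint")
            try:
                payload = pickle.load(fh)
            except Exception as exc:
                raise CheckpointError(f"{path}: corrupt checkpoint") from exc
        scene = cls.__new__(cls)
        scene.__dict__.update(payload)
        for cell in scene.neurons:
            cell.scene = scene
        return scene

    # ------------------------------------------------------------------ audits

    def front(self, fid: int) -> Front:
        return Front(self, fid)

    def alive_ids(self) -> np.ndarray:
        return np.nonzero(self.alive[: self.n])[0]

    def overlap_violations(self, brute: bool = False) -> list[tuple[int, int]]:
        """All-pairs overlap audit (for tests and end-of-run checks).

        By default candidate pairs come from the spatial index (equivalent
        to the quadratic scan because the index is conservative; ``brute``
        forces the plain all-pairs computation).  Pairs sharing an endpoint
        or linked parent–child are exempt, as are pairs within the same
        neuron (migrating somata legitimately touch their own leading
        process and axon trail).
        """
        ids = self.alive_ids()
        bad = []
        for ii, fid in enumerate(ids):
            if brute:
                rest = ids[ii + 1:]
            else:
                r = self.radii[fid]
                lo = np.minimum(self.orig[fid], self.end[fid]) - r - self.tolerance
                hi = np.maximum(self.orig[fid], self.end[fid]) + r + self.tolerance
                rest = self._candidates(lo, hi)
                rest = rest[rest > fid]
            if rest.size == 0:
                continue
            d = seg_seg_dist_many(
                self.orig[fid], self.end[fid],
                np.ascontiguousarray(self.orig[rest]),
                np.ascontiguousarray(self.end[rest]))
            hit = rest[d < self.radii[fid] + self.radii[rest] - self.tolerance]
            for other in hit:
                other = int(other)
                if self.neuron_ids[fid] == self.neuron_ids[other]:
                    continue
                if self.parents[other] == fid or self.parents[fid] == other:
                    continue
                ends_f = (self.orig[fid], self.end[fid])
                ends_o = (self.orig[other], self.end[other])
                if any(np.linalg.norm(a - b) < 1e-6 for a in ends_f for b in ends_o):
                    continue
                bad.append((int(fid), other))
        return bad
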