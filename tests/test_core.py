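"""Engine kernel: growth, collision, queries, retraction, checkpointing."""

import numpy as np
import pytest

from cerebdev.core import (
    DENDRITE,
    GLIA_PROCESS,
    PARALLEL_FIBER,
    CheckpointError,
    CollisionError,
    OutOfBoundsError,
    Scene,
    SimVolume,
    UnknownTreeError,
)
from cerebdev.geometry import point_segment_distance, segment_segment_distance

from conftest import make_soma, scatter_fronts


def test_volume_requires_nested_bounds():
    with pytest.raises(ValueError):
        SimVolume((0, 0, 0), (10, 10, 10), (1, 1, 1), (5, 5, 5))


class TestGrowFront:
    def test_growth_in_empty_scene(self, scene):
        soma = make_soma(scene, (0, 0, 0), radius=2.0)
        child = scene.grow_front(soma, (0, 0, 4), 0.5, DENDRITE)
        f = scene.front(child)
        assert f.structure_tag == "dendrite"
        assert f.parent_id == soma
        assert child in scene.front(soma).child_ids
        assert f.active and not scene.front(soma).active

    def test_out_of_bounds_end_rejected(self, scene):
        soma = make_soma(scene, (0, 0, 130), radius=2.0)
        with pytest.raises(OutOfBoundsError):
            scene.grow_front(soma, (0, 0, 141), 0.5, DENDRITE)

    def test_collision_reports_blocking_front(self, scene):
        make_soma(scene, (0, 0, 0), radius=2.0, neuron_id=0)
        blocker = scene.add_front(1, (-3, 2, 5), (3, 2, 5), 0.5, PARALLEL_FIBER)
        soma2 = make_soma(scene, (0, 2, 1), radius=0.8, neuron_id=2)
        with pytest.raises(CollisionError) as err:
            scene.grow_front(soma2, (0, 2, 8), 0.5, DENDRITE)
        assert blocker in err.value.ids
        # scene unchanged: the failed child was never inserted
        assert not scene.alive[scene.n - 1] or scene.n - 1 == soma2

    def test_collision_detection_matches_brute_force(self):
        """200 random fronts; proposed segments accepted/rejected exactly as
        an all-pairs capsule-distance oracle says."""
        scene = Scene(seed=3)
        rng = np.random.default_rng(42)
        scatter_fronts(scene, 200, rng, lo=(0, 0, 0), hi=(60, 60, 60))
        parent = make_soma(scene, (70.0, 70.0, 70.0), radius=1.0, neuron_id=999)
        agree = 0
        for _ in range(100):
            end = rng.uniform((0, 0, 0), (70, 70, 70))
            ids = scene.alive_ids()
            ids = ids[ids != parent]
            d = segment_segment_distance(scene.orig[parent], end,
                                         scene.orig[ids], scene.end[ids])
            oracle_hit = np.any(d < 0.5 + scene.radii[ids] - scene.tolerance)
            try:
                child = scene.grow_front(parent, end, 0.5, DENDRITE)
                engine_hit = False
                # undo so the probe does not change the scene
                scene.remove_front(child)
                scene.active[parent] = True
            except CollisionError:
                engine_hit = True
            assert engine_hit == oracle_hit
            agree += 1
        assert agree == 100


class TestQueryNeighbors:
    def test_zero_radius_empty(self, scene):
        assert scene.query_neighbors((0, 0, 0), 0.0).size == 0

    def test_matches_linear_scan(self):
        scene = Scene(seed=1)
        rng = np.random.default_rng(7)
        scatter_fronts(scene, 100, rng, lo=(0, 0, 0), hi=(80, 80, 80))
        for _ in range(50):
            p = rng.uniform((0, 0, 0), (80, 80, 80))
            got = set(scene.query_neighbors(p, 10.0).tolist())
            ids = scene.alive_ids()
            d = point_segment_distance(p, scene.orig[ids], scene.end[ids])
            want = set(ids[d <= 10.0].tolist())
            assert got == want

    def test_tag_filter(self, scene):
        scene.add_front(0, (0, 0, 0), (0, 0, 5), 0.5, DENDRITE)
        assert scene.query_neighbors((0, 0, 2), 5, tags=PARALLEL_FIBER).size == 0
        assert scene.query_neighbors((0, 0, 2), 5, tags=DENDRITE).size == 1


class TestSolveCollision:
    def test_spurious_call_returns_target(self, scene):
        soma = make_soma(scene, (0, 0, 0), radius=1.0)
        tgt = np.array([0, 0, -5.0])
        pos = scene.solve_collision(soma, tgt)
        assert np.allclose(pos, tgt)

    def test_bypass_around_thin_obstacle(self, scene):
        soma = make_soma(scene, (0, 0, 10), radius=1.0, neuron_id=0)
        scene.add_front(1, (-8, 0, 5), (8, 0, 5), 0.5, PARALLEL_FIBER)
        tgt = np.array([0, 0, 0.0])
        pos = scene.solve_collision(soma, tgt)
        assert pos is not None
        # returned position is collision-free and closer to the target
        hits = scene.collision_ids(pos, pos, 1.0, exclude_ids=(soma,))
        assert hits.size == 0
        assert np.linalg.norm(pos - tgt) < np.linalg.norm(
            scene.orig[soma] - tgt)

    def test_enclosed_mover_fails(self, scene):
        soma = make_soma(scene, (0, 0, 0), radius=2.0, neuron_id=0)
        # cage of crossing fibers directly below and around
        for z in (-4, -6, -8):
            for x in (-4, -2, 0, 2, 4):
                scene.add_front(1, (x, -8, z), (x, 8, z), 1.2, PARALLEL_FIBER)
        assert scene.solve_collision(soma, np.array([0, 0, -6.0])) is None


class TestAlternateLocation:
    def test_unblocked_returns_straight_ahead(self, scene):
        soma = make_soma(scene, (0, 0, 0), radius=1.0)
        pos = scene.alternate_location(soma, (0, 1, 0), 5.0, 0.5)
        assert np.allclose(pos, [0, 5, 0])

    def test_lateral_offset_with_preserved_heading(self, scene):
        tip = scene.add_front(0, (0, 0, 10), (0, 5, 10), 0.5, PARALLEL_FIBER)
        scene.add_front(1, (-5, 10, 10), (5, 10, 10), 0.8, DENDRITE)
        pos = scene.alternate_location(tip, (0, 1, 0), 5.0, 0.5)
        assert pos is not None
        assert pos[1] > 5.0  # heading sign preserved
        assert np.linalg.norm(pos - np.array([0, 10, 10])) <= 2.0 + 1e-9
        hits = scene.collision_ids(scene.end[tip], pos, 0.5,
                                   exclude_ids=(tip,),
                                   shared_point=scene.end[tip])
        assert hits.size == 0

    def test_dense_wall_returns_none(self, scene):
        tip = scene.add_front(0, (0, 0, 10), (0, 5, 10), 0.5, PARALLEL_FIBER)
        for dx in np.arange(-4, 4.5, 1.0):
            for dz in np.arange(-4, 4.5, 1.0):
                scene.add_front(1, (dx - 0.4, 9, 10 + dz),
                                (dx + 0.4, 9, 10 + dz), 0.45, DENDRITE)
        assert scene.alternate_location(tip, (0, 1, 0), 5.0, 0.5,
                                        max_lateral=2.0) is None


class TestRetractTree:
    def _build_tree(self, scene, neuron_id=0, tree=0, n=10):
        soma = make_soma(scene, (neuron_id * 30, 0, 0), radius=3.0,
                         neuron_id=neuron_id)
        fid = scene.grow_front(soma, (neuron_id * 30, 0, 5), 0.5, DENDRITE,
                               tree_index=tree)
        ids = [fid]
        for i in range(n - 1):
            fid = scene.grow_front(fid, (neuron_id * 30, 0, 10 + 5 * i),
                                   0.5, DENDRITE)
            ids.append(fid)
        return soma, ids

    def test_removal_counts_and_synapses(self, scene):
        _, ids = self._build_tree(scene, n=8)
        pf = scene.add_front(7, (10, -5, 20), (10, 5, 20), 0.5, PARALLEL_FIBER)
        scene.synapses.add(scene, pre=pf, post=ids[3])
        assert len(scene.synapses) == 1
        removed = scene.retract_tree(0, 0)
        assert removed == 8
        assert len(scene.synapses) == 0
        assert not scene.has_synapse[pf]  # partner freed
        assert not scene.alive[ids].any()

    def test_other_neuron_untouched(self, scene):
        self._build_tree(scene, neuron_id=0, n=5)
        _, other = self._build_tree(scene, neuron_id=1, n=5)
        scene.retract_tree(0, 0)
        assert scene.alive[other].all()

    def test_unknown_tree_raises(self, scene):
        make_soma(scene, (0, 0, 0))
        with pytest.raises(UnknownTreeError):
            scene.retract_tree(0, 3)


class TestCheckpoint:
    def test_round_trip_preserves_state(self, scene, tmp_path):
        rng = np.random.default_rng(0)
        scatter_fronts(scene, 30, rng)
        scene.cycle = 65
        path = tmp_path / "ck.pkl"
        scene.save_checkpoint(path)
        loaded = Scene.load_checkpoint(path)
        assert loaded.cycle == 65
        assert loaded.n == scene.n
        np.testing.assert_array_equal(loaded.orig[: scene.n],
                                      scene.orig[: scene.n])
        np.testing.assert_array_equal(loaded.alive[: scene.n],
                                      scene.alive[: scene.n])

    def test_truncated_file_rejected(self, tmp_path):
        path = tmp_path / "bad.pkl"
        path.write_bytes(b"CEREBDEV-CKPT-1\n\x00\x01trunc")
        with pytest.raises(CheckpointError):
            Scene.load_checkpoint(path)

    def test_wrong_magic_rejected(self, tmp_path):
        path = tmp_path / "other.pkl"
        path.write_bytes(b"NOTACHECKPOINT!!" * 4)
        with pytest.raises(CheckpointError):
            Scene.load_checkpoint(path)


def test_overlap_audit_clean_after_checked_growth():
    """Three cells growing blindly into shared space stay overlap-free
    because every insertion is collision-checked."""
    scene = Scene(seed=5)
    rng = np.random.default_rng(11)
    tips = {}
    for nid, pos in enumerate([(45, 50, 50), (55, 50, 50), (50, 57, 50)]):
        tips[nid] = [make_soma(scene, pos, radius=3.0, neuron_id=nid)]
    for _ in range(150):
        nid = int(rng.integers(3))
        parent = tips[nid][rng.integers(len(tips[nid]))]
        start = scene.end[parent] if scene.shapes[parent] else scene.orig[parent]
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        try:
            child = scene.grow_front(parent, start + 5 * d, 0.6, DENDRITE)
            tips[nid].append(child)
        except (CollisionError, OutOfBoundsError):
            pass
    assert sum(len(v) for v in tips.values()) > 20  # growth actually happened
    assert scene.overlap_violations() == []


def test_indexed_audit_equals_brute_force_audit():
    scene = Scene(seed=9)
    rng = np.random.default_rng(17)
    # multiple neurons, deliberately unchecked insertion so overlaps exist
    for i in range(300):
        a = rng.uniform((0, 0, 0), (60, 60, 60))
        d = rng.normal(size=3)
        d = d / np.linalg.norm(d) * 5.0
        scene.add_front(i % 40, a, a + d, 0.6, DENDRITE)
    fast = set(map(tuple, scene.overlap_violations()))
    slow = set(map(tuple, scene.overlap_violations(brute=True)))
    assert fast == slow
    assert len(slow) > 0
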