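"""Granule cell state machine: targeting, migration kinematics, T-junction,
parallel fiber extension and firing rates."""

import numpy as np
import pytest

from cerebdev import granule as gr
from cerebdev.core import DESCENDING_AXON, PARALLEL_FIBER, SOMA, SPHERE, Scene
from cerebdev.glia import extend_glia_processes, init_bergmann


def make_gc(scene, pos, nid=10, radius=1.2, phase=1, seed=1):
    p = np.asarray(pos, dtype=float)
    sid = scene.add_front(nid, p, p, radius, SOMA, shape=SPHERE, active=False)
    return gr.GranuleCell(neuron_id=nid, soma_id=sid, birth_phase=phase,
                          rng=np.random.default_rng([seed, nid]))


@pytest.fixture
def scaffold_scene():
    """One fully grown glia scaffold at (50, 50)."""
    scene = Scene(seed=0)
    glia = init_bergmann(scene, (50.0, 50.0, 0.0), neuron_id=0)
    for _ in range(40):
        extend_glia_processes(scene, glia)
    return scene, glia


class TestTargetSelection:
    def test_single_glia_selected(self, scaffold_scene):
        scene, _ = scaffold_scene
        gc = make_gc(scene, (60, 52, 80))
        fid = gr.select_target_process(scene, gc)
        assert fid >= 0
        assert gc.state == gr.HORIZONTAL
        assert scene.front(fid).structure_tag == "glia_process"

    def test_empty_scene_fails(self):
        scene = Scene(seed=0)
        gc = make_gc(scene, (50, 50, 80))
        assert gr.select_target_process(scene, gc) == -1
        assert gc.state == gr.FAILED

    def test_equidistant_tie_breaks_to_lowest_id(self):
        scene = Scene(seed=0)
        a = scene.add_front(0, (40, 50, 78), (40, 50, 82), 0.8, 1)  # glia tag
        b = scene.add_front(1, (60, 50, 78), (60, 50, 82), 0.8, 1)
        scene.tags[a] = scene.tags[b] = 1
        gc = make_gc(scene, (50, 50, 80))
        assert gr.select_target_process(scene, gc) == min(a, b)


class TestMigrationKinematics:
    def test_horizontal_reach_time(self, scaffold_scene):
        """Unobstructed approach: the soma reaches contact within the
        distance/step budget plus the one-front lag of the leading process."""
        scene, _ = scaffold_scene
        gc = make_gc(scene, (70, 50, 80))
        gr.select_target_process(scene, gc)
        d0 = np.hypot(*(gc.target_xy - scene.orig[gc.soma_id][:2]))
        budget = int(np.ceil(d0 / 4.0)) + 3
        for i in range(budget + 1):
            if gr.horizontal_step(scene, gc) == "reached":
                break
        assert gc.state == gr.RADIAL
        assert i <= budget

    def test_radial_descent_and_arrival(self, scaffold_scene):
        scene, _ = scaffold_scene
        gc = make_gc(scene, (56, 50, 85))
        gr.select_target_process(scene, gc)
        while gr.horizontal_step(scene, gc) != "reached":
            pass
        gr.begin_radial(scene, gc)
        z0 = scene.orig[gc.soma_id][2]
        steps = 0
        while gc.state == gr.RADIAL and steps < 60:
            gr.radial_step(scene, gc)
            steps += 1
        assert gc.state == gr.ARRIVED
        assert scene.orig[gc.soma_id][2] <= gr.ARRIVAL_Z + 1e-9
        # descent takes at least the unobstructed minimum number of steps
        assert steps >= int(np.floor((z0 - gr.ARRIVAL_Z) / 5.0))

    def test_axon_trail_is_continuous(self, scaffold_scene):
        scene, _ = scaffold_scene
        gc = make_gc(scene, (56, 50, 85))
        gr.select_target_process(scene, gc)
        while gr.horizontal_step(scene, gc) != "reached":
            pass
        gr.begin_radial(scene, gc)
        while gc.state == gr.RADIAL:
            gr.radial_step(scene, gc)
        # walk the deposited chain: every front starts where its parent
        # ended; the chain hangs off the axon root's origin (the root itself
        # is the short upward stub whose distal end is the T-junction)
        fid = gc.axon_tip
        count = 0
        while int(scene.parents[fid]) != gc.axon_root:
            p = int(scene.parents[fid])
            np.testing.assert_allclose(scene.orig[fid], scene.end[p])
            fid = p
            count += 1
        np.testing.assert_allclose(scene.orig[fid], scene.orig[gc.axon_root])
        assert count > 10

    def test_arrival_request_at_floor_is_noop(self, scaffold_scene):
        scene, _ = scaffold_scene
        gc = make_gc(scene, (56, 50, -15.5))
        gc.target_xy = np.array([50.0, 50.0])
        gc.target_front = 1
        gc.state = gr.RADIAL
        assert gr.radial_step(scene, gc) == "arrived"
        assert gc.state == gr.ARRIVED

    def test_begin_radial_idempotent(self, scaffold_scene):
        scene, _ = scaffold_scene
        gc = make_gc(scene, (56, 50, 85))
        gr.select_target_process(scene, gc)
        while gr.horizontal_step(scene, gc) != "reached":
            pass
        gr.begin_radial(scene, gc)
        root = gc.axon_root
        n = scene.n
        gr.begin_radial(scene, gc)
        assert gc.axon_root == root
        assert scene.n == n


class TestTJunction:
    def _descending_cell(self, scene):
        gc = make_gc(scene, (56, 50, 85))
        gr.select_target_process(scene, gc)
        while gr.horizontal_step(scene, gc) != "reached":
            pass
        gr.begin_radial(scene, gc)
        gr.radial_step(scene, gc)
        return gc

    def test_two_branches_perpendicular(self, scaffold_scene):
        scene, _ = scaffold_scene
        gc = self._descending_cell(scene)
        res = gr.bifurcate_pf(scene, gc)
        assert res == "ok"
        assert len(gc.branches) == 2
        assert {b.sign for b in gc.branches} == {1, -1}
        jz = scene.end[gc.junction][2]
        for b in gc.branches:
            f = scene.front(b.tip)
            d = f.end - f.orig
            assert abs(d[0]) < 1e-6 and abs(d[2]) < 1e-6  # pure ±y
            assert f.end[2] == pytest.approx(jz)

    def test_walled_side_gives_single_branch_failure(self, scaffold_scene):
        scene, _ = scaffold_scene
        gc = self._descending_cell(scene)
        # wall off +y with a dense slab near the junction
        base = scene.end[gc.axon_root]
        for dx in np.arange(-8, 8.5, 1.0):
            for dz in np.arange(-9, 9.5, 1.0):
                scene.add_front(99, (base[0] + dx, base[1] + 1.5, base[2] + dz),
                                (base[0] + dx, base[1] + 8, base[2] + dz),
                                0.45, 5)
        for _ in range(8):
            res = gr.bifurcate_pf(scene, gc)
            if res != "pending":
                break
        assert res == "failed"
        assert len(gc.branches) <= 1


class TestParallelFiberExtension:
    def test_runs_to_wall_and_stops(self):
        scene = Scene(seed=0)
        src = scene.add_front(0, (50, 0, 50), (50, 0, 50), 1.0, SOMA,
                              shape=SPHERE)
        tip = scene.grow_front(src, (50, -5, 50), 0.5, PARALLEL_FIBER)
        br = gr.PFBranch(tip=tip, sign=-1, length=5.0)
        for _ in range(100):
            gr.extend_pf(scene, br, branch_cap=np.inf)
            if br.done:
                break
        assert br.reason == "wall"
        assert scene.end[br.tip][1] == pytest.approx(scene.volume.full_lo[1])

    def test_branch_cap_enforced(self):
        scene = Scene(seed=0)
        src = scene.add_front(0, (50, 0, 50), (50, 0, 50), 1.0, SOMA,
                              shape=SPHERE)
        tip = scene.grow_front(src, (50, 5, 50), 0.5, PARALLEL_FIBER)
        br = gr.PFBranch(tip=tip, sign=1, length=5.0)
        while not br.done:
            gr.extend_pf(scene, br, branch_cap=150.0)
        assert br.reason == "cap"
        assert br.length <= 150.0 + 1e-9

    def test_fronts_stay_aligned_with_y(self):
        scene = Scene(seed=0)
        src = scene.add_front(0, (50, 0, 50), (50, 0, 50), 1.0, SOMA,
                              shape=SPHERE)
        tip = scene.grow_front(src, (50, 5, 50), 0.5, PARALLEL_FIBER)
        # obstacle forcing a lateral dodge
        scene.add_front(9, (50, 12, 49), (50, 12, 51), 0.5, 5)
        br = gr.PFBranch(tip=tip, sign=1, length=5.0)
        for _ in range(20):
            gr.extend_pf(scene, br)
            if br.done:
                break
        ids = np.nonzero(scene.alive[: scene.n]
                         & (scene.tags[: scene.n] == PARALLEL_FIBER))[0]
        for fid in ids:
            d = scene.end[fid] - scene.orig[fid]
            L = np.linalg.norm(d)
            if L < 1e-9:
                continue
            angle = np.degrees(np.arccos(abs(d[1]) / L))
            assert angle <= 5.0 + 1e-6


class TestFiringRates:
    def test_ranges_and_means(self):
        rng = np.random.default_rng(0)
        gc = gr.GranuleCell(neuron_id=0, soma_id=0, birth_phase=1, rng=rng)
        pre = np.array([gr.update_firing_rate(gc) for _ in range(10_000)])
        assert pre.max() <= 0.2 and pre.min() >= 0.0
        assert pre.mean() == pytest.approx(0.1, abs=0.01)
        gc.state = gr.ARRIVED
        post = np.array([gr.update_firing_rate(gc) for _ in range(10_000)])
        assert post.max() <= 10.0
        assert post.mean() == pytest.approx(5.0, abs=0.25)

    def test_failed_cells_keep_low_range(self):
        gc = gr.GranuleCell(neuron_id=0, soma_id=0, birth_phase=1,
                            rng=np.random.default_rng(1))
        gc.state = gr.FAILED
        rates = [gr.update_firing_rate(gc) for _ in range(1000)]
        assert max(rates) <= 0.2

    def test_forced_high_overrides_state(self):
        gc = gr.GranuleCell(neuron_id=0, soma_id=0, birth_phase=1,
                            rng=np.random.default_rng(2))
        rates = [gr.update_firing_rate(gc, force_high=True)
                 for _ in range(2000)]
        assert max(rates) > 1.0
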