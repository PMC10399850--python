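"""Purkinje dendritic growth rules: roots, targeting, elongation direction,
synapses, branching, signal integration."""

import numpy as np
import pytest

from cerebdev import purkinje as pk
from cerebdev.core import DENDRITE, PARALLEL_FIBER, SOMA, SPHERE, Scene
from cerebdev.geometry import unit

from conftest import make_pf


def make_pc(scene, pos=(50, 50, 0), nid=0, seed=7):
    p = np.asarray(pos, dtype=float)
    params = pk.PurkinjeParams()
    sid = scene.add_front(nid, p, p, params.soma_radius, SOMA,
                          shape=SPHERE, active=False)
    return pk.PurkinjeCell(neuron_id=nid, soma_id=sid,
                           rng=np.random.default_rng([seed, nid])), params


class TestActivation:
    def test_five_roots_on_upper_hemisphere(self, scene):
        cell, params = make_pc(scene)
        roots = pk.activate_purkinje(scene, cell, params)
        assert len(roots) == 5
        c = scene.orig[cell.soma_id]
        for fid in roots:
            assert scene.end[fid][2] > c[2]
            assert scene.front(fid).tree_index == scene.tree_indices[fid]

    def test_azimuthal_spread_at_least_40_degrees(self, scene):
        cell, params = make_pc(scene)
        roots = pk.activate_purkinje(scene, cell, params)
        c = scene.orig[cell.soma_id]
        az = sorted(np.arctan2(*(scene.end[f] - c)[[1, 0]]) for f in roots)
        gaps = np.diff(az + [az[0] + 2 * np.pi])
        assert np.all(np.degrees(gaps) >= 40.0)

    def test_tree_slots_are_positional(self, scene):
        cell, params = make_pc(scene)
        pk.activate_purkinje(scene, cell, params)
        for i, fid in enumerate(cell.roots):
            assert scene.tree_indices[fid] == i


class TestTargeting:
    def test_nearest_free_fiber_wins(self, scene):
        params = pk.PurkinjeParams()
        near = make_pf(scene, 40, 60, x=53, z=20)
        make_pf(scene, 40, 60, x=57, z=20)
        got = pk.find_target_pf(scene, np.array([50.0, 50, 20]), params)
        assert got[0] == near
        assert got[2] == pytest.approx(3.0)

    def test_occupied_fiber_skipped(self, scene):
        params = pk.PurkinjeParams()
        near = make_pf(scene, 40, 60, x=53, z=20)
        far = make_pf(scene, 40, 60, x=57, z=20)
        scene.has_synapse[near] = True
        got = pk.find_target_pf(scene, np.array([50.0, 50, 20]), params)
        assert got[0] == far

    def test_no_fiber_in_range_gives_none(self, scene):
        params = pk.PurkinjeParams()
        make_pf(scene, 40, 60, x=75, z=20)
        assert pk.find_target_pf(scene, np.array([50.0, 50, 20]), params) is None


class TestElongationDirection:
    def test_heading_plus_upward_bias_without_target(self, scene):
        cell, params = make_pc(scene)
        params.noise_weight = 0.0
        tip_front = scene.add_front(0, (50, 50, 20), (55, 50, 20), 0.8,
                                    DENDRITE, tree_index=0)
        tip = pk.DendriteTip(front=tip_front, heading=np.array([1.0, 0, 0]))
        d = pk.elongation_direction(scene, cell, tip, None, params)
        expect = unit(np.array([1.0, 0.0, params.upward_bias]))
        np.testing.assert_allclose(d, expect, atol=1e-9)

    def test_post_synapse_growth_perpendicular_to_fiber(self, scene):
        cell, params = make_pc(scene)
        tip_front = scene.add_front(0, (50, 50, 20), (55, 50, 20), 0.8,
                                    DENDRITE, tree_index=0)
        tip = pk.DendriteTip(front=tip_front, heading=np.array([0.0, 1, 0]),
                             just_synapsed=True)
        d = pk.elongation_direction(scene, cell, tip, None, params)
        assert abs(d[1]) < 1e-9

    def test_y_repulsion_decays_with_distance(self, scene):
        cell, params = make_pc(scene)
        params.noise_weight = 0.0
        tip_front = scene.add_front(0, (50, 50, 20), (55, 50, 20), 0.8,
                                    DENDRITE, tree_index=0)
        tip = pk.DendriteTip(front=tip_front, heading=np.array([1.0, 0, 0]))

        def y_component(dy):
            other = scene.add_front(9, (54, 50 + dy, 19.5),
                                    (56, 50 + dy, 19.5), 0.8, DENDRITE,
                                    tree_index=2)
            d = pk.elongation_direction(scene, cell, tip, None, params)
            scene.remove_front(other)
            return d[1]

        near = y_component(2.0)
        far = y_component(6.0)
        assert near < 0 and far < 0          # pushed away (−y)
        assert abs(near) > abs(far)          # decays with |Δy|

    def test_zero_blend_falls_back_to_up(self, scene):
        cell, params = make_pc(scene)
        params.noise_weight = 0.0
        params.upward_bias = 0.0
        tip_front = scene.add_front(0, (50, 50, 20), (50, 50, 20), 0.8,
                                    DENDRITE, tree_index=0)
        tip = pk.DendriteTip(front=tip_front, heading=np.zeros(3))
        d = pk.elongation_direction(scene, cell, tip, None, params)
        np.testing.assert_allclose(d, [0, 0, 1])


class TestSynapses:
    def test_single_contact_per_fiber_front(self, scene):
        pf = make_pf(scene, 40, 60, x=50, z=20)
        d1 = scene.add_front(0, (49, 50, 19), (49.5, 50, 19.5), 0.8, DENDRITE)
        d2 = scene.add_front(1, (51, 50, 19), (50.5, 50, 19.5), 0.8, DENDRITE)
        assert scene.synapses.add(scene, pre=pf, post=d1) is not None
        assert scene.synapses.add(scene, pre=pf, post=d2) is None
        assert len(scene.synapses) == 1

    def test_registry_bijective(self, scene):
        records = []
        for i in range(10):
            pf = make_pf(scene, 40, 60, x=30 + i * 2, z=20, neuron_id=100 + i)
            dd = scene.add_front(i, (30 + i * 2, 50, 18),
                                 (30 + i * 2, 50, 19), 0.8, DENDRITE)
            records.append(scene.synapses.add(scene, pre=pf, post=dd))
        ids = [r.pre for r in records] + [r.post for r in records]
        assert len(set(ids)) == len(ids)


class TestBranching:
    def _grow_alone(self, p_branch, cycles=40, seed=3):
        scene = Scene(seed=0)
        cell, params = make_pc(scene, seed=seed)
        params.p_branch = p_branch
        params.noise_weight = 0.2
        params.max_tips_per_tree = 64
        pk.activate_purkinje(scene, cell, params)
        for _ in range(cycles):
            pk.grow_cell_cycle(scene, cell, params)
        return scene, cell

    def test_no_random_branching_at_p_zero(self):
        scene, cell = self._grow_alone(0.0)
        from cerebdev.metrics import tree_stats
        bp = sum(tree_stats(scene, cell.neuron_id, t).branch_points
                 for t in cell.living_trees())
        assert bp == 0

    def test_branch_fraction_tracks_probability(self):
        """Branch events per tip-cycle ≈ p_branch (binomial check)."""
        p = 0.08
        scene, cell = self._grow_alone(p, cycles=60, seed=5)
        from cerebdev.metrics import tree_stats
        stats = [tree_stats(scene, cell.neuron_id, t)
                 for t in cell.living_trees()]
        branches = sum(s.branch_points for s in stats)
        fronts = sum(s.front_count for s in stats)
        # every front is one tip-cycle; each branch event adds one extra tip
        frac = branches / fronts
        assert frac == pytest.approx(p, abs=0.04)

    def test_directed_branch_fires_only_beyond_threshold(self, scene):
        cell, params = make_pc(scene)
        params.noise_weight = 0.0
        params.p_branch = 0.0
        # target far to the side: angle heading→target ≈ 90° > 60°
        make_pf(scene, 40, 60, x=58, z=20)
        root = scene.grow_front(cell.soma_id, (50, 50, 20), 0.8, DENDRITE,
                                tree_index=0)
        cell.roots, cell.tree_alive = [root], [True]
        cell.front_count, cell.integrated_signal = [1], [0.0]
        cell.syn_pre = {0: []}
        cell.tips = {0: [pk.DendriteTip(front=root,
                                        heading=np.array([0.0, 0, 1.0]))]}
        pk.grow_cell_cycle(scene, cell, params)
        assert len(cell.tips[0]) == 2  # straight child + branch toward target
        headings = [t.heading for t in cell.tips[0]]
        # one child heads substantially toward +x (the fiber)
        assert max(h[0] for h in headings) > 0.5


def test_signal_integration_running_sum():
    cell, _ = make_pc(Scene(seed=0))
    cell.roots, cell.tree_alive = [1, 2], [True, True]
    cell.integrated_signal = [0.0, 0.0]
    cell.syn_pre = {0: [(10, 100)], 1: []}
    cell.front_count = [1, 1]
    for _ in range(10):
        pk.integrate_signal(cell, {100: 2.0})
    assert cell.integrated_signal[0] == pytest.approx(20.0)
    assert cell.integrated_signal[1] == 0.0


def test_arrived_partners_dominate_signal():
    """Two equally wired trees: the one wired to arrived cells accumulates
    ~50× the signal of one wired to migrating cells (ratio of uniform
    means 5.0 vs 0.1)."""
    rng = np.random.default_rng(0)
    cell, _ = make_pc(Scene(seed=0))
    cell.roots, cell.tree_alive = [1, 2], [True, True]
    cell.integrated_signal = [0.0, 0.0]
    cell.front_count = [1, 1]
    cell.syn_pre = {0: [(i, 100 + i) for i in range(20)],
                    1: [(50 + i, 200 + i) for i in range(20)]}
    for _ in range(500):
        rates = {100 + i: rng.uniform(0, 10) for i in range(20)}
        rates.update({200 + i: rng.uniform(0, 0.2) for i in range(20)})
        pk.integrate_signal(cell, rates)
    ratio = cell.integrated_signal[0] / cell.integrated_signal[1]
    assert ratio == pytest.approx(50.0, rel=0.15)
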