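"""Morphometrics toolkit on synthetic trees.

Builds a perfect binary dendritic tree, measures it, exports it as SWC,
and shows the statistical helpers (Welch's t-test, coefficient of
variation) on toy samples.
"""

import numpy as np

from cerebdev.core import DENDRITE, SOMA, SPHERE, Scene
from cerebdev.io import export_swc, read_swc
from cerebdev.metrics import cv, tree_stats, welch_t
from cerebdev.purkinje import PurkinjeCell

scene = Scene(seed=0)
soma = scene.add_front(0, (100, 100, 10), (100, 100, 10), 7.0, SOMA,
                       shape=SPHERE)
level = [scene.add_front(0, (100, 100, 17), (100, 100, 22), 0.8, DENDRITE,
                         parent=soma, tree_index=0)]
off = 16.0
for _ in range(3):
    off /= 2
    nxt = []
    for node in level:
        e = scene.end[node]
        for sgn in (-1, 1):
            nxt.append(scene.add_front(0, e, e + (sgn * off, 0, 5), 0.8,
                                       DENDRITE, parent=node, tree_index=0))
    level = nxt

s = tree_stats(scene, 0, 0)
print(f"perfect binary tree: {s.front_count} fronts, "
      f"{s.branch_points} branch points, {s.terminals} terminals")
print(f"max path {s.max_path_length:.2f} um, "
      f"x-extent {s.max_x_extent:.1f} um, volume {s.total_volume:.1f} um^3")

cell = PurkinjeCell(neuron_id=0, soma_id=soma,
                    rng=np.random.default_rng(0))
cell.roots, cell.tree_alive = [1], [True]
cell.front_count, cell.integrated_signal, cell.syn_pre = [15], [0.0], {0: []}
export_swc(scene, cell, "scratch_tree.swc")
df = read_swc("scratch_tree.swc")
print(f"SWC export: {len(df)} rows, soma type {df.iloc[0]['type']}, "
      f"root parent {df.iloc[0]['parent']}")

rng = np.random.default_rng(1)
a = rng.normal(520, 200, 40)   # e.g. winner synapse counts, informed rule
b = rng.normal(390, 270, 40)   # random winner
t, dof, p = welch_t(a, b)
print(f"\nWelch's t-test: t = {t:.2f}, df = {dof:.1f}, p = {p:.4f}")
print(f"coefficient of variation of sample a: {cv(a):.3f}")
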