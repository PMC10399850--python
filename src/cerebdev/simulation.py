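"""Simulation orchestrator.

Wires the engine, the Bergmann glia scaffold, the granule cell migration
machinery, Purkinje dendritic growth and the selection scenario into one
cycle loop (cycle ≈ 2.2 h; cycle = 10 × postnatal day; 140 cycles ≈ P14).

Schedule of one run:

* cycle 0 — Purkinje and glia somata placed (skipped in NoGranCells,
  which grows Purkinje cells in an empty volume);
* cycles 1–35 — glia processes climb to z = 131 μm;
* cycles 15, 25, …, 125 — granule birth phases 1–12 (phase k starts at
  cycle 10k + 5, anchoring phase 6 at cycle 65), each also seeding
  ingrowing parallel-fiber sources in the y-wings;
* every cycle — granule state machines advance, fibers extend, firing
  rates are redrawn;
* cycle 65 (NoGranCells: 5) — Purkinje somata activate and grow roots;
  thereafter dendritic growth, synapse formation, signal integration and
  the scenario's selection rule run each cycle.

Determinism: every cell owns an RNG substream derived from
``(seed, neuron_id)`` and cells are processed in neuron-id order, so a
given (config, seed) always yields the identical trajectory.
"""

from __future__ import annotations

import math

import numpy as np

from . import granule as gr
from .config import RunConfig
from .core import SOMA, SPHERE, Scene, SimVolume
from .glia import BergmannGlia, extend_glia_processes, init_bergmann
from .granule import GranuleCell, IngrowingPF
from .purkinje import (
    PurkinjeCell,
    PurkinjeParams,
    activate_purkinje,
    grow_cell_cycle,
    integrate_signal,
)
from .scenarios import ScenarioParams, evaluate_cell


class Simulation:
    """One configured run; create, then :meth:`run`."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.scenario = ScenarioParams(config.scenario,
                                       config.resolved_scenario_params())
        self.events: list[dict] = []
        self.pp = PurkinjeParams(
            soma_radius=config.pc_soma_radius,
            dendrite_radius=config.dendrite_radius,
            pf_search_radius=config.pf_search_radius,
            contact_distance=config.syn_contact,
            upward_bias=config.upward_bias,
            repulsion_strength=config.repulsion_strength,
            repulsion_lambda=config.repulsion_lambda,
            noise_weight=config.noise_weight,
            p_branch=config.p_branch,
            theta_dev_deg=config.theta_dev_deg,
            step=config.dendrite_step,
            step_jitter=config.step_jitter,
            ceiling_z=config.ceiling_z,
            max_tips_per_tree=config.max_tips_per_tree,
        )
        self.activation_cycle = (5 if config.scenario == "NoGranCells"
                                 else config.activation_cycle)
        if config.checkpoint_in:
            self.scene = Scene.load_checkpoint(config.checkpoint_in)
            self.scene.seed = config.seed
        else:
            vol = SimVolume(tuple(config.main_lo), tuple(config.main_hi),
                            tuple(config.full_lo), tuple(config.full_hi))
            self.scene = Scene(volume=vol, seed=config.seed)
            self._build_initial()
        self._bind_cells()

    # ------------------------------------------------------------------- setup

    def _bind_cells(self):
        self.purkinje = [c for c in self.scene.neurons if isinstance(c, PurkinjeCell)]
        self.glia = [c for c in self.scene.neurons if isinstance(c, BergmannGlia)]
        self.granule = [c for c in self.scene.neurons if isinstance(c, GranuleCell)]
        self.ingrowing = [c for c in self.scene.neurons if isinstance(c, IngrowingPF)]
        self._next_nid = max((c.neuron_id for c in self.scene.neurons), default=-1) + 1

    def _alloc_nid(self) -> int:
        nid = self._next_nid
        self._next_nid += 1
        return nid

    def _cell_rng(self, nid: int) -> np.random.Generator:
        return np.random.default_rng([self.cfg.seed % (2**31), nid])

    def _build_initial(self):
        cfg, scene = self.cfg, self.scene
        self._next_nid = 0
        # Purkinje somata on a grid in the z = 0 plane; the inner block is
        # analyzed, border cells only provide dendritic repulsion
        xs = [cfg.main_lo[0] + (i + 0.5) * (cfg.main_hi[0] - cfg.main_lo[0]) / cfg.pc_nx
              for i in range(cfg.pc_nx)]
        ys = [cfg.main_lo[1] + (j + 0.5) * (cfg.main_hi[1] - cfg.main_lo[1]) / cfg.pc_ny
              for j in range(cfg.pc_ny)]
        ix0 = (cfg.pc_nx - cfg.pc_inner_nx) // 2
        iy0 = (cfg.pc_ny - cfg.pc_inner_ny) // 2
        for j, y in enumerate(ys):
            for i, x in enumerate(xs):
                nid = self._alloc_nid()
                c = np.array([x, y, 0.0])
                sid = scene.add_front(nid, c, c, cfg.pc_soma_radius, SOMA,
                                      shape=SPHERE, active=False)
                inner = (ix0 <= i < ix0 + cfg.pc_inner_nx
                         and iy0 <= j < iy0 + cfg.pc_inner_ny)
                scene.neurons.append(PurkinjeCell(
                    neuron_id=nid, soma_id=sid, rng=self._cell_rng(nid),
                    analyzed=inner))
        if cfg.scenario == "NoGranCells":
            return
        # Bergmann glia interleaved between the Purkinje grid points; the
        # seven process lanes tile each glia's territory so neighboring
        # scaffolds stay clear of each other
        sx = xs[1] - xs[0]
        span = 0.5 * (sx - 2.0 - 2 * cfg.glia_process_radius)
        lanes = tuple(np.linspace(-span, span, 7))
        for j in range(cfg.pc_ny - 1):
            for i in range(cfg.pc_nx - 1):
                nid = self._alloc_nid()
                c = np.array([0.5 * (xs[i] + xs[i + 1]),
                              0.5 * (ys[j] + ys[j + 1]), 0.0])
                glia = init_bergmann(scene, c, nid,
                                     soma_radius=cfg.glia_soma_radius,
                                     process_radius=cfg.glia_process_radius,
                                     lane_offsets=lanes)
                scene.neurons.append(glia)

    # ----------------------------------------------------------------- spawning

    def _spawn_phase(self, k: int):
        """Phase-k births: granule somata in the k-th z-band of the main
        volume and ingrowing fiber sources in the y-wings."""
        cfg, scene = self.cfg, self.scene
        rng = np.random.default_rng([cfg.seed % (2**31), 900_000 + k])
        z_lo = cfg.phase_band * (k - 1)
        z_hi = cfg.phase_band * k
        r = cfg.gc_soma_radius
        for _ in range(cfg.gc_per_phase):
            placed = False
            for _try in range(10):
                p = np.array([
                    rng.uniform(cfg.main_lo[0] + r, cfg.main_hi[0] - r),
                    rng.uniform(cfg.main_lo[1] + r, cfg.main_hi[1] - r),
                    rng.uniform(z_lo + r, z_hi),
                ])
                if scene.collision_ids(p, p, r).size == 0:
                    placed = True
                    break
            if not placed:
                continue
            nid = self._alloc_nid()
            sid = scene.add_front(nid, p, p, r, SOMA, shape=SPHERE, active=False)
            scene.neurons.append(GranuleCell(
                neuron_id=nid, soma_id=sid, birth_phase=k,
                rng=self._cell_rng(nid)))
        # ingrowing parallel fibers: sources split between the two wings,
        # each growing a single fiber toward (and hopefully through) the
        # main volume
        rs = 1.0
        wings = (
            (cfg.full_lo[1] + rs, cfg.main_lo[1] - rs, +1),
            (cfg.main_hi[1] + rs, cfg.full_hi[1] - rs, -1),
        )
        for idx in range(cfg.ingrowing_per_phase):
            y0, y1, sign = wings[idx % 2]
            placed = False
            for _try in range(10):
                p = np.array([
                    rng.uniform(cfg.main_lo[0] + rs, cfg.main_hi[0] - rs),
                    rng.uniform(y0, y1),
                    rng.uniform(z_lo + rs, z_hi),
                ])
                if scene.collision_ids(p, p, rs).size == 0:
                    placed = True
                    break
            if not placed:
                continue
            nid = self._alloc_nid()
            # arrival cycle mimics the migration the source cell would have
            # had: a few horizontal cycles plus the descent from its birth z
            descent = math.ceil((p[2] - gr.ARRIVAL_Z) / cfg.radial_step)
            arrival = scene.cycle + 3 + descent + int(rng.integers(0, 6))
            pf = gr.make_ingrowing_pf(scene, nid, p, sign, arrival,
                                      rng=self._cell_rng(nid))
            scene.neurons.append(pf)

    # -------------------------------------------------------------------- cycle

    def _granule_cycle(self):
        cfg, scene = self.cfg, self.scene
        for gc in self.granule:
            if gc.state == gr.BORN:
                gr.select_target_process(scene, gc,
                                         search_radius=cfg.glia_search_radius)
            if gc.tjunction == "pending" and gc.axon_root >= 0 \
                    and scene.birth_cycles[gc.axon_root] < scene.cycle:
                gr.bifurcate_pf(scene, gc, step=cfg.pf_step,
                                pf_radius=cfg.pf_radius,
                                max_lateral=cfg.pf_max_lateral)
            if gc.state == gr.HORIZONTAL:
                res = gr.horizontal_step(
                    scene, gc, step=cfg.horizontal_step,
                    contact=cfg.contact_distance,
                    leading_radius=cfg.leading_radius,
                    retry_budget=cfg.retry_budget)
                if res == "reached":
                    gr.begin_radial(scene, gc, axon_radius=cfg.axon_radius,
                                    leading_radius=cfg.leading_radius)
            elif gc.state == gr.RADIAL:
                gr.radial_step(scene, gc, step=cfg.radial_step,
                               tether=cfg.tether,
                               retry_budget=cfg.retry_budget)
            for br in gc.branches:
                if not br.done:
                    gr.extend_pf(scene, br, step=cfg.pf_step,
                                 pf_radius=cfg.pf_radius,
                                 branch_cap=cfg.pf_branch_cap,
                                 max_lateral=cfg.pf_max_lateral)
        for ing in self.ingrowing:
            if ing.branch is None:
                gr.start_ingrowing_fiber(scene, ing, step=cfg.pf_step,
                                         pf_radius=cfg.pf_radius,
                                         max_lateral=cfg.pf_max_lateral)
            elif not ing.branch.done:
                gr.extend_pf(scene, ing.branch, step=cfg.pf_step,
                             pf_radius=cfg.pf_radius,
                             branch_cap=np.inf,
                             max_lateral=cfg.pf_max_lateral)

    def _update_rates(self) -> dict:
        force = self.cfg.force_arrived_rates
        rates = {}
        for gc in self.granule:
            rates[gc.neuron_id] = gr.update_firing_rate(gc, force_high=force)
        for ing in self.ingrowing:
            ing._arrived = self.scene.cycle >= ing.arrival_cycle
            rates[ing.neuron_id] = gr.update_firing_rate(ing, force_high=force)
        return rates

    def step(self):
        scene, cfg = self.scene, self.cfg
        scene.cycle += 1
        t = scene.cycle
        if cfg.scenario != "NoGranCells":
            for k in range(1, cfg.n_phases + 1):
                if t == cfg.phase_start(k):
                    self._spawn_phase(k)
                    self._bind_cells()
            for glia in self.glia:
                extend_glia_processes(scene, glia,
                                      process_radius=cfg.glia_process_radius)
            self._granule_cycle()
        rates = self._update_rates()
        if t == self.activation_cycle:
            for pc in self.purkinje:
                activate_purkinje(scene, pc, self.pp)
        if t >= self.activation_cycle:
            for pc in self.purkinje:
                grow_cell_cycle(scene, pc, self.pp)
            for pc in self.purkinje:
                integrate_signal(pc, rates)
            for pc in self.purkinje:
                evaluate_cell(scene, pc, self.scenario, events=self.events)

    def run(self, until: int | None = None) -> "Simulation":
        stop = until if until is not None else self.cfg.total_cycles
        while self.scene.cycle < stop:
            self.step()
            if (self.cfg.checkpoint_out
                    and self.scene.cycle == self.cfg.checkpoint_cycle):
                self.scene.save_checkpoint(self.cfg.checkpoint_out)
        return self

    # ------------------------------------------------------------------- views

    @property
    def analyzed_cells(self) -> list[PurkinjeCell]:
        return [pc for pc in self.purkinje if pc.analyzed]

    def winner_trees(self, analyzed_only: bool = True):
        """(cell, tree_index) pairs of all living trees at the current cycle."""
        cells = self.analyzed_cells if analyzed_only else self.purkinje
        return [(pc, t) for pc in cells for t in pc.living_trees()]
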