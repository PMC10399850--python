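"""Run configuration and presets.

``RunConfig`` gathers every tunable of the simulation — volume bounds, cell
counts, phase schedule, growth-rule constants, scenario thresholds, seed —
and round-trips losslessly through YAML.  Two presets are provided:

* ``full`` — the full-scale setup: 200×180×160 μm main volume, ~250
  granule cells and ~850 ingrowing parallel fibers per phase (12 phases),
  8×6 Purkinje grid with the inner 6×4 = 24 cells analyzed.  Hours of
  compute per run.
* ``desk`` — a scaled-down volume preserving every mechanism (all twelve
  phases, both migrations, all scenarios) at interactive run times:
  100×90 μm footprint with proportionally scaled y-wings, 24 granule
  cells and 60 ingrowing fibers per phase, 5×4 Purkinje grid with the
  inner 3×2 = 6 cells analyzed.  Threshold-based scenario parameters scale
  with the reduced parallel-fiber density (see ``DESK_SCENARIO_PARAMS``).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .scenarios import DEFAULT_PARAMS

# Desk-scale scenario thresholds.  Fixed cycles are kept; count/signal
# thresholds shrink roughly with the ~4× lower parallel-fiber supply and
# smaller trees of the desk volume so that both retraction phases trigger
# inside the simulated window, as they do at full scale.
DESK_SCENARIO_PARAMS = {
    "RandomRetract": {"random_retract_cycle": 72},
    "NoRetract": {},
    "NoGranCells": {"cycle_1": 30, "whole_1st": 100, "tree_th": 20,
                    "cycle_2": 37, "whole_2nd": 130},
    "FixedRetract": {"cycle_1": 90, "cycle_2": 97},
    "SizeRetract": {"whole_1st": 300, "tree_th": 20, "whole_2nd": 400},
    "SynapseRetract": {"whole_1st": 8, "tree_th": 3, "whole_2nd": 16},
    "InputRetract": {"whole_1st": 300, "whole_2nd": 900},
}


@dataclass
class RunConfig:
    # identity
    scenario: str = "NoRetract"
    preset: str = "desk"
    seed: int = 1
    total_cycles: int = 140
    scenario_params: dict = field(default_factory=dict)

    # volume (μm)
    main_lo: tuple = (-20.0, -20.0, -20.0)
    main_hi: tuple = (180.0, 160.0, 140.0)
    full_lo: tuple = (-20.0, -160.0, -20.0)
    full_hi: tuple = (180.0, 300.0, 140.0)

    # granule cell population and kinetics
    gc_per_phase: int = 250
    ingrowing_per_phase: int = 850
    n_phases: int = 12
    phase_band: float = 11.0          # z-thickness of one birth band
    gc_soma_radius: float = 1.2       # "squeezed" migrating soma
    leading_radius: float = 0.6
    pf_radius: float = 0.5
    axon_radius: float = 0.5
    horizontal_step: float = 4.0
    radial_step: float = 5.0
    pf_step: float = 5.0
    contact_distance: float = 2.0
    tether: float = 3.0
    glia_search_radius: float = 30.0
    retry_budget: int = 3
    pf_branch_cap: float = 150.0      # per branch; whole fiber ≤ 300 μm
    pf_max_lateral: float = 0.4       # keeps fiber fronts within ~5° of y

    # Bergmann glia
    glia_soma_radius: float = 5.0
    glia_process_radius: float = 0.8

    # Purkinje cells
    pc_nx: int = 8
    pc_ny: int = 6
    pc_inner_nx: int = 6
    pc_inner_ny: int = 4
    pc_soma_radius: float = 7.0
    activation_cycle: int = 65
    dendrite_radius: float = 0.8
    pf_search_radius: float = 10.0
    syn_contact: float = 1.5
    upward_bias: float = 0.08
    repulsion_strength: float = 1.0
    repulsion_lambda: float = 5.0
    noise_weight: float = 0.45
    p_branch: float = 0.05
    theta_dev_deg: float = 60.0
    dendrite_step: float = 5.0
    step_jitter: float = 0.5
    ceiling_z: float = 100.0
    max_tips_per_tree: int = 40

    # experimental switches
    force_arrived_rates: bool = False  # all granule cells fire at post-arrival rates

    # i/o
    checkpoint_in: str = ""
    checkpoint_out: str = ""
    checkpoint_cycle: int = 65        # when checkpoint_out is written
    outdir: str = ""

    def phase_start(self, k: int) -> int:
        """Cycle at which birth phase k (1-based) begins: 10k + 5."""
        return 10 * k + 5

    def resolved_scenario_params(self) -> dict:
        base = dict(DEFAULT_PARAMS[self.scenario])
        if self.preset == "desk":
            base.update(DESK_SCENARIO_PARAMS.get(self.scenario, {}))
        base.update(self.scenario_params)
        return base

    # ------------------------------------------------------------- serialization

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, src) -> "RunConfig":
        if hasattr(src, "read"):
            data = yaml.safe_load(src.read())
        else:
            try:
                with open(src) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(src)
        for key in ("main_lo", "main_hi", "full_lo", "full_hi"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def full_config(scenario: str = "NoRetract", seed: int = 1, **overrides) -> RunConfig:
    """Full-scale preset (the published problem size; hours per run)."""
    cfg = RunConfig(scenario=scenario, preset="full", seed=seed)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def desk_config(scenario: str = "NoRetract", seed: int = 1, **overrides) -> RunConfig:
    """Desk-scale preset: every mechanism at interactive run times."""
    cfg = RunConfig(
        scenario=scenario,
        preset="desk",
        seed=seed,
        main_lo=(-20.0, -20.0, -20.0),
        main_hi=(80.0, 70.0, 140.0),
        full_lo=(-20.0, -90.0, -20.0),
        full_hi=(80.0, 140.0, 140.0),
        gc_per_phase=24,
        ingrowing_per_phase=60,
        pc_nx=5,
        pc_ny=4,
        pc_inner_nx=3,
        pc_inner_ny=2,
        max_tips_per_tree=10,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


PRESETS = {"full": full_config, "desk": desk_config}
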