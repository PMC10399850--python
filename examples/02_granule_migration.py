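"""Granule cell migration in a small volume.

Runs the granule-cell environment (glia scaffold, phased births,
horizontal + radial migration, parallel fibers) at a reduced size for 80
cycles and prints the migration bookkeeping.  Success rates below 100% are
expected: cells genuinely get stuck in the crowded fiber mat, as in the
developing tissue.
"""

from cerebdev.config import desk_config
from cerebdev.io import migration_report
from cerebdev.metrics import success_rates
from cerebdev.simulation import Simulation

cfg = desk_config("NoRetract", seed=1, gc_per_phase=10,
                  ingrowing_per_phase=20, total_cycles=80)
sim = Simulation(cfg).run()

print(migration_report(sim).to_string(index=False))
rm = success_rates(sim)
print(f"\nradial migration success : {rm.radial_success:.1%}"
      f"  (arrived {rm.arrived} of {rm.born} born)")
print(f"T-junction success       : {rm.t_junction_success:.1%}")
print(f"local fibers spanning y  : {rm.local_pf_full_extension:.1%}")
print(f"ingrowing fibers through : {rm.ingrowing_pf_completion:.1%}")
print(f"fibers in central volume : {rm.pf_count_front} toward +y, "
      f"{rm.pf_count_back} toward -y")
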