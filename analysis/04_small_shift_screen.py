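#!/usr/bin/env python
"""Hit calling when the complex is barely larger than the free target.

The large two-domain target (R_h 2.96 nm) gains only ~8-22% on binding, so
a fixed 10% cutoff can miss genuine high-affinity binders.  This simulates
the heat-lysate screen at 1:30 with triplicates and 0.5% Rh noise and
compares the threshold rule with the one-sided Dunnett many-to-one test
against the preculture control.

Writes results/04_small_shift_screen.tsv.
"""

from fidascreen import io, screening, simulate
from fidascreen.physics import InstrumentMethod
from fidascreen.simulate import LysateModel

SEED = 2
DILUTION = 30.0
method = InstrumentMethod()
truth = simulate.gk_campaign(SEED, delta_rh_fraction=0.08)

sheet, traces, record = simulate.simulate_campaign(
    truth, LysateModel.heat(), method, seed=SEED, output="rh",
    rh_noise_sd=0.005 * truth.indicator_rh_free)
table = screening.screen_campaign(sheet, traces, method)
at30 = table[table.dilution_factor == DILUTION].copy()
at30 = at30.merge(record[["binder_id", "is_binder", "true_kd_M"]],
                  on="binder_id")
io.write_table(at30, "results/04_small_shift_screen.tsv", {"seed": SEED})

print(at30[["binder_id", "is_binder", "rh_mean", "pct_change",
            "hit_threshold", "p_adjusted", "hit_statistical"]]
      .to_string(index=False, float_format=lambda x: f"{x:.4g}"))

weak = at30[at30.binder_id == "3B"].iloc[0]
print(f"\nbinder 3B (true KD {weak.true_kd_M * 1e9:.1f} nM, complex +8%): "
      f"threshold hit = {bool(weak.hit_threshold)}, "
      f"Dunnett hit = {bool(weak.hit_statistical)} "
      f"(p_adj = {weak.p_adjusted:.2g})")
print("the fixed 10% cutoff misses this high-affinity binder; "
      "the statistical rule recovers it (at the cost of calling small "
      "nonspecific shifts significant, so small-change hits deserve "
      "skepticism)")
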