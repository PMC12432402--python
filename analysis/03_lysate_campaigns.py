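#!/usr/bin/env python
"""Screen directly on bacterial lysates: heat vs chemical lysis.

Simulates full trace-level campaigns (10 candidates, 4 true binders,
dilutions 1:2 to 1:100, triplicates) for both lysis modes, runs the
complete evaluation pipeline (fit, viscosity normalization against the
buffer reference, threshold and Dunnett calls against the matched
preculture), and tallies false positives/negatives per dilution.

The expected pattern: chemical lysates keep the whole host proteome, so
nonspecific size shifts produce false positives at every dilution; heat
lysis precipitates host proteins and the false positives vanish by 1:30.

Writes results/03_screen_<mode>.tsv and results/03_fpfn.tsv.
"""

import pandas as pd

from fidascreen import io, screening, simulate
from fidascreen.physics import InstrumentMethod
from fidascreen.simulate import LysateModel

SEED = 1
method = InstrumentMethod()
truth = simulate.alfa_campaign(SEED)

reports = []
for lysate, mode in [(LysateModel.heat(), "heat"),
                     (LysateModel.chemical(), "chemical")]:
    sheet, traces, record = simulate.simulate_campaign(
        truth, lysate, method, seed=SEED)
    table = screening.screen_campaign(sheet, traces, method)
    io.write_table(table, f"results/03_screen_{mode}.tsv",
                   {"seed": SEED, "lysis": mode})
    rep = screening.dilution_series_report(table, record)
    rep["lysis"] = mode
    reports.append(rep)
    thr = rep[rep.rule == "threshold"]
    print(f"\n{mode} lysis, 10% threshold rule "
          f"({int(thr.n_binders.iloc[0])} binders, "
          f"{int(thr.n_nonbinders.iloc[0])} non-binders):")
    print(thr[["dilution_factor", "false_positives",
               "false_negatives"]].to_string(index=False))

fpfn = pd.concat(reports, ignore_index=True)
io.write_table(fpfn, "results/03_fpfn.tsv", {"seed": SEED})

heat30 = fpfn[(fpfn.lysis == "heat") & (fpfn.rule == "threshold")
              & (fpfn.dilution_factor == 30.0)].iloc[0]
print(f"\nheat lysis at 1:30: {int(heat30.false_positives)} false positives,"
      f" {int(heat30.false_negatives)} false negatives "
      "(clean separation of binders and non-binders)")
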