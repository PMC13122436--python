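"""Estimate standardized selection differentials on natal-exit size for the
Delta, Ocean, and All segments of each cohort, then regress them on mean
natal-river flow (linear and quadratic), mean Delta-entry size, and logged
escapement the previous fall.

Run after 04:  python analysis/05_selection_differentials.py
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from otolife.reference import sampling_point_summaries
from otolife.selection import regress_i, segment_differentials

OUT = Path("results")

wild = pd.read_csv(OUT / "analysis_records.csv")
# adults carry their cohort-matched outmigration year: escapement − age + 1
adults = wild.collection_point == "spawning"
wild.loc[adults, "outmigration_year"] = (
    wild.loc[adults, "escapement_year"] - wild.loc[adults, "assigned_age"] + 1
)

sel = segment_differentials(wild)
sel.to_csv(OUT / "selection_differentials.csv", index=False)
print("standardized selection differentials (SD-standardised):")
print(sel.pivot_table(index="year", columns="segment", values="i").round(2).to_string())
print("\nsegment means:", sel.groupby("segment").i.mean().round(2).to_dict())

# covariate regressions on the published flow series
flows = (
    sampling_point_summaries()
    .drop_duplicates("outmigration_year")
    .set_index("outmigration_year")["flow_cfs"]
)
fits = {}
for seg, grp in sel.groupby("segment"):
    grp = grp[grp.year.isin(flows.index)]
    if len(grp) < 4:
        continue
    x = np.log10(flows.loc[grp.year].to_numpy())
    for form in ("linear", "quadratic"):
        if len(grp) < (3 if form == "linear" else 4):
            continue
        fit = regress_i(grp.i.to_numpy(), x, form=form)
        fits[f"{seg}:{form}:log10_flow"] = {
            "params": list(fit.params),
            "fvalue": float(fit.fvalue),
            "f_pvalue": float(fit.f_pvalue),
            "rsquared_adj": float(fit.rsquared_adj),
        }
(OUT / "selection_regressions.json").write_text(json.dumps(fits, indent=2))
print(f"\nwrote {OUT/'selection_differentials.csv'} and selection_regressions.json")
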