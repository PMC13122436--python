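"""Screen and assign provenance: eye-lens δ³⁴S prescreen for adults, the
stand-in natal classifier on the early otolith transect, and the exogenous
feeding-check reassignment rule.  Keeps the wild natal-river (AME) fish as
the analysis set.

Run after 02:  python analysis/03_provenance.py
"""

from pathlib import Path

import pandas as pd

from otolife.config import load_config
from otolife.pipeline import apply_provenance
from otolife.profiles import read_profiles_csv

OUT = Path("results")

records = pd.read_csv(OUT / "reconstructed_records.csv")
profiles = read_profiles_csv(OUT / "profiles.csv")
iso = load_config(OUT / "isoscape_config.yaml")

rec = apply_provenance(records, profiles, iso)
rec.to_csv(OUT / "provenance_records.csv", index=False)

print("assigned sources by sampling point:")
print(rec.groupby("collection_point").assigned_source.value_counts().to_string())
wild = rec[rec.assigned_source == "AME"]
acc = (wild.origin_true == "natal-river-wild").mean()
print(f"\nanalysis set: {len(wild)} AME-assigned fish ({100*acc:.1f}% truly wild)")
print(f"wrote {OUT/'provenance_records.csv'}")
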