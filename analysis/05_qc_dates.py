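#!/usr/bin/env python
"""QC utilities on worked examples: Ry sexing, mtDNA contamination, and
admixture-date conversion anchored on the Kofun reference age."""

import json
from pathlib import Path

from rohabc.qc import (
    PileupSite,
    assign_sex,
    convert_admixture_date,
    mt_contamination,
    reference_age,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"
OUT.mkdir(parents=True, exist_ok=True)

ref_age = reference_age([1378, 1340, 1325])  # three Kofun median dates

pileup = [
    PileupSite(152, "T", {"A": 0, "C": 1, "G": 0, "T": 61}),
    PileupSite(3010, "A", {"A": 55, "C": 0, "G": 0, "T": 0}),
    PileupSite(8701, "C", {"A": 0, "C": 47, "G": 0, "T": 3}),   # damage-prone
    PileupSite(16223, "T", {"A": 1, "C": 0, "G": 0, "T": 58}),
]

out = {
    "sex_calls": {
        "ry_0.000": assign_sex(0, 1000).call,
        "ry_0.050": assign_sex(50, 1000).call,
        "ry_0.100": assign_sex(100, 1000).call,
    },
    "contamination": mt_contamination(pileup).__dict__,
    "kofun_reference_age_bp": ref_age,
    "admixture_dates_bp": {
        "northeast_asian_pulse": convert_admixture_date(84, 33, 25, ref_age).__dict__,
        "east_asian_pulse": convert_admixture_date(16, 7, 25, ref_age).__dict__,
    },
}
with open(OUT / "05_qc.json", "w") as fh:
    json.dump(out, fh, indent=2)
print(json.dumps(out, indent=2))
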