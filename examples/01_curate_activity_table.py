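"""Curate a raw SMILES/IC50 activity table.

Builds a tiny table with the classic pathologies — mixed units, a
duplicate structure written two ways, an unparseable SMILES, a weak
compound over the 10 uM potency cutoff — and shows how curation resolves
each one.
"""

from qsarkit import curate

raw = [
    {"compound_id": "A1", "smiles": "CCOc1ccccc1C(=O)N", "ic50": 85, "unit": "nM"},
    {"compound_id": "A2", "smiles": "O=C(N)c1ccccc1OCC", "ic50": 340, "unit": "nM"},  # same molecule as A1
    {"compound_id": "A3", "smiles": "Cc1ccc2[nH]c(N)nc2c1", "ic50": 0.45, "unit": "uM"},
    {"compound_id": "A4", "smiles": "C1CC", "ic50": 10, "unit": "nM"},               # unclosed ring
    {"compound_id": "A5", "smiles": "c1ccccc1", "ic50": 55, "unit": "uM"},           # too weak
]

table = curate(raw)

print(f"{len(table.records)} curated records, {len(table.rejects)} rejects\n")
print(table.to_frame().to_string(index=False))
print("\nrejects:")
print(table.rejects_frame().to_string(index=False))
print(
    "\nA1/A2 are one molecule: their potencies merge to the geometric-mean "
    "IC50 (~170 nM -> pIC50 6.77). The invalid SMILES and the 55 uM compound "
    "are logged with machine-readable reasons, never silently dropped."
)
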