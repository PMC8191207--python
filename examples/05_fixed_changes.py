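"""Scan a protein alignment for residues fixed in a focal group.

Builds a small alignment where the two smallest species share a leucine at
one column while every other species carries serine (the same pattern as a
reported kinase-domain change), maps the column onto the human row and
annotates it with a supplied domain interval.
"""

from phylorates import (ProteinAlignment, annotate_domains, attach_reference,
                        scan_fixed_changes)

aln = ProteinAlignment("CDC7_like", {
    "human":   "MSKTELIQAVR",
    "stoat":   "MSKTELLQAVR",
    "ferret":  "MSKTELLQAVR",
    "meerkat": "MSKTELLQAVR",
    "cat":     "MSKTELSQAVR",
    "fox":     "MSKTELSQAVR",
    "bear":    "MSKTELSQAVR",
    "walrus":  "MSKTELSQAVR",
})

focal = ["stoat", "ferret", "meerkat"]
background = ["cat", "fox", "bear", "walrus"]   # human row excluded

sites = scan_fixed_changes(aln, focal, background, mode="strict")
attach_reference(sites, aln, "human")
annotate_domains(sites, {"CDC7_like": [("protein kinase", 1, 11)]})

for s in sites:
    print(f"column {s.column}: {s.background_residues}->{s.focal_residue}, "
          f"human position {s.ref_position}, label {s.label}, "
          f"domains {s.domains}")
print()
print("The focal group is fixed for L where all background carnivores have")
print("S; gap-containing or ambiguous columns would have been skipped.")
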