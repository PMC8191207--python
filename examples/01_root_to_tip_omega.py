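"""Compute per-species root-to-tip omega for one gene on a small tree.

Builds a four-species chronogram and a hand-written branch-rate table,
applies the outlier rule (dN or dS below 0.0002 invalidates a branch) and
prints the per-species mean omega along the root-to-tip path.
"""

import pandas as pd

from phylorates import BranchRatesTable, parse_newick, root_to_tip_omega

tree = parse_newick("(((lynx:10,cat:10)N1:20,fox:30)N2:25,bear:55);")

rates = BranchRatesTable(pd.DataFrame(
    [
        ("ex_gene", "N1", 0.010, 0.050, 0.20),
        ("ex_gene", "N2", 0.020, 0.050, 0.40),
        ("ex_gene", "lynx", 0.015, 0.050, 0.30),
        # sub-threshold dS: this branch's inflated omega is marked n/a
        ("ex_gene", "cat", 0.0005, 0.0001, 5.00),
        ("ex_gene", "fox", 0.010, 0.050, 0.20),
        ("ex_gene", "bear", 0.005, 0.050, 0.10),
    ],
    columns=["gene", "branch", "dN", "dS", "omega"],
))

table = root_to_tip_omega(tree, rates)
print(table.to_string(index=False))
print()
print("cat averages only its two valid path branches (0.40, 0.20 -> 0.30);")
print("the omega=5.0 outlier branch is excluded by the dS < 0.0002 rule.")
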