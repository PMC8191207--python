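"""Fit PGLS with maximum-likelihood Pagel's lambda on simulated data.

Simulates a 20-species chronogram, Brownian body masses, and one gene whose
log10 root-to-tip omega increases with log10 body mass (slope 0.4), then
recovers the slope and the phylogenetic signal by PGLS.
"""

import numpy as np

from phylorates import (SimulationConfig, pgls_gene, root_to_tip_omega,
                        simulate_dataset)

cfg = SimulationConfig(seed=7, n_species=20, n_effect_genes=1, n_null_genes=0,
                       effect_beta=0.4, gene_lambda=0.9, gene_sigma=0.3,
                       n_alignments=0, n_null_records=0, n_alt_records=0)
ds = simulate_dataset(cfg)

rtt = root_to_tip_omega(ds.tree, ds.rates)
mass = ds.phenotypes.set_index("species")["body_mass_g"]
fit = pgls_gene(rtt, mass, ds.tree)

print(f"species used       : {fit.n}")
print(f"slope (log10 units): {fit.slope:+.4f}   planted: +0.4000")
print(f"lambda_hat         : {fit.lambda_hat:.3f}")
print(f"two-sided p        : {fit.p_value:.4g}")
print()
print("The slope is the change in log10 omega per unit log10 body mass;")
print("lambda_hat near 1 indicates strong phylogenetic signal in the")
print("residuals, so species cannot be treated as independent points.")
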