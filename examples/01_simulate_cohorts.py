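"""Simulate a two-cohort case-control genotype study with planted signals.

Builds the standard toy dataset — 400 individuals in two diverged
cohorts, 300 common SNPs with mild LD, two additive risk SNPs and one
XOR-type epistatic pair — and prints its basic composition.
"""

import numpy as np

import episnp as e

matrix, pheno, truth = e.make_toy_fixture(seed=1)

print(f"samples: {matrix.n_samples}   SNPs: {matrix.n_snps}")
print(f"cases: {pheno.status.sum()}   controls: {(pheno.status == 0).sum()}")
for name in ("A", "B"):
    n = (pheno.cohort == name).sum()
    print(f"cohort {name}: {n} samples")
cases = pheno.status == 1
print(f"ER+ cases: {(pheno.er_status[cases] == 'positive').sum()}  "
      f"ER- cases: {(pheno.er_status[cases] == 'negative').sum()}")
print("planted marginal SNPs:", [s for s, _ in truth.marginal_snps])
print("planted XOR pair:", [(a, b) for a, b, _, _ in truth.interaction_pairs])

freq = matrix.dosage.mean(axis=0) / 2
print(f"allele-frequency range: {freq.min():.2f}-{freq.max():.2f}")
# Case fraction sits near one half because the liability intercept is
# auto-centred; the planted SNPs shift individual risks around it.
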