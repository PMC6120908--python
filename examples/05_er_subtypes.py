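"""Classify the ER+ vs ER- subtype of cases from risk-predictive SNPs.

The selected SNP union is re-ranked by boosting gain against ER labels
(zero-gain SNPs are dropped) and evaluated per top-k panel with a
10-fold CV linear SVM — the protocol for asking whether risk SNPs also
separate molecular subtypes.
"""

import episnp as e

matrix, pheno, truth = e.make_toy_fixture(seed=5)
er_snps = [s for s, _ in truth.er_snps]
union = er_snps + [s for s in matrix.snp_ids[:48] if s not in er_snps]

out = e.er_subtype_task(
    matrix, pheno, union, k_grid=[5, 10, 25, 50], seed=5,
    boosting_params=e.BoostingParams(n_trees=100, tree_depth=3, learning_rate=0.1,
                                     subsample=0.8, seed=5),
)
print(f"{'k':>4} {'mAP':>7} {'sd':>6} {'accuracy %':>11}")
for k, row in sorted(out.items()):
    print(f"{k:>4} {100 * row['map']:>7.1f} {100 * row['sd']:>6.1f} {row['accuracy']:>11.1f}")
# The planted ER SNPs dominate small panels; mAP well above the ER+
# fraction among cases shows the subtype signal survives re-ranking.
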