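# episnp

Selection of **interacting SNP groups** for case-control disease risk
prediction, with the additive baselines they are measured against.

Genome-wide association workflows usually score variants one at a time and
summarize risk with a polygenic risk score (PRS),
`PRS_i = Σ_s β_s · g_si`, where `g_si ∈ {0, 1, 2}` is individual *i*'s
dosage of the effect allele of SNP *s* and `β_s` its per-allele log odds
ratio. That additive view cannot express epistasis — interactions between
variants whose joint effect is invisible marginally. `episnp` implements a
two-module, machine-learning alternative developed for breast-cancer
case-control cohorts:

1. **Gain ranking.** A gradient-boosted tree ensemble (binary logistic
   objective) is fitted on all SNPs; each SNP is scored by its *gain* — the
   average training-loss reduction of the splits that use it — giving an
   interaction-aware candidate ranking.
2. **Adaptive iterative search.** From the gain-sorted candidates, a top
   list and a bottom list of *M* SNPs are formed. Each pass re-ranks the
   two lists with boosting models trained on each list's SNPs alone,
   substitutes the top list's lowest-ranked SNP with the bottom list's
   highest-ranked one, and grows both windows by *W*, until the windows
   overlap. Epistatic partners buried deep in the initial ranking surface
   when a window model sees them together. For every group size *k*, a
   linear-kernel SVM (`κ(x_i, x_j) = x_iᵀ x_j`) on the top-*k* SNPs is
   scored on validation data by average precision; the best (M, W, k)
   defines the selected group.
3. **Back-end.** The linear SVM on the selected group predicts case status
   for unseen samples.

Evaluation follows the repeated stratified nested cross-validation protocol
(default 10 × 5-fold: test folds never touch selection; an inner validation
fold steers the search), with precision-recall metrics:
`Precision = TP/(TP+FP)`, `Recall = TP/(TP+FN)`, and
`AP = Σ_i (recall_i − recall_{i−1}) · precision_i` over every score
cut-off; mAP (reported ×100) averages AP over test splits. Baselines:
the PRS as a classifier, a fixed literature SNP panel fed to the SVM, and
L1 / L2 / elastic-net (L1 ratio 0.4) logistic regressions at C = 0.7.
A two-cohort genotype simulator (Balding–Nichols divergence, Markov-chain
LD, logistic phenotypes with product- or XOR-type interactions, ER-subtype
labels among cases) makes every stage testable end to end.

## Worked example

From `examples/03_rank_and_select.py` (module 1 → module 2 → SVM on one
train/validation/test split of the simulated toy cohort):

```
candidates with positive gain: 292 of 300
top 5 by gain: [('rs00026', 5.84), ('rs00023', 4.68), ('rs00196', 3.98), ...]
chosen window M=8, increment W=5, group size S=50
best validation AP: 63.3
planted causal SNPs inside the selected group: 4/4 ['rs00010', 'rs00120', 'rs00200', 'rs00250']
test AP of the SVM on the selected group: 64.2
```

The simulator planted two additive risk SNPs and one XOR-type pair with no
additive signal of its own; all four end up inside the 50-SNP selected
group, and the SVM's test AP (64.2 on the 0–100 scale, against a 50% case
prevalence) reflects signal an additive PRS cannot fully express. The other
examples cover simulation (`01`), the PRS baseline on additive versus
epistatic data (`02`), the full repeated nested CV comparison (`04`), ER±
subtype classification from selected SNPs (`05`) and cross-cohort
transfer/merging (`06`). A thin `episnp` CLI wraps the same functions
(`episnp simulate|rank|select|prs|baseline|run|transfer|merge`).

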