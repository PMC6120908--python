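"""The method's two selection modules on one training/validation split:
gain ranking by gradient tree boosting, then the adaptive iterative
top/bottom-list search for the interacting-SNP group.
"""

import numpy as np
from sklearn.model_selection import train_test_split

import episnp as e
from episnp import presets

matrix, pheno, truth = e.make_toy_fixture(seed=3)
y = pheno.labels_for(matrix)

fold, test = train_test_split(np.arange(matrix.n_samples), test_size=0.2, stratify=y, random_state=3)
train, valid = train_test_split(fold, test_size=0.2, stratify=y[fold], random_state=3)

# module 1: boosting on all SNPs, gain importance ranking
model = e.fit_boosting(matrix.take_samples(train), y[train], presets.RANKING_PARAMS)
ranking = e.rank_snps_by_gain(model)
candidates = e.candidate_snps(ranking)
print(f"candidates with positive gain: {len(candidates)} of {matrix.n_snps}")
print("top 5 by gain:", [(s, round(g, 2)) for s, g in ranking.entries[:5]])

# module 2: adaptive iterative search over window sizes M and increments W
result = e.select_best_window(
    candidates,
    matrix.take_samples(train), y[train],
    matrix.take_samples(valid), y[valid],
    presets.SEARCH_SMALL,
    presets.RERANK_PARAMS,
)
print(f"chosen window M={result.chosen_m}, increment W={result.chosen_w}, "
      f"group size S={result.group_size}")
print(f"best validation AP: {100 * result.best_ap:.1f}")
hits = [s for s in truth.causal_snp_ids if s in result.selected_snps]
print(f"planted causal SNPs inside the selected group: {len(hits)}/4 {hits}")

# back-end: linear SVM on the selected group, scored on untouched test data
sub = matrix.restrict_snps(result.selected_snps)
scores = e.svm_train_predict(sub.take_samples(fold), y[fold], sub.take_samples(test))
print(f"test AP of the SVM on the selected group: "
      f"{100 * e.average_precision_from_scores(scores, y[test]):.1f}")
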