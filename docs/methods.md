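# Methods

## The selection method

The package targets the regime of case-control genotype studies:
`p ≫ n` additive-encoded SNP dosages (0/1/2 counts of the minor allele),
a few hundred to a few thousand samples, and the suspicion that part of
the heritable signal lives in SNP-SNP interactions that additive models
(single-SNP tests, PRS, penalized logistic regression) cannot express.

**Module 1 — gain ranking.** A gradient-boosted decision-tree ensemble
with the binary logistic objective is fitted on all SNPs (xgboost
backend; histogram trees, single thread, fixed seed — reruns are
bit-identical). Each SNP's importance is its *gain*: the average
training-loss reduction over the splits that use it. We use the
per-split average (xgboost's `gain`) rather than total gain, so a SNP
used in few but decisive splits — the signature of an interaction
partner that only matters inside the right subtree — is not swamped by
frequently-split marginal SNPs. SNPs never used in any split have no
gain and are excluded from the candidate list.

**Module 2 — adaptive iterative search.** Candidates are sorted by gain.
A *top list* (first M) and *bottom list* (last M) are formed; each pass

1. re-ranks both lists with two boosting models trained independently on
   each list's SNPs only — in a short list, an epistatic pair dominates
   the restricted model even if its global gain was modest;
2. substitutes the top list's lowest-ranked SNP with the bottom list's
   highest-ranked SNP (one exchange per direction per pass);
3. grows both windows by W.

Passes repeat until the windows would overlap (top span + bottom span
reaching the candidate count), so a run takes at most ⌈N/(2W)⌉ + 1
passes and the output is always a permutation of the candidates. For
each group size k, a linear SVM on the top-k SNPs of the final ordering
is scored on validation data by average precision; the search runs for
every (M, W) on the configured grids and the (M, W, k) with the best
validation AP defines the selected group. Ties break toward smaller k,
then smaller M, then smaller W.

*Ordering semantics.* The substitution step needs the two window
rankings only to identify which pair of SNPs to exchange. Two readings
are implemented (`SearchConfig.resort_windows`): the default keeps the
global ordering intact apart from the exchange; the alternative also
re-sorts each window block by its window model's gains every pass.
The default was chosen after measuring both on planted-signal fixtures:
late passes operate on windows of half the candidate list, where a
window model's gain estimates are noisy, and re-sorting those large
blocks repeatedly scrambles the head of the list badly enough to undo
the concentration the substitutions achieve (causal-recovery dropped
from 9/10 to 5-6/10 fixture seeds). With substitution-only ordering the
window models act as detectors and the ordering accumulates their
verdicts one exchange at a time.

**Back-end.** A linear-kernel soft-margin SVM (κ(x,y) = xᵀy, C = 1 by
default; the reference protocol leaves C unstated) fitted on the
training fold restricted to the selected SNPs; its continuous decision
scores rank test samples for AP. A linear back-end deliberately
restricts what selection can exploit: an interaction helps only through
whatever linear projection it has (see *Limitations*).

## Evaluation protocol

Repeated stratified nested CV, default 10 repetitions × 5 outer folds.
Per repetition the data are split 4:1 into training fold and test data
(stratified); the training fold is split into 5 stratified inner folds —
inner fold 1 is the validation data that steers the search (a
`rotate_inner` flag rotates it per outer fold instead), folds 2-5 merged
form the training set that fits the ranking and window models. Test
samples never participate in tuning or selection; `check_no_leakage`
asserts the partitions are disjoint on every split. Hyperparameter
tuning, when enabled, is a two-stage grid search on the training fold:
(trees, depth, learning rate) by stratified inner-CV log-loss with full
subsampling, then the subsampling rate with the triple fixed; ties
prefer smaller depth, fewer trees, smaller learning rate.

Metrics are computed by explicit enumeration of every distinct score as
a cut-off, descending; tied scores enter together at one threshold
(which changes AP relative to per-sample enumeration — deliberate, and
pinned by tests against an independent literal-loop oracle and against
scikit-learn's average-precision implementation at 1e-9). mAP is the
mean AP over test splits, reported ×100; the spread is the sample
standard deviation.

The ER-subtype task restricts to cases with known estrogen-receptor
status, re-ranks the supplied SNP union by boosting gain against ER
labels (zero-gain SNPs dropped), and reports per-k mAP and overall
accuracy from a stratified 10-fold CV of the linear SVM.

## Parameters that matter

| parameter | default | role |
|---|---|---|
| tree depth | 2 (library default) | interaction order a tree can express; 2-3 suffices for pairs |
| learning rate | 0.01 | shrinkage per tree; small rates need many trees |
| n_trees | 500 | fixed grid axis; no early stopping |
| subsample | 0.5 | row sampling per tree; 40-60% works best in this protocol |
| colsample | 1.0 | column sampling per tree; < 1 forces exploration across SNPs |
| M grid | 2, 4, 6, 8, 20, 30 | initial window sizes of the search |
| W grid | 1, 2, 3, 4, 5 | window growth per pass |
| max group size | 600 | cap on the selected-group size S |
| PRS weight scale | ln(OR) | log odds ratio per effect allele; a flag switches to raw OR |
| penalized C / L1 ratio | 0.7 / 0.4 | the reference baselines' fixed settings |

The library defaults for depth and learning rate are the optima the
reference protocol reports on full-size cohorts (~10³ samples, 1.25×10⁵
SNPs). The shipped desk-scale presets (`episnp.presets`) differ
deliberately: a 400-sample, 300-SNP study supports fewer, deeper trees —
ranking uses 300 trees of depth 3, learning rate 0.05, subsample 0.6,
colsample 0.3 (column sampling gives marginally-invisible interaction
partners a chance to root a tree and expose their partner one level
down); window re-ranking uses 150 trees of depth 3 with the full column
view, since the window is already a narrow subset and stable gains
matter more than exploration. The preset search grid (M ∈ {8, 30},
W = 5, k ∈ {50, 100}) keeps selected-group fractions (≈17-33% of
candidates) in the same regime as the full-scale protocol's reported
groups, and keeps a 10-seed study inside minutes on one CPU. All preset
problem sizes were fixed once at design time and are shared by the
examples, the test suite and `scripts/acceptance.py`.

## The simulator

`episnp.simulate` generates what the method needs to be tested against,
and nothing more:

* **Structure** — per-SNP ancestral frequency from a uniform MAF range;
  cohort frequencies from the Balding–Nichols Beta distribution at a
  given Fst (clamped away from 0/1 with a warning in the degenerate
  tail). Two cohorts emulate a discovery/validation cohort pair.
* **LD** — a first-order Markov copying chain along adjacent SNPs:
  each haplotype allele copies its left neighbour with probability
  `ld_decay`. Copying mixes frequencies (`f_s = ld·f_{s−1} +
  (1−ld)·p_s`); `effective_frequencies` exposes the induced marginals
  and the frequency invariants are tested against those.
* **Phenotype** — logistic liability with additive marginal terms
  `β·g`, product interactions `β·g_i·g_j` and carrier-XOR interactions
  `β·1[(g_i>0) ≠ (g_j>0)]`. A `None` intercept auto-centres the
  liability so the case fraction lands near one half. ER± labels among
  cases follow their own logistic model; controls stay `unknown`.

What it does *not* emulate: coalescent-accurate LD blocks and
recombination maps, rare variants and realistic MAF spectra, genotyping
error/missingness mechanisms, covariates, or linked selection. Passing
tests on these fixtures therefore show that the algorithmic machinery
behaves as specified under controlled signal — not that the method will
attain any particular accuracy on real genotype data.

A note on XOR effects and MAF: a carrier-XOR term has exactly zero
linear signal when carrier frequency is ½ (MAF ≈ 0.29) and a partial
linear "leakage" elsewhere. Since the back-end is a linear SVM, the toy
fixture draws MAFs from 0.35-0.5 (common variants, carrier frequency
0.58-0.75), so an XOR pair is worth retaining for the validation-AP
argmax once selection has surfaced it. The pure-epistasis fixture used
for the interaction-advantage study keeps the same range: there the PRS
is handed the *generating* betas applied additively — the best additive
story available — and still fails, because the additive projection of
an XOR effect has the wrong shape and sign structure.

## Numerical and degenerate-case choices

* Gain ties in rankings break by training-matrix column order
  (deterministic); the ranking is otherwise permutation-equivariant up
  to xgboost's column-order-dependent tie handling inside trees.
* `2M ≥ |candidates|` at entry: the search runs zero passes and returns
  the input order (immediate-overlap degenerate case).
* Windows of fewer than two SNPs, or windows whose model never splits,
  are returned unchanged by the re-ranker; zero-gain window members
  keep their incoming relative order behind the positive-gain ones.
* Missing genotype calls are excluded SNP-wise by default (a column
  with ≥1 missing call is dropped; `axis="sample"` switches to
  row-wise). The reference protocol reports a final common SNP count,
  which implies column-wise exclusion; the choice is surfaced as a flag
  because the protocol text does not pin it down.
* PRS weights default to ln(OR); whether the reference used OR or
  ln(OR) is not stated, so both are supported.
* The L2 penalty yields no exact zeros, so its "selection" is top-k by
  |coefficient| and requires an explicit k (pair it with the proposed
  method's group size to compare at equal panel width).
* Penalized solvers: saga for L1/elastic net, lbfgs for L2, tolerance
  1e-6, 5000 iterations; non-convergence raises with diagnostics rather
  than silently returning a half-fitted model. Dosages share a scale,
  so standardization is off.
* All randomness flows from explicit integer seeds (numpy Generators,
  xgboost seeds, stratified fold seeds); identical configs reproduce
  reports byte for byte.

## Known limitations

* The linear back-end bounds what interaction selection can buy:
  a perfectly balanced XOR pair is selectable (module 2 sees it) but
  unusable by the SVM. A non-linear back-end would decouple these.
* Validation APs on desk-scale fixtures carry large sampling noise
  (~60-80 validation samples); the (M, W, k) argmax inherits it.
  That is a property of the protocol at small n, not of the
  implementation, and it is why recovery criteria are stated over
  seeds rather than per run.
* The search's swap budget is one exchange per direction per pass, so
  rescuing a deeply-buried interacting pair takes many passes; with
  large W (few passes) deep pairs may stay buried.
* Hyperparameter tuning cost is the full grid times inner folds times
  tree fits; the presets skip tuning and use fixed study-scale
  parameters instead.
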