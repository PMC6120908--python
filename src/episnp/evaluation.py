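"""Evaluation layer: PR metrics, the linear-SVM back-end, and the
repeated nested cross-validation and ER-subtype protocols.

Precision, recall and average precision (AP) are computed by explicit
enumeration of every distinct score as a cut-off (descending); tied scores
enter at a single threshold together.  AP is the recall-increment weighted
sum of precisions,

    AP = sum_i (recall_i - recall_{i-1}) * precision_i,   recall_0 = 0,

the same summary a PR curve integrates to.  mAP is the mean of AP over
test splits and is conventionally reported on the 0-100 scale.

The risk-prediction protocol is 10 repetitions of stratified 5-fold CV.
Within each repetition the data are split 4:1 into training fold and test
data; the training fold is further split into 5 stratified inner folds —
one is the validation data that steers SNP selection, the other four are
merged into the training set that fits the ranking model.  Test samples
never touch selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data_io import GenotypeMatrix, PhenotypeTable, WeightTable

# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0


@dataclass(frozen=True)
class PrCurve:
    """Precision/recall at each distinct score threshold, descending."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.recall, dtype=float)
        p = np.asarray(self.precision, dtype=float)
        if np.any(np.diff(r) < -1e-12):
            raise ValueError("recall must be non-decreasing along descending thresholds")
        if np.any((p < 0) | (p > 1)) or np.any((r < 0) | (r > 1)):
            raise ValueError("precision/recall must lie in [0, 1]")


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-d arrays of equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if labels.sum() == 0:
        raise ValueError("at least one positive label required")
    return scores, labels


def precision_recall_curve(scores, labels) -> PrCurve:
    """PR curve over every distinct score cut-off, highest first.

    A sample is predicted positive when its score is >= the cut-off, so
    tied scores cross the threshold together.
    """
    scores, labels = _check_scores_labels(scores, labels)
    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    y_sorted = labels[order]
    cum_tp = np.cumsum(y_sorted)
    n_pos = int(labels.sum())
    # last index of each tie block marks the threshold where the block enters
    distinct = np.flatnonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])
    tp = cum_tp[distinct]
    n_pred = distinct + 1
    precision = tp / n_pred
    recall = tp / n_pos
    return PrCurve(thresholds=s_sorted[distinct], precision=precision, recall=recall)


def average_precision(curve: PrCurve) -> float:
    """Recall-increment weighted mean of precisions along the curve."""
    recall = np.asarray(curve.recall, dtype=float)
    prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev) * np.asarray(curve.precision, dtype=float)))


def average_precision_from_scores(scores, labels) -> float:
    return average_precision(precision_recall_curve(scores, labels))


def mean_average_precision(aps: Sequence[float] | Sequence["SplitResult"]) -> tuple[float, float]:
    """Mean and sample standard deviation of per-split AP."""
    if len(aps) == 0:
        raise ValueError("no split results to average")
    vals = np.asarray([a.test_ap if isinstance(a, SplitResult) else float(a) for a in aps])
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return float(np.mean(vals)), sd


def overall_accuracy(predicted_labels, labels) -> float:
    """Percentage of correctly classified instances (0-100)."""
    pred = np.asarray(predicted_labels)
    y = np.asarray(labels)
    if pred.shape != y.shape or pred.size == 0:
        raise ValueError("predictions and labels must be equal-length non-empty arrays")
    return 100.0 * float(np.mean(pred == y))


# ---------------------------------------------------------------------------
# SVM back-end


@dataclass(frozen=True)
class SvmParams:
    """Linear-kernel SVM settings; C is the soft-margin penalty."""

    C: float = 1.0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")


def svm_train_predict(train_X, train_labels, test_X, params: SvmParams = SvmParams()) -> np.ndarray:
    """Fit a linear-kernel maximum-margin classifier on dosages and return
    continuous decision scores on the test samples (AP ranks by score)."""
    if isinstance(train_X, GenotypeMatrix):
        train_X = train_X.values()
    if isinstance(test_X, GenotypeMatrix):
        test_X = test_X.values()
    y = np.asarray(train_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("SVM training requires both classes present")
    clf = SVC(kernel="linear", C=params.C)
    clf.fit(np.asarray(train_X, dtype=float), y)
    return clf.decision_function(np.asarray(test_X, dtype=float))


# ---------------------------------------------------------------------------
# CV protocol


@dataclass(frozen=True)
class CvScheme:
    """Repeated stratified nested CV layout (defaults: 10 x 5-fold)."""

    n_repetitions: int = 10
    n_outer_folds: int = 5
    n_inner_folds: int = 5
    stratified: bool = True
    rotate_inner: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repetitions < 1 or self.n_outer_folds < 2 or self.n_inner_folds < 2:
            raise ValueError("need >=1 repetition and >=2 outer/inner folds")
        if not self.stratified:
            raise ValueError("the protocol is stratified by construction")


@dataclass
class SplitResult:
    """One outer split's outcome: selection, scores and bookkeeping ids."""

    repetition: int
    fold: int
    method: str
    selected_snps: tuple[str, ...]
    chosen_m: int | None
    chosen_w: int | None
    test_ap: float
    train_ids: tuple[str, ...]
    valid_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    params: dict = field(default_factory=dict)

    @property
    def group_size(self) -> int:
        return len(self.selected_snps)


METHOD_NAMES = ("proposed", "proposed_no_search", "l1", "l2", "elasticnet", "prs", "fixed_panel")


@dataclass(frozen=True)
class MethodSpec:
    """Which selection route an outer split runs, with its settings.

    ``boosting``/``rerank`` are :class:`~episnp.boosting.BoostingParams`
    (rerank defaults to the ranking params); ``search`` is a
    :class:`~episnp.search.SearchConfig`; ``tune_grid`` a
    :class:`~episnp.boosting.ParamGrid` enabling per-training-fold
    hyperparameter tuning when given.  ``weights`` is required for
    ``prs``, ``panel`` for ``fixed_panel``, ``penalized`` for the
    regularized-regression routes.
    """

    name: str = "proposed"
    boosting: object | None = None
    rerank: object | None = None
    search: object | None = None
    svm: SvmParams = SvmParams()
    tune_grid: object | None = None
    weights: WeightTable | None = None
    panel: tuple[str, ...] | None = None
    penalized: object | None = None
    k_target: int = 100

    def __post_init__(self) -> None:
        if self.name not in METHOD_NAMES:
            raise ValueError(f"unknown method {self.name!r}; expected one of {METHOD_NAMES}")
        if self.name == "prs" and self.weights is None:
            raise ValueError("method 'prs' requires a weight table")
        if self.name == "fixed_panel" and not self.panel:
            raise ValueError("method 'fixed_panel' requires a SNP panel")


def _stratified_folds(y: np.ndarray, n_folds: int, seed: int):
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def _derive_seed(seed: int, *keys: int) -> int:
    out = int(seed) % (2**31 - 1)
    for k in keys:
        out = (out * 1_000_003 + int(k) + 1) % (2**31 - 1)
    return out


def _run_split(
    matrix: GenotypeMatrix,
    y: np.ndarray,
    train_idx: np.ndarray,
    valid_idx: np.ndarray,
    test_idx: np.ndarray,
    spec: MethodSpec,
    seed: int,
) -> tuple[tuple[str, ...], int | None, int | None, float, dict]:
    """Execute one method on one (training set, validation, test) split."""
    from . import baselines as _baselines
    from . import boosting as _boosting
    from . import prs as _prs
    from . import search as _search

    fold_idx = np.concatenate([train_idx, valid_idx])  # the training fold
    params_used: dict = {}
    chosen_m = chosen_w = None

    if spec.name == "prs":
        result = _prs.compute_prs(matrix.take_samples(test_idx), spec.weights)
        scores = result.scores
        selected = result.used_snps
    else:
        if spec.name in ("proposed", "proposed_no_search"):
            bparams = spec.boosting if spec.boosting is not None else _boosting.BoostingParams()
            bparams = _boosting.replace_seed(bparams, _derive_seed(seed, 11))
            if spec.tune_grid is not None:
                bparams = _boosting.tune_hyperparameters(
                    matrix.take_samples(fold_idx), y[fold_idx], spec.tune_grid, seed=_derive_seed(seed, 13)
                )
            model = _boosting.fit_boosting(matrix.take_samples(train_idx), y[train_idx], bparams)
            ranking = _boosting.rank_snps_by_gain(model)
            candidates = _boosting.candidate_snps(ranking)
            params_used["boosting"] = _boosting.params_dict(bparams)
            if spec.name == "proposed":
                sconfig = spec.search if spec.search is not None else _search.SearchConfig()
                rerank = spec.rerank if spec.rerank is not None else bparams
                result = _search.select_best_window(
                    candidates,
                    matrix.take_samples(train_idx),
                    y[train_idx],
                    matrix.take_samples(valid_idx),
                    y[valid_idx],
                    sconfig,
                    rerank,
                    svm_params=spec.svm,
                )
                selected = result.selected_snps
                chosen_m, chosen_w = result.chosen_m, result.chosen_w
            else:
                selected = tuple(candidates)
        elif spec.name in ("l1", "l2", "elasticnet"):
            pconfig = spec.penalized if spec.penalized is not None else _baselines.PenalizedConfig(penalty=spec.name)
            if pconfig.penalty != spec.name:
                raise ValueError(f"penalized config penalty {pconfig.penalty!r} != method {spec.name!r}")
            selected = tuple(
                _baselines.penalized_lr_select(
                    matrix.take_samples(fold_idx), y[fold_idx], pconfig, k_target=spec.k_target
                )
            )
        elif spec.name == "fixed_panel":
            panel = _baselines.fixed_panel_baseline(matrix, spec.panel)
            selected = panel.matrix.snp_ids
        else:  # pragma: no cover - guarded by MethodSpec
            raise ValueError(spec.name)
        if not selected:
            raise ValueError(f"method {spec.name!r} selected no SNPs")
        sub = matrix.restrict_snps(selected)
        scores = svm_train_predict(
            sub.take_samples(fold_idx), y[fold_idx], sub.take_samples(test_idx), spec.svm
        )
    ap = average_precision_from_scores(scores, y[test_idx])
    return tuple(selected), chosen_m, chosen_w, ap, params_used


def repeated_nested_cv(
    matrix: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    scheme: CvScheme,
    spec: MethodSpec,
    progress: Callable[[SplitResult], None] | None = None,
) -> list[SplitResult]:
    """Run the full repeated nested CV protocol for one method.

    Returns ``n_repetitions * n_outer_folds`` :class:`SplitResult` rows
    (50 under the defaults), each with its test AP and the ids of the
    disjoint training/validation/test partitions.
    """
    y = phenotypes.labels_for(matrix)
    if len(np.unique(y)) < 2:
        raise ValueError("both cases and controls are required")
    results: list[SplitResult] = []
    for rep in range(scheme.n_repetitions):
        outer = _stratified_folds(y, scheme.n_outer_folds, _derive_seed(scheme.seed, rep))
        for fold, (fold_idx, test_idx) in enumerate(outer):
            inner = _stratified_folds(
                y[fold_idx], scheme.n_inner_folds, _derive_seed(scheme.seed, rep, fold)
            )
            inner_pick = fold % scheme.n_inner_folds if scheme.rotate_inner else 0
            inner_train, inner_valid = inner[inner_pick]
            train_idx = fold_idx[inner_train]
            valid_idx = fold_idx[inner_valid]
            selected, m, w, ap, used = _run_split(
                matrix, y, train_idx, valid_idx, test_idx, spec, _derive_seed(scheme.seed, rep, fold, 7)
            )
            res = SplitResult(
                repetition=rep,
                fold=fold,
                method=spec.name,
                selected_snps=selected,
                chosen_m=m,
                chosen_w=w,
                test_ap=ap,
                train_ids=tuple(matrix.sample_ids[i] for i in train_idx),
                valid_ids=tuple(matrix.sample_ids[i] for i in valid_idx),
                test_ids=tuple(matrix.sample_ids[i] for i in test_idx),
                params=used,
            )
            results.append(res)
            if progress is not None:
                progress(res)
    return results


def check_no_leakage(results: Sequence[SplitResult]) -> None:
    """Assert test/train/validation partitions never share a sample."""
    for r in results:
        test = set(r.test_ids)
        fold = set(r.train_ids) | set(r.valid_ids)
        if test & fold:
            raise AssertionError(
                f"leakage: repetition {r.repetition} fold {r.fold} shares "
                f"{len(test & fold)} samples between test and training fold"
            )
        if set(r.train_ids) & set(r.valid_ids):
            raise AssertionError(
                f"leakage: repetition {r.repetition} fold {r.fold} shares samples "
                "between training set and validation data"
            )


# ---------------------------------------------------------------------------
# ER-subtype protocol


def er_subtype_task(
    matrix: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    snp_union: Sequence[str],
    k_grid: Sequence[int],
    seed: int = 0,
    boosting_params: object | None = None,
    svm_params: SvmParams = SvmParams(),
    n_folds: int = 10,
) -> dict[int, dict[str, float]]:
    """Classify ER+ vs ER- cases from a SNP set, per top-k panel size.

    The SNP union is re-ranked by boosting gain against the ER labels
    (zero-gain SNPs are discarded), then for each ``k`` the top-k SNPs
    feed a stratified ``n_folds``-fold CV with the linear SVM back-end.
    Returns per-k mAP, its sd, and mean overall accuracy (all 0-100 except
    where noted: mAP values here are on the 0-1 scale; callers scale for
    reporting).
    """
    from . import boosting as _boosting

    if not snp_union:
        raise ValueError("snp_union must be non-empty")
    pheno = phenotypes.for_samples(matrix.sample_ids)
    known = (pheno.status == 1) & np.isin(pheno.er_status, ("positive", "negative"))
    if not known.any():
        raise ValueError("no cases with known ER status")
    idx = np.flatnonzero(known)
    sub = matrix.take_samples(idx).restrict_snps(list(snp_union))
    y = (pheno.er_status[idx] == "positive").astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both ER+ and ER- cases are required")

    bparams = boosting_params if boosting_params is not None else _boosting.BoostingParams()
    bparams = _boosting.replace_seed(bparams, _derive_seed(seed, 31))
    model = _boosting.fit_boosting(sub, y, bparams)
    ranking = _boosting.rank_snps_by_gain(model)
    surviving = _boosting.candidate_snps(ranking)

    out: dict[int, dict[str, float]] = {}
    folds = _stratified_folds(y, n_folds, _derive_seed(seed, 37))
    for k in k_grid:
        k_eff = min(int(k), len(surviving))
        panel = sub.restrict_snps(surviving[:k_eff])
        aps: list[float] = []
        accs: list[float] = []
        for tr, te in folds:
            scores = svm_train_predict(panel.take_samples(tr), y[tr], panel.take_samples(te), svm_params)
            aps.append(average_precision_from_scores(scores, y[te]))
            accs.append(overall_accuracy((scores > 0).astype(int), y[te]))
        m, sd = mean_average_precision(aps)
        out[k_eff] = {"map": m, "sd": sd, "accuracy": float(np.mean(accs))}
    return out
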