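"""Module 2 of the selection method: the adaptive iterative SNP search.

Starting from the gain-sorted candidate list, a *top list* of the M
highest-ranked and a *bottom list* of the M lowest-ranked SNPs are formed.
Each pass:

1. re-ranks the two lists with two boosting models trained independently
   on just that list's SNPs (interactions hidden inside a short list become
   visible once the list is modelled on its own);
2. swaps the top list's lowest-ranked SNP with the bottom list's
   highest-ranked SNP (one exchange per direction per pass);
3. grows both windows by W.

Passes repeat until the two windows would overlap (top span + bottom span
reaching the candidate count); SNPs never captured by a window keep their
original relative order between the final blocks.  For every candidate
group size k, a linear SVM on the top-k SNPs of the final ordering is
scored on the validation data by AP; the (M, W, k) triple with the best
validation AP defines the selected interacting-SNP group.

The interacting-pair rescue this buys: an epistatic SNP with no marginal
signal starts deep in the gain ranking, meets its partner inside the
bottom window, dominates the window-restricted re-ranking, and is swapped
upward — which a single global ranking pass cannot do.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .boosting import BoostingParams, fit_boosting
from .data_io import GenotypeMatrix
from .evaluation import SvmParams, average_precision_from_scores, svm_train_predict

REFERENCE_WINDOW_SIZES = (2, 4, 6, 8, 20, 30)
REFERENCE_WINDOW_INCREMENTS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class SearchConfig:
    """Grid of window sizes M and window increments W, plus the group cap."""

    window_sizes: tuple[int, ...] = REFERENCE_WINDOW_SIZES
    window_increments: tuple[int, ...] = REFERENCE_WINDOW_INCREMENTS
    max_group_size: int = 600
    k_grid: tuple[int, ...] | None = None
    resort_windows: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.window_sizes or not self.window_increments:
            raise ValueError("window grids must be non-empty")
        if any(m < 1 for m in self.window_sizes) or any(w < 1 for w in self.window_increments):
            raise ValueError("window sizes and increments must be >= 1")
        if self.max_group_size < 1:
            raise ValueError("max_group_size must be >= 1")


@dataclass
class SearchResult:
    """Best (M, W, k) over the grid with the full validation-AP trace."""

    selected_snps: tuple[str, ...]
    chosen_m: int
    chosen_w: int
    best_ap: float
    ap_trace: dict[tuple[int, int], dict[int, float]]
    iterations: dict[tuple[int, int], int]
    final_orders: dict[tuple[int, int], tuple[str, ...]] = field(default_factory=dict)

    @property
    def group_size(self) -> int:
        return len(self.selected_snps)


def default_k_grid(n: int, cap: int = 600) -> tuple[int, ...]:
    """Dense for small k (where the method's optima live), coarse beyond."""
    ks = list(range(1, min(n, 10) + 1))
    ks += [12, 16, 20, 25, 30, 40, 50, 75, 100, 150, 200, 300, 400, 600]
    ks = sorted({k for k in ks if 1 <= k <= min(n, cap)})
    return tuple(ks)


def _rerank_window(
    window: Sequence[str],
    train: GenotypeMatrix,
    labels: np.ndarray,
    params: BoostingParams,
    seed: int,
) -> list[str]:
    """Order a window's SNPs by gain of a model fit on that window alone.

    Zero-gain SNPs follow the positive-gain ones, keeping their incoming
    relative order; a window too small or degenerate to split is returned
    unchanged.
    """
    if len(window) < 2:
        return list(window)
    sub = train.restrict_snps(list(window))
    model = fit_boosting(sub, labels, dataclasses.replace(params, seed=seed))
    gains = model.gain_importances()
    pos = {s: i for i, s in enumerate(window)}
    return sorted(window, key=lambda s: (-gains[s], pos[s]))


def adaptive_iterative_search(
    candidates: Sequence[str],
    train_matrix: GenotypeMatrix,
    train_labels,
    valid_matrix: GenotypeMatrix,
    valid_labels,
    M: int,
    W: int,
    params: BoostingParams = BoostingParams(),
    svm_params: SvmParams = SvmParams(),
    k_grid: Sequence[int] | None = None,
    max_group_size: int = 600,
    resort_windows: bool = False,
) -> tuple[list[str], dict[int, float], int]:
    """One (M, W) run of the iterative top/bottom-list search.

    Returns the re-ranked candidate list (always a permutation of the
    input), the validation AP for each k over the final list, and the
    number of swap passes executed.  If the initial windows already cover
    the list (2M >= number of candidates) no pass runs and the input
    order is returned.

    By default the window models only *identify* the substitution pair
    (the top list's lowest-ranked and the bottom list's highest-ranked
    SNP), which exchange positions; the rest of the ordering is kept.
    ``resort_windows=True`` additionally re-sorts each window block by
    its window model's gains every pass — a stronger intervention whose
    late large-window re-sorts carry much more sampling noise.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    if len(set(candidates)) != len(candidates):
        raise ValueError("duplicate SNPs in candidate list")
    y_train = np.asarray(train_labels, dtype=int)
    y_valid = np.asarray(valid_labels, dtype=int)
    for y in (y_train, y_valid):
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
    if M < 1 or W < 1:
        raise ValueError("M and W must be >= 1")

    N = len(candidates)
    order = list(candidates)
    top_span, bot_span = M, M
    iterations = 0
    while top_span + bot_span < N:
        top = _rerank_window(
            order[:top_span], train_matrix, y_train, params, seed=params.seed + 2 * iterations
        )
        bottom = _rerank_window(
            order[N - bot_span :], train_matrix, y_train, params, seed=params.seed + 2 * iterations + 1
        )
        if resort_windows:
            # exchange the top list's weakest with the bottom list's strongest
            top[-1], bottom[0] = bottom[0], top[-1]
            order = top + order[top_span : N - bot_span] + bottom
        else:
            i = order.index(top[-1])  # top list's lowest-ranked SNP
            j = order.index(bottom[0])  # bottom list's highest-ranked SNP
            order[i], order[j] = order[j], order[i]
        top_span += W
        bot_span += W
        iterations += 1

    if k_grid is None:
        k_grid = default_k_grid(N, cap=max_group_size)
    ap_by_k = evaluate_topk_curve(order, train_matrix, y_train, valid_matrix, y_valid, k_grid, svm_params)
    return order, ap_by_k, iterations


def evaluate_topk_curve(
    ranking: Sequence[str],
    train_matrix: GenotypeMatrix,
    train_labels,
    valid_matrix: GenotypeMatrix,
    valid_labels,
    k_grid: Sequence[int],
    svm_params: SvmParams = SvmParams(),
) -> dict[int, float]:
    """Validation AP of a linear SVM on the top-k SNPs, for each k."""
    ranking = list(ranking)
    y_train = np.asarray(train_labels, dtype=int)
    y_valid = np.asarray(valid_labels, dtype=int)
    out: dict[int, float] = {}
    for k in k_grid:
        k = int(k)
        if k < 1 or k > len(ranking):
            raise ValueError(f"k={k} outside 1..{len(ranking)}")
        snps = ranking[:k]
        scores = svm_train_predict(
            train_matrix.restrict_snps(snps), y_train, valid_matrix.restrict_snps(snps), svm_params
        )
        out[k] = average_precision_from_scores(scores, y_valid)
    return out


def select_best_window(
    candidates: Sequence[str],
    train_matrix: GenotypeMatrix,
    train_labels,
    valid_matrix: GenotypeMatrix,
    valid_labels,
    config: SearchConfig = SearchConfig(),
    params: BoostingParams = BoostingParams(),
    svm_params: SvmParams = SvmParams(),
    keep_orders: bool = False,
) -> SearchResult:
    """Run the search for every (M, W) pair and pick the best (M, W, k).

    The winner maximizes validation AP; exact ties break toward smaller
    k, then smaller M, then smaller W.
    """
    candidates = list(candidates)
    k_grid = config.k_grid if config.k_grid is not None else default_k_grid(
        len(candidates), cap=config.max_group_size
    )
    trace: dict[tuple[int, int], dict[int, float]] = {}
    iters: dict[tuple[int, int], int] = {}
    orders: dict[tuple[int, int], tuple[str, ...]] = {}
    best: tuple[float, int, int, int] | None = None  # (ap, k, M, W)
    best_order: list[str] | None = None
    for m in sorted(config.window_sizes):
        for w in sorted(config.window_increments):
            order, ap_by_k, n_iter = adaptive_iterative_search(
                candidates,
                train_matrix,
                train_labels,
                valid_matrix,
                valid_labels,
                m,
                w,
                params=params,
                svm_params=svm_params,
                k_grid=k_grid,
                max_group_size=config.max_group_size,
                resort_windows=config.resort_windows,
            )
            trace[(m, w)] = ap_by_k
            iters[(m, w)] = n_iter
            if keep_orders:
                orders[(m, w)] = tuple(order)
            for k in sorted(ap_by_k):
                ap = ap_by_k[k]
                cand = (ap, k, m, w)
                if best is None or ap > best[0] or (ap == best[0] and (k, m, w) < best[1:]):
                    best = cand
                    best_order = order
    ap, k, m, w = best
    return SearchResult(
        selected_snps=tuple(best_order[:k]),
        chosen_m=m,
        chosen_w=w,
        best_ap=ap,
        ap_trace=trace,
        iterations=iters,
        final_orders=orders,
    )
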