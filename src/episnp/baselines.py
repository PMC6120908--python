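"""Baseline SNP selectors: penalized logistic regression (L1 / L2 /
elastic net) and the fixed literature-panel feature restriction.

The regularized regressions use inverse strength C = 0.7 and, for elastic
net, L1 ratio 0.4 — the settings the reference evaluation fixes rather
than tunes.  L1 and elastic net select the SNPs with non-zero
coefficients (ordered by |coefficient|); L2 produces no exact zeros, so
its selection is the top-k by |coefficient|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .data_io import GenotypeMatrix

PENALTIES = ("l1", "l2", "elasticnet")


@dataclass(frozen=True)
class PenalizedConfig:
    penalty: str = "l1"
    C: float = 0.7
    l1_ratio: float = 0.4
    seed: int = 0
    tol: float = 1e-6
    max_iter: int = 5000

    def __post_init__(self) -> None:
        if self.penalty not in PENALTIES:
            raise ValueError(f"penalty must be one of {PENALTIES}, got {self.penalty!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if not (0.0 <= self.l1_ratio <= 1.0):
            raise ValueError("l1_ratio must be in [0, 1]")


def penalized_lr_select(
    matrix: GenotypeMatrix | np.ndarray,
    labels,
    config: PenalizedConfig = PenalizedConfig(),
    k_target: int | None = None,
) -> list[str]:
    """Fit the penalized logistic model and return the selected SNPs.

    L1/elastic net: SNPs with non-zero coefficient, by |coefficient|
    descending.  L2: top ``k_target`` by |coefficient| (required, since
    ridge never zeroes exactly).  Deterministic given the config seed.
    """
    if isinstance(matrix, GenotypeMatrix):
        snp_ids = list(matrix.snp_ids)
        X = matrix.values()
    else:
        X = np.asarray(matrix, dtype=float)
        snp_ids = [f"f{j}" for j in range(X.shape[1])]
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")

    l1_ratio = {"l1": 1.0, "l2": 0.0, "elasticnet": config.l1_ratio}[config.penalty]
    model = LogisticRegression(
        C=config.C,
        l1_ratio=l1_ratio,
        solver="lbfgs" if config.penalty == "l2" else "saga",
        tol=config.tol,
        max_iter=config.max_iter,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("error", category=ConvergenceWarning)
        try:
            model.fit(X, y)
        except ConvergenceWarning as exc:
            raise RuntimeError(
                f"penalized logistic regression did not converge "
                f"(penalty={config.penalty}, C={config.C}, tol={config.tol}, "
                f"max_iter={config.max_iter}): {exc}"
            ) from exc
    coef = model.coef_.ravel()
    order = sorted(range(len(snp_ids)), key=lambda j: (-abs(coef[j]), j))
    if config.penalty == "l2":
        if k_target is None:
            raise ValueError("k_target is required for the l2 penalty (no exact zeros)")
        return [snp_ids[j] for j in order[: int(k_target)]]
    return [snp_ids[j] for j in order if coef[j] != 0.0]


@dataclass(frozen=True)
class PanelResult:
    """Matrix restricted to a fixed SNP panel, plus absent panel members."""

    matrix: GenotypeMatrix
    missing_snps: tuple[str, ...]


def fixed_panel_baseline(matrix: GenotypeMatrix, panel_snp_ids) -> PanelResult:
    """Restrict the matrix to a literature panel (e.g. the 51 published
    risk SNPs); panel members absent from the matrix are reported."""
    panel = list(panel_snp_ids)
    present = set(matrix.snp_ids)
    kept = [s for s in panel if s in present]
    missing = tuple(s for s in panel if s not in present)
    if not kept:
        raise ValueError("no panel SNP present in the genotype matrix")
    return PanelResult(matrix=matrix.restrict_snps(kept), missing_snps=missing)
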