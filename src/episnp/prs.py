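"""Polygenic risk score baseline.

The PRS of individual *i* over *m* risk SNPs is the weighted allele count

    PRS_i = beta_1 g_1i + ... + beta_m g_mi,

where ``g_si`` is the dosage of the effect allele (0, 1 or 2) and
``beta_s`` the per-allele effect.  By convention the weight is the natural
log of the published odds ratio (``scale='log_or'``); ``scale='or'`` uses
the raw odds ratio instead for studies that report it that way.  The PRS
assumes independent SNPs with linear, additive effects — exactly the
assumption the interaction-aware selection method relaxes.

Used as a classifier, the score itself ranks samples: precision and
recall are computed at every distinct cut-off and summarized by AP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import MISSING, GenotypeMatrix, WeightTable
from .evaluation import PrCurve, average_precision, precision_recall_curve


@dataclass(frozen=True)
class PrsVector:
    """Per-sample scores plus provenance of the weights actually used."""

    scores: np.ndarray
    sample_ids: tuple[str, ...]
    used_snps: tuple[str, ...]
    skipped_snps: tuple[str, ...]

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores).all():
            raise ValueError("PRS scores must be finite")

    @property
    def n_snps_used(self) -> int:
        return len(self.used_snps)


def compute_prs(matrix: GenotypeMatrix, weights: WeightTable, scale: str = "log_or") -> PrsVector:
    """Score every sample over the weight-table SNPs present in the matrix.

    The matrix is assumed already aligned to effect alleles
    (see :func:`episnp.data_io.align_dosages_to_effect_allele`).  Weight
    SNPs absent from the matrix are skipped and reported in
    ``skipped_snps``; an empty intersection is an error, as are missing
    calls among the scored SNPs.
    """
    if scale not in ("log_or", "or"):
        raise ValueError("scale must be 'log_or' or 'or'")
    present = set(matrix.snp_ids)
    used = [s for s in weights.snp_ids if s in present]
    skipped = [s for s in weights.snp_ids if s not in present]
    if not used:
        raise ValueError("no weight-table SNP present in the genotype matrix")
    beta_all = weights.beta if scale == "log_or" else weights.odds_ratio
    beta = np.array([beta_all[weights.snp_ids.index(s)] for s in used])
    sub = matrix.restrict_snps(used)
    if (sub.dosage == MISSING).any():
        raise ValueError("missing genotype calls among PRS SNPs; drop or impute first")
    scores = sub.values() @ beta
    return PrsVector(
        scores=scores,
        sample_ids=matrix.sample_ids,
        used_snps=tuple(used),
        skipped_snps=tuple(skipped),
    )


def evaluate_prs_classifier(scores, labels) -> tuple[PrCurve, float]:
    """PR curve over every distinct PRS cut-off, and its AP."""
    curve = precision_recall_curve(scores, labels)
    return curve, average_precision(curve)
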