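"""Synthetic two-cohort case-control genotype data with planted signals.

The generator emulates the structure the selection method is designed to
exploit, at desk scale:

* population structure between two cohorts via the Balding-Nichols model —
  each SNP has an ancestral frequency ``p`` and each cohort draws its own
  frequency from ``Beta(p(1-Fst)/Fst, (1-p)(1-Fst)/Fst)``;
* local linkage disequilibrium via a first-order Markov copying chain along
  adjacent SNPs (each haplotype allele copies its left neighbour with
  probability ``ld_decay``, otherwise is drawn fresh);
* a logistic case/control phenotype with additive marginal effects and
  explicitly epistatic interaction terms, including XOR-type interactions
  that carry no marginal per-SNP signal;
* an estrogen-receptor (ER±) subtype label among cases, itself a logistic
  function of planted SNPs.

All draws derive from the config seed, so a fixed config reproduces its
dataset bit for bit.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_io import GenotypeMatrix, PhenotypeTable

_FREQ_CLAMP = (0.005, 0.995)
_PRODUCT = "product"
_XOR = "xor"


@dataclass(frozen=True)
class SimulationConfig:
    """Generating conditions for one synthetic dataset.

    ``n_samples`` is per cohort; sample ids are prefixed with the cohort
    letter (``A_0001`` ...), which is how downstream code recovers cohort
    membership.  ``intercept=None`` centres the liability so that the case
    fraction lands near one half, the balanced design the evaluation
    protocol stratifies for.
    """

    n_samples: int = 200
    n_snps: int = 300
    n_cohorts: int = 2
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.0
    fst: float = 0.0
    marginal_effects: tuple[tuple[int, float], ...] = ()
    interaction_effects: tuple[tuple[int, int, float, str], ...] = ()
    intercept: float | None = None
    er_effects: tuple[tuple[int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        if not (0.0 <= self.ld_decay < 1.0):
            raise ValueError(f"ld_decay must be in [0, 1), got {self.ld_decay}")
        if self.n_cohorts < 1 or self.n_cohorts > 26:
            raise ValueError("n_cohorts must be between 1 and 26")
        for idx, _ in self.marginal_effects:
            if not 0 <= idx < self.n_snps:
                raise ValueError(f"marginal effect index {idx} out of range")
        for i, j, _, kind in self.interaction_effects:
            if not (0 <= i < self.n_snps and 0 <= j < self.n_snps) or i == j:
                raise ValueError(f"interaction indices ({i}, {j}) invalid")
            if kind not in (_PRODUCT, _XOR):
                raise ValueError(f"interaction type must be 'product' or 'xor', got {kind!r}")
        for idx, _ in self.er_effects:
            if not 0 <= idx < self.n_snps:
                raise ValueError(f"er effect index {idx} out of range")

    @property
    def cohort_names(self) -> tuple[str, ...]:
        return tuple(string.ascii_uppercase[: self.n_cohorts])

    def snp_id(self, index: int) -> str:
        return f"rs{index:05d}"


@dataclass(frozen=True)
class TruthSet:
    """Ground truth of a simulated dataset, for recovery bookkeeping."""

    marginal_snps: tuple[tuple[str, float], ...]
    interaction_pairs: tuple[tuple[str, str, float, str], ...]
    er_snps: tuple[tuple[str, float], ...]
    config: SimulationConfig

    @property
    def causal_snp_ids(self) -> tuple[str, ...]:
        ids: list[str] = [s for s, _ in self.marginal_snps]
        for a, b, _, _ in self.interaction_pairs:
            ids.extend((a, b))
        seen: set[str] = set()
        return tuple(s for s in ids if not (s in seen or seen.add(s)))


def truth_set(config: SimulationConfig) -> TruthSet:
    return TruthSet(
        marginal_snps=tuple((config.snp_id(i), b) for i, b in config.marginal_effects),
        interaction_pairs=tuple(
            (config.snp_id(i), config.snp_id(j), b, k) for i, j, b, k in config.interaction_effects
        ),
        er_snps=tuple((config.snp_id(i), b) for i, b in config.er_effects),
        config=config,
    )


# ---------------------------------------------------------------------------
# genotypes


def cohort_frequencies(config: SimulationConfig) -> np.ndarray:
    """Per-cohort post-divergence allele frequencies, shape (n_cohorts, n_snps).

    Reproduces exactly the frequency draws :func:`simulate_genotypes` uses
    (a dedicated seeded stream), so callers can compare empirical to
    generating frequencies.
    """
    rng = np.random.default_rng([config.seed, 0])
    p = rng.uniform(config.maf_range[0], config.maf_range[1], config.n_snps)
    if config.fst == 0.0:
        return np.tile(p, (config.n_cohorts, 1))
    a = p * (1.0 - config.fst) / config.fst
    b = (1.0 - p) * (1.0 - config.fst) / config.fst
    freqs = rng.beta(a, b, size=(config.n_cohorts, config.n_snps))
    lo, hi = _FREQ_CLAMP
    if (freqs < lo).any() or (freqs > hi).any():
        warnings.warn("degenerate cohort allele frequencies clamped away from 0/1")
        freqs = np.clip(freqs, lo, hi)
    return freqs


def effective_frequencies(config: SimulationConfig) -> np.ndarray:
    """Marginal allele frequencies induced by the LD copying chain.

    Copying from the left neighbour mixes frequencies:
    ``f_s = ld * f_{s-1} + (1 - ld) * p_s`` with ``f_0 = p_0``.  With
    ``ld_decay = 0`` this is just the cohort frequency.
    """
    freqs = cohort_frequencies(config)
    eff = freqs.copy()
    for s in range(1, config.n_snps):
        eff[:, s] = config.ld_decay * eff[:, s - 1] + (1.0 - config.ld_decay) * freqs[:, s]
    return eff


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw the dosage matrix for all cohorts (stacked by cohort)."""
    freqs = cohort_frequencies(config)
    rng = np.random.default_rng([config.seed, 1])
    n, S = config.n_samples, config.n_snps
    blocks: list[np.ndarray] = []
    sample_ids: list[str] = []
    for c, name in enumerate(config.cohort_names):
        dosage = np.zeros((n, S), dtype=np.int8)
        for _hap in range(2):
            fresh = rng.random((n, S)) < freqs[c]
            if config.ld_decay > 0.0:
                copy = rng.random((n, S)) < config.ld_decay
                allele = fresh.copy()
                for s in range(1, S):
                    allele[:, s] = np.where(copy[:, s], allele[:, s - 1], fresh[:, s])
            else:
                allele = fresh
            dosage += allele.astype(np.int8)
        blocks.append(dosage)
        sample_ids.extend(f"{name}_{i:04d}" for i in range(n))
    snp_ids = tuple(config.snp_id(s) for s in range(S))
    return GenotypeMatrix(tuple(sample_ids), snp_ids, np.vstack(blocks))


# ---------------------------------------------------------------------------
# phenotypes


def _liability_terms(matrix: GenotypeMatrix, config: SimulationConfig) -> np.ndarray:
    g = matrix.dosage.astype(np.float64)
    eta = np.zeros(matrix.n_samples)
    for idx, beta in config.marginal_effects:
        eta += beta * g[:, idx]
    for i, j, beta, kind in config.interaction_effects:
        if kind == _PRODUCT:
            eta += beta * g[:, i] * g[:, j]
        else:  # xor on carrier status: no marginal per-SNP signal
            eta += beta * ((g[:, i] > 0) != (g[:, j] > 0)).astype(float)
    return eta


def _cohort_from_id(sample_id: str) -> str:
    return sample_id.split("_", 1)[0]


def simulate_case_control(matrix: GenotypeMatrix, config: SimulationConfig) -> PhenotypeTable:
    """Draw case/control labels from the logistic liability model."""
    eta = _liability_terms(matrix, config)
    intercept = config.intercept if config.intercept is not None else -float(np.mean(eta))
    prob = expit(intercept + eta)
    rng = np.random.default_rng([config.seed, 2])
    status = (rng.random(matrix.n_samples) < prob).astype(int)
    return PhenotypeTable(
        pd.DataFrame(
            {
                "sample_id": list(matrix.sample_ids),
                "status": status,
                "er_status": "unknown",
                "cohort": [_cohort_from_id(s) for s in matrix.sample_ids],
            }
        )
    )


def simulate_er_status(
    matrix: GenotypeMatrix, phenotypes: PhenotypeTable, config: SimulationConfig
) -> PhenotypeTable:
    """Assign ER± labels to cases from a logistic model; controls stay unknown."""
    pheno = phenotypes.for_samples(matrix.sample_ids)
    case_mask = pheno.status == 1
    if not case_mask.any():
        raise ValueError("no cases present; cannot assign ER status")
    g = matrix.dosage.astype(np.float64)
    eta = np.zeros(matrix.n_samples)
    for idx, beta in config.er_effects:
        eta += beta * g[:, idx]
    prob = expit(eta)
    rng = np.random.default_rng([config.seed, 3])
    draw = rng.random(matrix.n_samples) < prob
    er = np.where(case_mask, np.where(draw, "positive", "negative"), "unknown")
    df = pheno.frame.copy()
    df["er_status"] = er
    return PhenotypeTable(df)


def simulate_dataset(config: SimulationConfig) -> tuple[GenotypeMatrix, PhenotypeTable, TruthSet]:
    """Genotypes, phenotypes (with ER labels if configured) and ground truth."""
    matrix = simulate_genotypes(config)
    pheno = simulate_case_control(matrix, config)
    if config.er_effects or (pheno.status == 1).any():
        pheno = simulate_er_status(matrix, pheno, config)
    return matrix, pheno, truth_set(config)


def make_toy_fixture(seed: int = 0, **overrides) -> tuple[GenotypeMatrix, PhenotypeTable, TruthSet]:
    """Small deterministic dataset used throughout tests and docs.

    Two cohorts of 200 samples (400 total), 300 common-variant SNPs with
    mild LD and a small cohort divergence, two marginal risk SNPs and one
    XOR-type interacting pair (epistatic signal with only the partial
    linear leakage that off-half carrier frequencies induce).
    """
    config = SimulationConfig(
        n_samples=200,
        n_snps=300,
        n_cohorts=2,
        maf_range=(0.35, 0.5),
        ld_decay=0.1,
        fst=0.02,
        marginal_effects=((10, 0.8), (120, 0.8)),
        interaction_effects=((200, 250, 2.0, _XOR),),
        er_effects=((10, 1.5), (200, -1.5)),
        seed=seed,
    )
    config = replace(config, **overrides)
    return simulate_dataset(config)
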