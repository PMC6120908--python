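"""Desk-scale presets: the study conditions used by the shipped
examples, tests and the results-reproduction script.

The method was developed on cohorts of ~700-900 individuals over 125k
SNPs; the presets here scale every experiment down to a few hundred
samples and a few hundred SNPs so a full repeated-CV study runs on one
CPU in minutes.  Problem sizes, generator settings and grids are fixed
here once so every entry point exercises identical conditions.

Boosting settings differ from the library-wide defaults (depth 2,
learning rate 0.01, many trees — the optima reported for the full-size
cohorts) because a 300-SNP, 400-sample fixture supports fewer, deeper
trees with column sampling: depth 3 exposes three-way split chains that
surface interacting pairs, and colsample 0.3 forces exploration across
SNPs so epistatic SNPs without marginal signal still enter trees.
"""

from __future__ import annotations

from .boosting import BoostingParams
from .evaluation import CvScheme, MethodSpec, SvmParams
from .search import SearchConfig
from .simulate import SimulationConfig

#: Module-1 ranking ensemble for ~300-SNP fixtures.
RANKING_PARAMS = BoostingParams(
    n_trees=300, tree_depth=3, learning_rate=0.05, subsample=0.6, colsample=0.3, seed=0
)

#: Window re-ranking ensemble used inside the adaptive search.  Full
#: column view (colsample 1.0) keeps window gain estimates stable; the
#: window itself is already a narrow SNP subset.
RERANK_PARAMS = BoostingParams(
    n_trees=150, tree_depth=3, learning_rate=0.1, subsample=0.7, colsample=1.0, seed=0
)

#: Search grid for desk-scale selection runs.  Group sizes 50/100 of
#: ~300 candidates match the selected-group fractions the method reports
#: at full scale (hundreds of SNPs from thousands of candidates).
SEARCH_SMALL = SearchConfig(window_sizes=(8, 30), window_increments=(5,), k_grid=(50, 100))

#: Small stratified scheme: one repetition of the 5-fold outer protocol.
SCHEME_SMALL = CvScheme(n_repetitions=1, n_outer_folds=5, n_inner_folds=5, seed=0)


def proposed_spec(seed: int = 0, search: SearchConfig = SEARCH_SMALL) -> MethodSpec:
    """Full method (ranking + adaptive search + SVM) at desk scale."""
    return MethodSpec(
        name="proposed",
        boosting=BoostingParams(**{**RANKING_PARAMS.__dict__, "seed": seed}),
        rerank=BoostingParams(**{**RERANK_PARAMS.__dict__, "seed": seed}),
        search=search,
        svm=SvmParams(),
    )


def ablation_spec(seed: int = 0) -> MethodSpec:
    """Ranking without the adaptive search: every candidate SNP is used."""
    return MethodSpec(
        name="proposed_no_search",
        boosting=BoostingParams(**{**RANKING_PARAMS.__dict__, "seed": seed}),
        svm=SvmParams(),
    )


def epistasis_config(seed: int = 0) -> SimulationConfig:
    """Pure-epistasis study: no marginal effects, two XOR pairs.

    The regime where an additive PRS has nothing to work with and
    interaction-aware selection should win.
    """
    return SimulationConfig(
        n_samples=200,
        n_snps=250,
        n_cohorts=2,
        maf_range=(0.35, 0.5),
        ld_decay=0.0,
        fst=0.01,
        marginal_effects=(),
        interaction_effects=((20, 70, 2.0, "xor"), (150, 210, 2.0, "xor")),
        seed=seed,
    )


def null_config(seed: int = 0) -> SimulationConfig:
    """All-noise study: no causal SNPs at all."""
    return SimulationConfig(
        n_samples=300,
        n_snps=100,
        n_cohorts=2,
        maf_range=(0.2, 0.5),
        ld_decay=0.0,
        fst=0.01,
        seed=seed,
    )
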