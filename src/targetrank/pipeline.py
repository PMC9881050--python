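"""End-to-end convenience pipeline.

Ties the stages together the way a genome-wide study runs them:
generate or load the inputs, assemble the feature matrix, build the
gold standard, rank features by mRMR, fit the incremental
likelihood-ratio models and cross-validate them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bayes import LikelihoodRatioNB
from .datasets import GoldStandard, build_gold_standard
from .evaluation import ReplicateSummary, cross_validate
from .profiles import FeatureMatrix
from .selection import FeatureRanking, mrmr_rank


@dataclass
class PipelineResult:
    matrix: FeatureMatrix
    gold: GoldStandard
    ranking: FeatureRanking
    model: LikelihoodRatioNB
    cv: ReplicateSummary

    @property
    def selected_features(self) -> list[str]:
        return list(self.model.features_)


def run_pipeline(
    genome,
    n_features: int = 6,
    n_replicates: int = 100,
    negative_size: int = 100,
    folds: int = 10,
    seed: int = 0,
    n_bins: int = 5,
    alpha: float = 0.5,
    matrix: FeatureMatrix | None = None,
) -> PipelineResult:
    """Features -> gold standard -> mRMR -> model -> cross-validated AUC.

    ``genome`` is a :class:`~targetrank.simulate.SyntheticGenome` (or
    any object with ``protein_ids``, ``positives`` and a
    ``feature_matrix()`` method).  The final model integrates the top
    ``n_features`` mRMR-ranked features and is fitted on the positives
    plus the first negative replicate; its quoted performance is the
    replicate-averaged cross-validation AUC.
    """
    if matrix is None:
        matrix = genome.feature_matrix()
    gold = build_gold_standard(
        genome.positives,
        genome.protein_ids,
        size=negative_size,
        n_replicates=n_replicates,
        seed=seed,
    )
    ranking = mrmr_rank(matrix, gold)
    features = ranking.features[:n_features]
    cv = cross_validate(
        matrix, gold, features, folds=folds, seed=seed, n_bins=n_bins, alpha=alpha
    )
    labeled = sorted(gold.positives) + sorted(gold.replicate_negatives(0))
    y = np.array(
        [1.0] * len(gold.positives) + [0.0] * len(gold.replicate_negatives(0))
    )
    model = LikelihoodRatioNB(
        features=features, n_bins=n_bins, alpha=alpha, kinds=matrix.kinds
    )
    model.fit(matrix.data.loc[labeled], y)
    return PipelineResult(matrix, gold, ranking, model, cv)
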