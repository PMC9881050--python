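"""Model evaluation and group-comparison statistics.

ROC/AUC, 10-fold cross-validation repeated over the negative replicate
sets, the independent-test scheme (every trained replicate model
against every test negative replicate), and the per-feature
target-vs-nontarget comparisons (one-sided rank-sum or Fisher tests
with Benjamini-Hochberg adjustment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .bayes import LikelihoodRatioNB
from .errors import (
    DegenerateLabelsError,
    InsufficientDataError,
    LeakageError,
)


@dataclass
class RocResult:
    """ROC curve points and the area under it."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC of a score vector against 0/1 labels.

    The AUC equals the Mann-Whitney statistic: the fraction of
    positive-negative pairs ranked correctly, with ties credited 0.5.
    """
    from sklearn.metrics import roc_curve

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if not ((y == 1).any() and (y == 0).any()):
        raise DegenerateLabelsError("need both classes for a ROC curve")
    fpr, tpr, _ = roc_curve(y, s)
    # rank-based AUC (exact tie handling)
    ranks = stats.rankdata(s)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return RocResult(fpr, tpr, float(auc))


@dataclass
class ReplicateSummary:
    """Per-replicate AUCs with their mean and standard deviation."""

    aucs: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd(self) -> float:
        return float(np.std(self.aucs, ddof=1)) if len(self.aucs) > 1 else 0.0

    def __repr__(self) -> str:
        return f"ReplicateSummary(mean={self.mean:.4f}, sd={self.sd:.4f}, n={len(self.aucs)})"


def cross_validate(
    matrix,
    gold,
    features,
    folds: int = 10,
    seed: int = 0,
    n_bins: int = 5,
    alpha: float = 0.5,
) -> ReplicateSummary:
    """Stratified k-fold cross-validation repeated per negative replicate.

    For each negative replicate the positives and that replicate's
    negatives are split into stratified folds; the model is refitted on
    each training fold (bins and LR tables alike, so no fold leaks into
    fitting) and the pooled held-out scores give one AUC.  The summary
    aggregates one AUC per replicate.
    """
    features = list(features.features) if hasattr(features, "features") else list(features)
    n_pos = len(gold.positives)
    loo = all(
        folds == n_pos + len(neg) for _, neg in gold.negative_replicates
    )  # folds = n: leave-one-out (cannot be stratified)
    if not loo and (
        n_pos < folds or any(len(neg) < folds for _, neg in gold.negative_replicates)
    ):
        raise InsufficientDataError(
            f"need >= {folds} positives and negatives per replicate"
        )
    rng = np.random.SeedSequence(seed)
    fold_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in rng.spawn(gold.n_replicates)]
    aucs = []
    pos_sorted = sorted(gold.positives)
    for (rep_i, (_, negatives)), fseed in zip(
        enumerate(gold.negative_replicates), fold_seeds
    ):
        labeled = pos_sorted + sorted(negatives)
        y = np.array([1.0] * n_pos + [0.0] * len(negatives))
        X = matrix.data.loc[labeled]
        if loo:
            splits = [
                (np.delete(np.arange(len(y)), i), np.array([i]))
                for i in range(len(y))
            ]
        else:
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fseed)
            splits = list(skf.split(X, y))
        held_scores = np.empty(len(y))
        for train_idx, test_idx in splits:
            model = LikelihoodRatioNB(
                features=features, n_bins=n_bins, alpha=alpha, kinds=matrix.kinds
            )
            model.fit(X.iloc[train_idx], y[train_idx])
            held_scores[test_idx] = model.decision_function(X.iloc[test_idx])
        aucs.append(roc_auc(held_scores, y).auc)
    return ReplicateSummary(np.array(aucs))


def independent_test(
    matrix,
    gold,
    features,
    test_positives,
    test_negative_replicates,
    n_bins: int = 5,
    alpha: float = 0.5,
) -> ReplicateSummary:
    """Independent-test evaluation over the replicate grid.

    One model is trained per gold-standard negative replicate (on the
    full positives plus that replicate) and each is scored against
    every independent-test negative replicate, giving
    n_gold x n_test AUCs.  Raises :class:`LeakageError` if the test
    positives overlap the training positives.
    """
    features = list(features.features) if hasattr(features, "features") else list(features)
    test_pos = sorted(set(test_positives))
    if set(test_pos) & set(gold.positives):
        raise LeakageError("independent test positives overlap the training positives")
    pos_sorted = sorted(gold.positives)
    aucs = []
    for _, negatives in gold.negative_replicates:
        labeled = pos_sorted + sorted(negatives)
        y = np.array([1.0] * len(pos_sorted) + [0.0] * len(negatives))
        model = LikelihoodRatioNB(
            features=features, n_bins=n_bins, alpha=alpha, kinds=matrix.kinds
        )
        model.fit(matrix.data.loc[labeled], y)
        for test_negs in test_negative_replicates:
            negs = sorted(test_negs[1] if isinstance(test_negs, tuple) else test_negs)
            ids = test_pos + negs
            yt = np.array([1.0] * len(test_pos) + [0.0] * len(negs))
            scores = model.decision_function(matrix.data.loc[ids])
            aucs.append(roc_auc(scores, yt).auc)
    return ReplicateSummary(np.array(aucs))


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted P values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ComparisonReport:
    """Per-feature positives-vs-negatives comparison table."""

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def compare_features(matrix, positives, negatives) -> ComparisonReport:
    """Feature-by-feature comparison of target vs non-target proteins.

    Continuous features get a one-sided Wilcoxon rank-sum test (with
    group means and mean ranks), binary features a one-sided Fisher
    exact test (with per-group fractions); the test's direction is the
    enrichment/depletion observed in the data, and P values are
    Benjamini-Hochberg adjusted across all tested features.  Features
    constant across both groups are skipped.
    """
    pos_ids = sorted(set(positives))
    neg_ids = sorted(set(negatives))
    rows = []
    for name in matrix.feature_names:
        kind = matrix.kinds[name]
        a = matrix.data[name].reindex(pos_ids).dropna().to_numpy(dtype=float)
        b = matrix.data[name].reindex(neg_ids).dropna().to_numpy(dtype=float)
        if a.size == 0 or b.size == 0:
            continue
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            continue  # constant: no test possible
        if kind == "binary":
            tbl = [
                [int(a.sum()), int(a.size - a.sum())],
                [int(b.sum()), int(b.size - b.sum())],
            ]
            direction = "greater" if a.mean() >= b.mean() else "less"
            p = stats.fisher_exact(tbl, alternative=direction)[1]
            rows.append(
                {
                    "feature": name,
                    "test": "fisher",
                    "direction": direction,
                    "positive_summary": 100.0 * a.mean(),
                    "negative_summary": 100.0 * b.mean(),
                    "p_value": float(p),
                }
            )
        else:
            ranks = stats.rankdata(pooled)
            direction = (
                "greater"
                if ranks[: a.size].mean() >= ranks[a.size :].mean()
                else "less"
            )
            p = stats.mannwhitneyu(a, b, alternative=direction)[1]
            rows.append(
                {
                    "feature": name,
                    "test": "rank_sum",
                    "direction": direction,
                    "positive_summary": float(a.mean()),
                    "negative_summary": float(b.mean()),
                    "positive_mean_rank": float(ranks[: a.size].mean()),
                    "negative_mean_rank": float(ranks[a.size :].mean()),
                    "p_value": float(p),
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["adjusted_p"] = benjamini_hochberg(table["p_value"])
    return ComparisonReport(table)
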