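"""Mutual information and mRMR feature ranking.

Continuous features are discretized into three states at mean +/- one
standard deviation (computed on the labeled training proteins only);
mutual information is the plug-in estimate on the empirical joint
distribution, in bits.  The mRMR ranking is the maximum-relevance /
minimum-redundancy quotient scheme: the first feature maximizes
relevance to the class label, and each subsequent pick maximizes

    I(f_j, c) / mean over selected f_i of I(f_j, f_i).

With a gold standard of repeatedly sampled negative sets, every MI term
is the mean over the negative replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import (
    ConstantFeatureError,
    MissingLabelsError,
    ShapeError,
)


def discretize(
    values, mean: float | None = None, std: float | None = None
) -> np.ndarray:
    """Map a continuous vector to 3 states: below mean - sd, within one
    sd of the mean, above mean + sd.

    ``mean``/``std`` default to statistics of the supplied values; pass
    training-set statistics to discretize held-out data consistently.
    NaNs propagate (returned as NaN).
    """
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size < 2 or np.all(finite == finite[0]):
        raise ConstantFeatureError("cannot discretize a (near-)constant vector")
    m = float(np.mean(finite)) if mean is None else mean
    s = float(np.std(finite)) if std is None else std
    out = np.full(v.shape, np.nan)
    ok = np.isfinite(v)
    out[ok & (v < m - s)] = 0.0
    out[ok & (v >= m - s) & (v <= m + s)] = 1.0
    out[ok & (v > m + s)] = 2.0
    return out


def mutual_information(x, y) -> float:
    """Plug-in mutual information between two categorical vectors, in bits.

    Pairs with a missing entry (NaN) on either side are dropped;
    0*log 0 terms contribute 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ShapeError(f"length mismatch: {x.shape} vs {y.shape}")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size == 0:
        raise ShapeError("no complete observations")
    xi = np.unique(x, return_inverse=True)[1]
    yi = np.unique(y, return_inverse=True)[1]
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])))


def entropy(x) -> float:
    """Shannon entropy of a categorical vector, in bits (= MI(x, x))."""
    return mutual_information(x, x)


@dataclass
class FeatureRanking:
    """mRMR output: feature order with per-step relevance and redundancy."""

    table: pd.DataFrame  # rank, feature, relevance, redundancy

    @property
    def features(self) -> list[str]:
        return list(self.table["feature"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _discretized_labeled_matrix(matrix, labeled_ids, kinds):
    """Discretize each feature on the labeled subset; returns a DataFrame
    of categorical codes (NaN = missing).  A feature constant on the
    subset is kept as-is: it carries zero mutual information with
    anything, which the plug-in estimate reproduces exactly."""
    sub = matrix.data.loc[labeled_ids]
    cols = {}
    for name in matrix.data.columns:
        col = sub[name].to_numpy(dtype=float)
        if kinds[name] == "binary":
            cols[name] = col
        else:
            try:
                cols[name] = discretize(col)
            except ConstantFeatureError:
                cols[name] = col
    return pd.DataFrame(cols, index=sub.index)


def mrmr_rank(matrix, gold) -> FeatureRanking:
    """Rank all features of a FeatureMatrix by mRMR against a GoldStandard.

    Relevance I(f, c) and redundancy I(f_i, f_j) are averaged over the
    gold standard's negative replicates (each replicate labels the
    positives 1 and its own negatives 0).  Ties break lexicographically
    by feature name.
    """
    if not gold.negative_replicates:
        raise MissingLabelsError("gold standard has no negative replicates")
    names = None
    rel_sum = None
    red_sum = None
    n_rep = gold.n_replicates
    for _, negatives in gold.negative_replicates:
        labeled = sorted(gold.positives) + sorted(negatives)
        y = np.array([1.0] * len(gold.positives) + [0.0] * len(negatives))
        disc = _discretized_labeled_matrix(matrix, labeled, matrix.kinds)
        if names is None:
            names = list(disc.columns)
            k = len(names)
            rel_sum = np.zeros(k)
            red_sum = np.zeros((k, k))
        arr = disc.to_numpy()
        for i, name in enumerate(names):
            rel_sum[i] += mutual_information(arr[:, i], y)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                mi = mutual_information(arr[:, i], arr[:, j])
                red_sum[i, j] += mi
                red_sum[j, i] += mi
    relevance = rel_sum / n_rep
    redundancy = red_sum / n_rep
    order = greedy_mrmr_order(names, relevance, redundancy)

    rows = []
    selected: list[int] = []
    idx = {n: i for i, n in enumerate(names)}
    for rank, name in enumerate(order, start=1):
        i = idx[name]
        mean_red = (
            float(np.mean([redundancy[i, j] for j in selected])) if selected else 0.0
        )
        rows.append(
            {
                "rank": rank,
                "feature": name,
                "relevance": float(relevance[i]),
                "redundancy": mean_red,
            }
        )
        selected.append(i)
    return FeatureRanking(pd.DataFrame(rows))


def greedy_mrmr_order(
    names: list[str], relevance: np.ndarray, redundancy: np.ndarray
) -> list[str]:
    """Greedy mRMR quotient selection given precomputed MI tables.

    Step 1 takes the most relevant feature (the quotient's denominator
    is undefined for an empty selected set).  Later steps maximize
    relevance / mean redundancy with two limit conventions: zero mean
    redundancy with positive relevance gives a +inf quotient (such
    candidates rank first, ordered by relevance); zero relevance gives
    a quotient of 0 even when the redundancy is also 0 (a feature
    carrying no class information never maximizes the quotient).  All
    remaining ties break by feature name.
    """
    remaining = list(range(len(names)))
    # step 1: pure relevance, ties by name
    first = min(remaining, key=lambda i: (-relevance[i], names[i]))
    order = [first]
    remaining.remove(first)
    while remaining:
        def key(j):
            mean_red = np.mean([redundancy[j, i] for i in order])
            if relevance[j] == 0.0:
                return (2, 0.0, names[j])
            if mean_red == 0.0:
                # +inf quotient: rank ahead of all finite quotients,
                # between zero-redundancy candidates prefer relevance
                return (0, -relevance[j], names[j])
            return (1, -relevance[j] / mean_red, names[j])

        best = min(remaining, key=key)
        order.append(best)
        remaining.remove(best)
    return [names[i] for i in order]


class MRMRRanker(BaseEstimator):
    """scikit-learn style transformer exposing the mRMR ranking.

    Operates on a plain (X, y) design: fit computes the ranking on one
    labeled sample (binary features passed through, continuous features
    discretized at mean +/- sd); transform keeps the top ``k`` ranked
    columns.  For the replicate-averaged ranking over a GoldStandard
    use :func:`mrmr_rank`.

    Parameters
    ----------
    k : int or None
        Number of top features transform retains (None = all).

    Attributes
    ----------
    ranking_ : list of str
        Features in selection order.
    relevance_ : dict
        Mean MI of each feature with the label.
    """

    def __init__(self, k: int | None = None):
        self.k = k

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if len(np.unique(y[np.isfinite(y)])) < 2:
            raise MissingLabelsError("need both classes in y")
        from .profiles import FeatureMatrix

        matrix = FeatureMatrix(X.copy())
        disc = _discretized_labeled_matrix(matrix, list(X.index), matrix.kinds)
        names = list(disc.columns)
        arr = disc.to_numpy()
        relevance = np.array([mutual_information(arr[:, i], y) for i in range(len(names))])
        redundancy = np.zeros((len(names), len(names)))
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                redundancy[i, j] = redundancy[j, i] = mutual_information(
                    arr[:, i], arr[:, j]
                )
        self.ranking_ = greedy_mrmr_order(names, relevance, redundancy)
        self.relevance_ = dict(zip(names, relevance))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "ranking_")
        keep = self.ranking_ if self.k is None else self.ranking_[: self.k]
        return pd.DataFrame(X)[keep]
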