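"""Likelihood-ratio naive Bayes target scorer.

Each feature f gets a per-bin likelihood ratio

    LR(f) = P(f | target) / P(f | non-target)
          = (TP_f / T) / (FP_f / F)

estimated from the gold standard (T positives, F negatives, TP_f/FP_f
of them in the bin), optionally with a pseudocount alpha:
((TP_f + a)/(T + k*a)) / ((FP_f + a)/(F + k*a)) over k bins; alpha = 0
reproduces the raw ratio.  Under the naive independence assumption the
combined score of a protein is the product of its per-feature LRs,
which is proportional to its posterior odds of being a target and is
used directly as the prediction score.

Binary features use their two categories as bins; continuous features
are cut into equal-frequency bins on the pooled labeled training
values.  A missing feature value contributes a neutral LR of 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .errors import (
    MissingLabelsError,
    ModelStateError,
    RangeError,
    SchemaError,
)

#: Default confidence-grade cutoffs on the combined LR.
GRADE_CUTOFFS = {"high": 100.0, "median": 1.0}


def fit_lr_table(
    values,
    labels,
    kind: str = "continuous",
    n_bins: int = 5,
    alpha: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one feature's per-bin likelihood-ratio table.

    Parameters
    ----------
    values, labels
        Feature values and 0/1 labels of the gold-standard proteins;
        rows with NaN values are excluded from fitting.
    kind
        "binary" (bins = the two categories) or "continuous"
        (equal-frequency bins on the pooled labeled values).
    n_bins, alpha
        Bin count for continuous features and the smoothing
        pseudocount.

    Returns
    -------
    (edges, lrs)
        ``edges`` are the interior cut points (empty for binary
        features); ``lrs`` has one entry per bin.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    ok = np.isfinite(v)
    v, y = v[ok], y[ok]
    t_tot = int((y == 1).sum())
    f_tot = int((y == 0).sum())
    if t_tot == 0 or f_tot == 0:
        raise MissingLabelsError("need >= 1 positive and >= 1 negative with values")
    if kind == "binary":
        edges = np.array([])
        codes = (v > 0.5).astype(int)
        k = 2
    else:
        qs = np.quantile(v, np.linspace(0, 1, n_bins + 1)[1:-1])
        edges = np.unique(qs)
        codes = np.searchsorted(edges, v, side="right")
        k = len(edges) + 1
    tp = np.bincount(codes[y == 1], minlength=k).astype(float)
    fp = np.bincount(codes[y == 0], minlength=k).astype(float)
    num = (tp + alpha) / (t_tot + k * alpha)
    den = (fp + alpha) / (f_tot + k * alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        lrs = num / den
    if alpha == 0:
        # raw ratio: empty-negative bins give inf, empty-both bins 1
        lrs[(tp == 0) & (fp == 0)] = 1.0
    return edges, lrs


def _bin_code(value: float, edges: np.ndarray, kind: str) -> int:
    if kind == "binary":
        return int(value > 0.5)
    return int(np.searchsorted(edges, value, side="right"))


def combined_lr(
    feature_values: Mapping[str, float], model: "LikelihoodRatioNB"
) -> float:
    """Product of the matched per-bin LRs over the model's features.

    Missing values (absent keys or NaN) contribute a neutral factor of
    1.  Accumulated in log space, returned in linear space.
    """
    check_model(model)
    log_sum = 0.0
    for name in model.features_:
        val = feature_values.get(name, np.nan)
        if val is None or not np.isfinite(val):
            continue
        code = _bin_code(val, model.bin_edges_[name], model.kinds_[name])
        log_sum += np.log(model.lr_tables_[name][code])
    return float(np.exp(log_sum))


def check_model(model: "LikelihoodRatioNB") -> None:
    if not hasattr(model, "lr_tables_"):
        raise ModelStateError("model is not fitted")


class LikelihoodRatioNB(BaseEstimator, ClassifierMixin):
    """Likelihood-ratio naive Bayes classifier over a protein feature table.

    scikit-learn compatible: ``fit(X, y)`` with X a DataFrame (or
    array) of feature values and y 0/1 labels; ``decision_function``
    returns log combined LR; ``predict`` thresholds the combined LR at
    1 (posterior odds above prior odds).

    Parameters
    ----------
    features : sequence of str, optional
        Feature subset (and order) to use; default all columns of X.
    n_bins : int
        Equal-frequency bin count for continuous features.
    alpha : float
        Smoothing pseudocount; 0 gives the raw frequency ratio.
    kinds : mapping, optional
        Per-feature "binary"/"continuous"; inferred from the observed
        values when omitted.

    Attributes
    ----------
    features_ : list of str
        Features actually used, in order.
    bin_edges_ : dict of str -> ndarray
        Interior bin edges per continuous feature.
    lr_tables_ : dict of str -> ndarray
        Per-bin likelihood ratios.
    """

    def __init__(
        self,
        features: Sequence[str] | None = None,
        n_bins: int = 5,
        alpha: float = 0.5,
        kinds: Mapping[str, str] | None = None,
    ):
        self.features = features
        self.n_bins = n_bins
        self.alpha = alpha
        self.kinds = kinds

    def fit(self, X, y):
        from .profiles import infer_kind

        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise SchemaError("X and y row counts differ")
        names = list(self.features) if self.features is not None else list(X.columns)
        missing = [n for n in names if n not in X.columns]
        if missing:
            raise SchemaError(f"features absent from X: {missing}")
        if not ((y == 1).any() and (y == 0).any()):
            raise MissingLabelsError("need both classes to fit")
        self.features_ = names
        self.kinds_ = {}
        self.bin_edges_ = {}
        self.lr_tables_ = {}
        for name in names:
            kind = (
                self.kinds[name]
                if self.kinds is not None and name in self.kinds
                else infer_kind(X[name])
            )
            edges, lrs = fit_lr_table(
                X[name], y, kind=kind, n_bins=self.n_bins, alpha=self.alpha
            )
            self.kinds_[name] = kind
            self.bin_edges_[name] = edges
            self.lr_tables_[name] = lrs
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def combined_lr(self, X) -> np.ndarray:
        """Combined likelihood ratio of each row (linear scale)."""
        check_is_fitted(self, "lr_tables_")
        X = pd.DataFrame(X)
        missing = [n for n in self.features_ if n not in X.columns]
        if missing:
            raise SchemaError(f"features absent from X: {missing}")
        return np.exp(self.decision_function(X))

    def decision_function(self, X) -> np.ndarray:
        """Log combined likelihood ratio of each row."""
        check_is_fitted(self, "lr_tables_")
        X = pd.DataFrame(X)
        out = np.zeros(X.shape[0])
        for name in self.features_:
            if name not in X.columns:
                raise SchemaError(f"feature {name!r} absent from X")
            v = X[name].to_numpy(dtype=float)
            edges, kind = self.bin_edges_[name], self.kinds_[name]
            lrs = self.lr_tables_[name]
            ok = np.isfinite(v)
            codes = np.zeros(v.shape, dtype=int)
            if kind == "binary":
                codes[ok] = (v[ok] > 0.5).astype(int)
            else:
                codes[ok] = np.searchsorted(edges, v[ok], side="right")
            contrib = np.where(ok, np.log(lrs[codes]), 0.0)
            out += contrib
        return out

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0.0).astype(int)

    def per_feature_lr(self, feature_values: Mapping[str, float]) -> dict[str, float]:
        """The individual LR contribution of each model feature for one
        protein (1.0 where the value is missing)."""
        check_is_fitted(self, "lr_tables_")
        out = {}
        for name in self.features_:
            val = feature_values.get(name, np.nan)
            if val is None or not np.isfinite(val):
                out[name] = 1.0
            else:
                code = _bin_code(val, self.bin_edges_[name], self.kinds_[name])
                out[name] = float(self.lr_tables_[name][code])
        return out

    # -- serialization ------------------------------------------------

    def to_json(self, path=None) -> str:
        check_is_fitted(self, "lr_tables_")
        payload = {
            "features": self.features_,
            "kinds": self.kinds_,
            "bin_edges": {k: list(v) for k, v in self.bin_edges_.items()},
            "lr_tables": {k: list(v) for k, v in self.lr_tables_.items()},
            "n_bins": self.n_bins,
            "alpha": self.alpha,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "LikelihoodRatioNB":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        model = cls(
            features=payload["features"],
            n_bins=payload["n_bins"],
            alpha=payload["alpha"],
            kinds=payload["kinds"],
        )
        model.features_ = list(payload["features"])
        model.kinds_ = dict(payload["kinds"])
        model.bin_edges_ = {k: np.array(v) for k, v in payload["bin_edges"].items()}
        model.lr_tables_ = {k: np.array(v) for k, v in payload["lr_tables"].items()}
        model.classes_ = np.array([0, 1])
        return model


@dataclass
class PredictionResult:
    """Genome-wide scores: one row per protein with rank and grade."""

    table: pd.DataFrame  # protein_id (index), combined_lr, lr_<feature>..., rank, grade

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "protein_id"
        out.to_csv(path, sep="\t")


def assign_grade(score: float, cutoffs: Mapping[str, float] = GRADE_CUTOFFS) -> str:
    if score >= cutoffs["high"]:
        return "high"
    if score >= cutoffs["median"]:
        return "median"
    return "low"


def predict_genome(
    matrix,
    model: LikelihoodRatioNB,
    known_targets: Iterable = (),
    grade_cutoffs: Mapping[str, float] = GRADE_CUTOFFS,
) -> PredictionResult:
    """Score and rank every protein of a FeatureMatrix.

    Ranks are by decreasing combined LR with ties broken by protein id;
    grades come from the configurable score cutoffs; the known-target
    flag marks gold-standard positives.
    """
    check_is_fitted(model, "lr_tables_")
    X = matrix.data
    missing = [n for n in model.features_ if n not in X.columns]
    if missing:
        raise SchemaError(f"matrix lacks model features: {missing}")
    scores = model.combined_lr(X)
    table = pd.DataFrame(index=X.index)
    table["combined_lr"] = scores
    for name in model.features_:
        v = X[name].to_numpy(dtype=float)
        edges, kind = model.bin_edges_[name], model.kinds_[name]
        lrs = model.lr_tables_[name]
        ok = np.isfinite(v)
        codes = np.zeros(v.shape, dtype=int)
        if kind == "binary":
            codes[ok] = (v[ok] > 0.5).astype(int)
        else:
            codes[ok] = np.searchsorted(edges, v[ok], side="right")
        table[f"lr_{name}"] = np.where(ok, lrs[codes], 1.0)
    order = sorted(range(len(table)), key=lambda i: (-scores[i], str(X.index[i])))
    ranks = np.empty(len(table), dtype=int)
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    table["rank"] = ranks
    table["grade"] = [assign_grade(s, grade_cutoffs) for s in scores]
    known = set(known_targets)
    table["known_target"] = [pid in known for pid in X.index]
    return PredictionResult(table.sort_values("rank"))


def incremental_models(
    ranking,
    k_max: int,
    gold,
    matrix,
    replicate: int = 0,
    n_bins: int = 5,
    alpha: float = 0.5,
) -> list[LikelihoodRatioNB]:
    """Fit Model_1 ... Model_k_max along the mRMR feature order.

    Model_j uses the first j ranked features, refitted from scratch on
    the positives and the chosen negative replicate.  Pair each model
    with a cross-validated AUC via :func:`targetrank.evaluation.cross_validate`.
    """
    features = ranking.features if hasattr(ranking, "features") else list(ranking)
    if k_max > len(features):
        raise RangeError(f"k_max={k_max} exceeds {len(features)} ranked features")
    labeled = sorted(gold.positives) + sorted(gold.replicate_negatives(replicate))
    y = np.array([1.0] * len(gold.positives) + [0.0] * (len(labeled) - len(gold.positives)))
    X = matrix.data.loc[labeled]
    models = []
    for j in range(1, k_max + 1):
        m = LikelihoodRatioNB(
            features=features[:j], n_bins=n_bins, alpha=alpha, kinds=matrix.kinds
        )
        m.fit(X, y)
        models.append(m)
    return models
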