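"""Expression-, polymorphism- and annotation-derived features.

Covers the tissue specificity score (TSPS), the housekeeping flag, the
smoothed nonsynonymous/synonymous polymorphism ratio C_ratio, and the
assembly of the full per-protein feature matrix consumed by feature
selection and the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIdError,
    InvalidCountError,
    UndefinedScoreError,
)

#: Annotation columns carrying binary protein-class flags (0/1).
BINARY_FLAGS = (
    "signal_peptide",
    "transmembrane",
    "signaling_molecule",
    "transcription_factor",
    "housekeeping",
    "self_interacting",
    "enzyme",
    "gpcr",
    "ion_channel",
    "nhr",
    "kinase",
    "transporter",
)

#: Continuous/count annotation columns consumed as inputs.
ANNOTATION_NUMERIC = (
    "domain_count",
    "age",
    "evolutionary_rate",
    "n_nonsynonymous",
    "n_synonymous",
    "reaction_count",
    "pathway_count",
)


def tsps(values: Sequence[float]) -> float:
    """Tissue specificity score of one gene's expression profile.

    With f_i the fraction of the gene's total expression in tissue i and
    p = 1/n the uniform fraction, the score is sum_i f_i * log2(f_i / p)
    - the KL divergence (in bits) of the expression fractions from
    uniform.  Zero for a uniformly expressed gene; log2(n) when all
    expression sits in a single tissue.  Terms with f_i = 0 contribute 0.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise UndefinedScoreError("profile needs >= 2 tissues")
    if np.any(v < 0):
        raise InvalidCountError("expression levels must be >= 0")
    total = v.sum()
    if total == 0:
        raise UndefinedScoreError("all-zero expression profile")
    f = v / total
    p = 1.0 / v.size
    nz = f > 0
    return float(np.sum(f[nz] * np.log2(f[nz] / p)))


def housekeeping_flag(values: Sequence[float], detect_threshold: float = 0.0) -> bool:
    """True iff the gene is detected (value strictly above threshold) in
    every tissue."""
    v = np.asarray(values, dtype=float)
    return bool(np.all(v > detect_threshold))


def c_ratio(n_nonsynonymous: int, n_synonymous: int, epsilon: float = 0.01) -> float:
    """Smoothed ratio of nonsynonymous to synonymous SNP counts.

    (N_ns + eps) / (N_s + eps); the smoothing constant (default 0.01)
    keeps the ratio defined and tempers small-count noise.
    """
    if n_nonsynonymous < 0 or n_synonymous < 0:
        raise InvalidCountError("SNP counts must be non-negative")
    if epsilon <= 0:
        raise InvalidCountError("epsilon must be > 0")
    return (n_nonsynonymous + epsilon) / (n_synonymous + epsilon)


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Proteins x features table with per-feature kind tags.

    ``data`` holds one row per protein (index = protein id) and one
    column per feature; missing values are NaN, never silent zeros.
    ``kinds`` maps each feature to "binary" or "continuous".
    """

    data: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise DuplicateIdError(f"duplicate protein ids {dupes[:5]}")
        self.data.index.name = "protein_id"
        if not self.kinds:
            self.kinds = {c: infer_kind(self.data[c]) for c in self.data.columns}

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "protein_id"
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path, kinds: Mapping[str, str] | None = None) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="protein_id", na_values=["NA"])
        return cls(df, dict(kinds) if kinds else {})


def infer_kind(column: pd.Series) -> str:
    """A feature is binary iff its observed values are a subset of {0, 1}."""
    observed = set(column.dropna().unique())
    return "binary" if observed and observed <= {0, 1, 0.0, 1.0} else "continuous"


def read_expression_tsv(path) -> pd.DataFrame:
    """Gene x tissue expression matrix (rows genes, columns tissues)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_annotation_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="protein_id")


def assemble_feature_matrix(
    sequences,
    expression: pd.DataFrame | None = None,
    annotations: pd.DataFrame | None = None,
    networks: Mapping[str, "object"] | None = None,
    detect_threshold: float = 0.0,
) -> FeatureMatrix:
    """Combine every feature source into one proteins x features table.

    Parameters
    ----------
    sequences
        Iterable of :class:`~targetrank.sequence.ProteinSequence`; the
        row set of the result is exactly these proteins.
    expression
        Gene x tissue matrix; drives TSPS and the housekeeping flag.
    annotations
        Per-protein table with the binary class flags, domain/age/rate
        columns and SNP counts (see :data:`BINARY_FLAGS` and
        :data:`ANNOTATION_NUMERIC`).
    networks
        Mapping with optional keys "ppi", "signal" (undirected) and
        "tf" (directed); supplies degree, betweenness, self-interaction
        and TF in/out-degree features.

    Proteins absent from a source get NaN for the features that source
    provides (the classifier treats NaN as neutral evidence).
    """
    from . import networks as netmod
    from .sequence import sequence_feature_table

    seqs = list(sequences)
    table = sequence_feature_table(seqs)

    ids = table.index

    if expression is not None:
        tsps_col, hk_col = {}, {}
        for pid in ids:
            if pid in expression.index:
                profile = expression.loc[pid].to_numpy(dtype=float)
                if profile.sum() > 0:
                    tsps_col[pid] = tsps(profile)
                hk_col[pid] = float(
                    housekeeping_flag(profile, detect_threshold=detect_threshold)
                )
        table["tsps"] = pd.Series(tsps_col, dtype=float)
        table["housekeeping"] = pd.Series(hk_col, dtype=float)

    if annotations is not None:
        for col in BINARY_FLAGS:
            if col == "housekeeping" and "housekeeping" in table.columns:
                continue  # expression-derived flag wins
            if col in annotations.columns:
                table[col] = annotations[col].reindex(ids).astype(float)
        for col in ANNOTATION_NUMERIC:
            if col in annotations.columns:
                table[col] = annotations[col].reindex(ids).astype(float)
        if {"n_nonsynonymous", "n_synonymous"} <= set(table.columns):
            ns = table.pop("n_nonsynonymous")
            s = table.pop("n_synonymous")
            mask = ns.notna() & s.notna()
            table["c_ratio"] = np.nan
            table.loc[mask, "c_ratio"] = (ns[mask] + 0.01) / (s[mask] + 0.01)

    if networks:
        for name in ("ppi", "signal"):
            g = networks.get(name)
            if g is None:
                continue
            deg = netmod.degree_map(g)
            btw = netmod.betweenness_map(g)
            table[f"degree_{name}"] = pd.Series(
                {pid: deg[pid] for pid in ids if pid in deg}, dtype=float
            )
            table[f"betweenness_{name}"] = pd.Series(
                {pid: btw[pid] for pid in ids if pid in btw}, dtype=float
            )
            if name == "ppi":
                table["self_interacting"] = pd.Series(
                    {
                        pid: float(netmod.self_interacting(g, pid))
                        for pid in ids
                        if pid in deg
                    },
                    dtype=float,
                )
        tf = networks.get("tf")
        if tf is not None:
            table["indegree_tf"] = pd.Series(
                {pid: float(tf.in_degree(pid)) for pid in ids if pid in tf},
                dtype=float,
            )
            table["outdegree_tf"] = pd.Series(
                {pid: float(tf.out_degree(pid)) for pid in ids if pid in tf},
                dtype=float,
            )

    return FeatureMatrix(table)
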