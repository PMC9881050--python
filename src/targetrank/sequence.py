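"""Sequence-derived protein features.

Implements the physicochemical descriptors used as classifier inputs:
amino-acid class percentages, GRAVY (grand average of hydropathy),
net sequence charge, theoretical isoelectric point, counts of
"potential" PEST proteolytic motifs and the fraction of the chain in
long intrinsically disordered regions (FoldIndex).

Alphabet: the 20 standard residues plus the ambiguity codes B
(Asp/Asn), Z (Glu/Gln), X (any) and U (selenocysteine).  Ambiguity
handling for each descriptor is documented on the function; the common
rule is B -> D, Z -> E, U -> C and X neutral (zero hydropathy, zero
charge, non-ionizable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import EmptySequenceError, InvalidSequenceError

ALPHABET = set("ACDEFGHIKLMNPQRSTVWY" + "BZXU")

#: Kyte-Doolittle hydropathy values for the 20 standard residues.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Hydropathy after resolving ambiguity codes (B->D, Z->E, U->C, X->0).
_HYDROPATHY = dict(KYTE_DOOLITTLE, B=-3.5, Z=-3.5, U=2.5, X=0.0)

# Amino-acid classes.  The nine groups overlap, so the percentages of a
# sequence do not sum to 100.  B and Z are members of the classes that
# their resolved residues share (B in small/charged/acidic, Z in
# polar/charged/acidic).
AA_CLASSES = {
    "tiny": set("ACGST"),
    "small": set("ABCDGNPSTV"),
    "aliphatic": set("AILV"),
    "aromatic": set("FHWY"),
    "nonpolar": set("ACFGILMPVWY"),
    "polar": set("DEHKNQRSTZ"),
    "charged": set("BDEHKRZ"),
    "basic": set("HKR"),
    "acidic": set("BDEZ"),
}

AA_CLASS_NAMES = tuple(AA_CLASSES)

#: Residue charge convention of EMBOSS pepstats: K,R = +1; H = +0.5;
#: D,E = -1; B,Z = -0.5; all other letters 0; termini ignored.
RESIDUE_CHARGE = {
    "K": 1.0, "R": 1.0, "H": 0.5,
    "D": -1.0, "E": -1.0, "B": -0.5, "Z": -0.5,
}

#: pKa values (Bjellqvist set, as used by the ProtParam tool) for the
#: ionizable groups.  Positive groups gain a proton below their pKa,
#: negative groups lose one above it.  B, Z, X and U are non-ionizable.
PKA_POSITIVE = {"nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}


@dataclass(frozen=True)
class ProteinSequence:
    """An identified amino-acid sequence.

    The sequence is upper-cased on construction and every letter must
    belong to the accepted alphabet (20 standard residues plus B, Z, X,
    U); anything else raises :class:`InvalidSequenceError`.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - ALPHABET
        if bad:
            raise InvalidSequenceError(
                f"{self.id!r}: unknown residue letter(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _require_nonempty(p: ProteinSequence) -> None:
    if len(p.seq) == 0:
        raise EmptySequenceError(f"{p.id!r}: empty sequence")


def read_fasta(path) -> list[ProteinSequence]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    The record id is the first whitespace-delimited token of the header.
    """
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinSequence(rec.id, str(rec.seq)))
    return records


def write_fasta(path, proteins: Iterable[ProteinSequence], width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.seq), width):
                fh.write(p.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Composition and bulk physicochemical descriptors
# ---------------------------------------------------------------------------

def aa_class_percentages(p: ProteinSequence) -> dict[str, float]:
    """Percentage of residues in each of the nine amino-acid classes.

    Classes overlap (e.g. every tiny residue is also small), so the
    returned percentages do not sum to 100.
    """
    _require_nonempty(p)
    n = len(p.seq)
    out = {}
    for name, members in AA_CLASSES.items():
        out[name] = 100.0 * sum(1 for aa in p.seq if aa in members) / n
    return out


def gravy(p: ProteinSequence) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    _require_nonempty(p)
    return sum(_HYDROPATHY[aa] for aa in p.seq) / len(p.seq)


def sequence_charge(p: ProteinSequence) -> float:
    """Net sequence charge under the pepstats residue-charge convention.

    K,R contribute +1, H +0.5, D,E -1, B,Z -0.5; termini are ignored.
    Additive: charge(ab) = charge(a) + charge(b).
    """
    _require_nonempty(p)
    return sum(RESIDUE_CHARGE.get(aa, 0.0) for aa in p.seq)


# ---------------------------------------------------------------------------
# Theoretical isoelectric point
# ---------------------------------------------------------------------------

def charge_at_ph(p: ProteinSequence, ph: float) -> float:
    """Henderson-Hasselbalch net charge of the protein at a given pH.

    Counts the free termini plus the ionizable side chains (D, E, C, Y,
    H, K, R) with the Bjellqvist pKa set.
    """
    _require_nonempty(p)
    pos = 1.0 / (1.0 + 10.0 ** (ph - PKA_POSITIVE["nterm"]))
    neg = -1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE["cterm"] - ph))
    for aa, pka in PKA_POSITIVE.items():
        if aa == "nterm":
            continue
        pos += p.seq.count(aa) / (1.0 + 10.0 ** (ph - pka))
    for aa, pka in PKA_NEGATIVE.items():
        if aa == "cterm":
            continue
        neg -= p.seq.count(aa) / (1.0 + 10.0 ** (pka - ph))
    return pos + neg


def theoretical_pi(p: ProteinSequence, tol: float = 1e-3) -> float:
    """pH at which the modeled net charge is zero, found by bisection.

    The charge curve is strictly decreasing in pH, so bisection on
    [0, 14] converges; iteration stops once |charge| < ``tol``.
    """
    _require_nonempty(p)
    lo, hi = 0.0, 14.0
    ph = 7.0
    for _ in range(200):
        q = charge_at_ph(p, ph)
        if abs(q) < tol:
            break
        if q > 0:
            lo = ph
        else:
            hi = ph
        ph = 0.5 * (lo + hi)
    return ph


# ---------------------------------------------------------------------------
# PEST motifs
# ---------------------------------------------------------------------------

#: Average residue masses (Da) used for the PEST mass-percent term.
RESIDUE_MASS = {
    "G": 57.05, "A": 71.08, "S": 87.08, "P": 97.12, "V": 99.13,
    "T": 101.10, "C": 103.14, "L": 113.16, "I": 113.16, "N": 114.10,
    "D": 115.09, "Q": 128.13, "K": 128.17, "E": 129.12, "M": 131.19,
    "H": 137.14, "F": 147.18, "R": 156.19, "Y": 163.18, "W": 186.21,
    "B": 115.09, "Z": 129.12, "U": 103.14, "X": 110.0,
}

#: All PEST scoring constants in one place so the score can be
#: recalibrated against an external epestfind run if needed.
PEST_CONSTANTS = {
    "depst_weight": 0.55,       # weight of the DEPST mass-percent term
    "hydrophobicity_weight": 0.5,  # weight of the hydrophobicity index
    "kd_scale": 10.0,           # rescaled KD hydropathy = kd_scale*KD + kd_offset
    "kd_offset": 45.0,          # maps KD in [-4.5, 4.5] onto [0, 90]
}

_PEST_FLANKS = set("KRH")
_DEPST = set("DEPST")


@dataclass(frozen=True)
class PestMotif:
    """A candidate PEST region, 0-based half-open, with its score."""

    start: int
    end: int
    score: float
    category: str  # "potential" (score >= threshold) or "poor"


def _pest_score(region: str) -> float:
    masses = np.array([RESIDUE_MASS[aa] for aa in region])
    depst_mass_pct = 100.0 * masses[[aa in _DEPST for aa in region]].sum() / masses.sum()
    c = PEST_CONSTANTS
    rescaled_kd = [c["kd_scale"] * _HYDROPATHY[aa] + c["kd_offset"] for aa in region]
    hydro_index = float(np.mean(rescaled_kd))
    return c["depst_weight"] * depst_mass_pct - c["hydrophobicity_weight"] * hydro_index


def find_pest_motifs(
    p: ProteinSequence, min_window: int = 10, threshold: float = 5.0
) -> list[PestMotif]:
    """Locate and score PEST candidate regions.

    Candidates are the maximal stretches free of positively charged
    residues (K, R, H), bounded by such residues or by the sequence
    termini, of length >= ``min_window``, containing at least one P, one
    of D/E and one of S/T.  Each candidate gets the mass-percent /
    hydrophobicity score; a score >= ``threshold`` makes it "potential".
    Sequences shorter than ``min_window + 2`` (too short to hold a
    flanked window) yield no motifs.
    """
    seq = p.seq
    if len(seq) < min_window + 2:
        return []
    motifs = []
    start = 0
    bounds = [i for i, aa in enumerate(seq) if aa in _PEST_FLANKS] + [len(seq)]
    for b in bounds:
        region = seq[start:b]
        if (
            len(region) >= min_window
            and "P" in region
            and (set(region) & set("DE"))
            and (set(region) & set("ST"))
        ):
            score = _pest_score(region)
            category = "potential" if score >= threshold else "poor"
            motifs.append(PestMotif(start, b, score, category))
        start = b + 1
    return motifs


def pest_count(p: ProteinSequence, min_window: int = 10, threshold: float = 5.0) -> int:
    """Number of "potential" PEST motifs (score >= threshold)."""
    return sum(
        1
        for m in find_pest_motifs(p, min_window=min_window, threshold=threshold)
        if m.category == "potential"
    )


# ---------------------------------------------------------------------------
# Intrinsic disorder (FoldIndex)
# ---------------------------------------------------------------------------

#: Unit charges used inside the fold index (H neutral, as in the
#: original FoldIndex definition; B, Z resolved to D, E).
_FOLDINDEX_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0, "B": -1.0, "Z": -1.0}

FOLDINDEX_CONSTANTS = {"a": 2.785, "b": 1.151}


def fold_index(p: ProteinSequence, window: int = 51) -> np.ndarray:
    """Per-position fold index over a centered window (truncated at termini).

    index = 2.785 * <H> - |<R>| - 1.151, where <H> is the mean scaled
    hydropathy (KD + 4.5)/9 and <R> the mean unit residue charge within
    the window.  Negative values predict disorder.
    """
    _require_nonempty(p)
    n = len(p.seq)
    h = np.array([(_HYDROPATHY[aa] + 4.5) / 9.0 for aa in p.seq])
    q = np.array([_FOLDINDEX_CHARGE.get(aa, 0.0) for aa in p.seq])
    half = window // 2
    # prefix sums for O(n) windowed means with truncation at the ends
    ch = np.concatenate([[0.0], np.cumsum(h)])
    cq = np.concatenate([[0.0], np.cumsum(q)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    width = hi - lo
    mean_h = (ch[hi] - ch[lo]) / width
    mean_q = (cq[hi] - cq[lo]) / width
    c = FOLDINDEX_CONSTANTS
    return c["a"] * mean_h - np.abs(mean_q) - c["b"]


@dataclass(frozen=True)
class DisorderSegment:
    """A maximal run of negative fold index, 0-based half-open."""

    start: int
    end: int


def disorder_segments(
    p: ProteinSequence, window: int = 51, min_region: int = 30
) -> list[DisorderSegment]:
    """Maximal negative-index runs of length >= ``min_region``."""
    neg = fold_index(p, window=window) < 0
    segments = []
    start = None
    for i, flag in enumerate(list(neg) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_region:
                segments.append(DisorderSegment(start, i))
            start = None
    return segments


def disorder_score(p: ProteinSequence, window: int = 51, min_region: int = 30) -> float:
    """Fraction of the chain inside disordered regions of length >= 30.

    Short negative-index runs (< ``min_region``) are ignored to curb
    false positives, so the score of an ordered protein is exactly 0.
    """
    _require_nonempty(p)
    segs = disorder_segments(p, window=window, min_region=min_region)
    return sum(s.end - s.start for s in segs) / len(p.seq)


def sequence_feature_table(proteins: Iterable[ProteinSequence]):
    """All sequence features for a collection of proteins, as a DataFrame.

    Columns: the nine class percentages, gravy, theoretical_pi, charge,
    pest_count, disorder_score; index = protein id.
    """
    import pandas as pd

    rows = {}
    for p in proteins:
        if p.id in rows:
            from .errors import DuplicateIdError

            raise DuplicateIdError(f"duplicate protein id {p.id!r}")
        row = dict(aa_class_percentages(p))
        row["gravy"] = gravy(p)
        row["theoretical_pi"] = theoretical_pi(p)
        row["charge"] = sequence_charge(p)
        row["pest_count"] = pest_count(p)
        row["disorder_score"] = disorder_score(p)
        rows[p.id] = row
    return pd.DataFrame.from_dict(rows, orient="index")
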