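"""Gold-standard construction and drug-table analyses.

Builds the positive set (known therapeutic targets after homology
redundancy removal), the repeatedly sampled negative sets, the
time-split train/test partition, and the drug-innovation and
drug-disease-overlap summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    EmptySequenceError,
    InsufficientUniverseError,
    InvalidInputError,
)
from .sequence import ProteinSequence

# Alignment parameters for the redundancy screen: global
# Needleman-Wunsch with BLOSUM62 and gap open/extend 10/0.5.  Identity
# is matches divided by alignment length (gaps included).
ALIGN_PARAMS = {"matrix": "BLOSUM62", "open_gap": -10.0, "extend_gap": -0.5}


def _aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(ALIGN_PARAMS["matrix"])
    aligner.open_gap_score = ALIGN_PARAMS["open_gap"]
    aligner.extend_gap_score = ALIGN_PARAMS["extend_gap"]
    return aligner


def pairwise_identity(a: ProteinSequence, b: ProteinSequence) -> float:
    """Global-alignment sequence identity, percent of alignment length."""
    if not a.seq or not b.seq:
        raise EmptySequenceError("cannot align an empty sequence")
    # BLOSUM62 has no selenocysteine column; score U as its closest
    # standard residue C.
    s1 = a.seq.replace("U", "C")
    s2 = b.seq.replace("U", "C")
    alignment = _aligner().align(s1, s2)[0]
    t, q = str(alignment[0]), str(alignment[1])
    matches = sum(1 for x, y in zip(t, q) if x == y and x != "-")
    return 100.0 * matches / len(t)


def remove_redundancy(
    proteins: Mapping[str, ProteinSequence] | Iterable[ProteinSequence],
    threshold: float = 40.0,
) -> list[str]:
    """Greedy homology filter: keep a protein iff its identity to every
    already-kept protein is <= ``threshold`` percent.

    Proteins are visited in lexicographic id order, which makes the
    result deterministic and idempotent; no retained pair exceeds the
    threshold.
    """
    if not isinstance(proteins, Mapping):
        proteins = {p.id: p for p in proteins}
    kept: list[str] = []
    for pid in sorted(proteins):
        if all(pairwise_identity(proteins[pid], proteins[k]) <= threshold for k in kept):
            kept.append(pid)
    return kept


# ---------------------------------------------------------------------------
# Gold standard
# ---------------------------------------------------------------------------

@dataclass
class GoldStandard:
    """One positive set plus repeatedly sampled negative replicate sets.

    Each negative replicate is disjoint from the positives and from
    every excluded (known or possible target) protein, and is
    reproducible from its stored sub-seed.
    """

    positives: frozenset
    negative_replicates: list[tuple[int, frozenset]]
    universe: frozenset

    def __post_init__(self) -> None:
        for seed, neg in self.negative_replicates:
            if neg & self.positives:
                raise InvalidInputError(
                    f"negative replicate (seed {seed}) overlaps the positives"
                )

    @property
    def n_replicates(self) -> int:
        return len(self.negative_replicates)

    def replicate_negatives(self, r: int) -> frozenset:
        return self.negative_replicates[r][1]


def sample_negatives(
    universe: Iterable,
    exclusions: Iterable,
    size: int = 100,
    n_replicates: int = 100,
    seed: int = 0,
    sequences: Mapping[str, ProteinSequence] | None = None,
    identity_threshold: float = 40.0,
) -> list[tuple[int, frozenset]]:
    """Draw ``n_replicates`` uniform negative sets of ``size`` proteins.

    The eligible pool is the universe minus all exclusions (known plus
    possible targets); when ``sequences`` are supplied the pool is
    additionally reduced to a non-redundant subset with the same
    homology filter used for the positives.  Replicates differ only by
    sub-seeds derived from the master seed, so the whole list is
    reproducible.
    """
    pool = sorted(set(universe) - set(exclusions))
    if sequences is not None:
        pool_seqs = {pid: sequences[pid] for pid in pool}
        pool = remove_redundancy(pool_seqs, threshold=identity_threshold)
    if len(pool) < size:
        raise InsufficientUniverseError(
            f"only {len(pool)} eligible proteins for negative sets of size {size}"
        )
    master = np.random.SeedSequence(seed)
    replicates = []
    for child in master.spawn(n_replicates):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(sub_seed)
        chosen = rng.choice(len(pool), size=size, replace=False)
        replicates.append((sub_seed, frozenset(pool[i] for i in chosen)))
    return replicates


def build_gold_standard(
    positives: Iterable,
    universe: Iterable,
    exclusions: Iterable = (),
    size: int = 100,
    n_replicates: int = 100,
    seed: int = 0,
    sequences: Mapping[str, ProteinSequence] | None = None,
) -> GoldStandard:
    """Positives plus seeded negative replicates over the given universe.

    The positives themselves are always excluded from the negative pool,
    on top of any caller-supplied exclusions.
    """
    pos = frozenset(positives)
    negs = sample_negatives(
        universe,
        set(exclusions) | pos,
        size=size,
        n_replicates=n_replicates,
        seed=seed,
        sequences=sequences,
    )
    return GoldStandard(pos, negs, frozenset(universe))


# ---------------------------------------------------------------------------
# Drug tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugRecord:
    """An approved drug with its type, approval year and therapeutic targets."""

    drug_id: str
    drug_type: str  # "protein" | "peptide" | "small_molecule"
    approval_year: int | None
    targets: frozenset


def read_drug_table_tsv(path) -> list[DrugRecord]:
    """Drug-target TSV: drug_id, drug_type, approval_year (empty =
    unknown), comma-separated target ids."""
    records = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            drug_id, drug_type, year, targets = line.split("\t")
            records.append(
                DrugRecord(
                    drug_id,
                    drug_type,
                    int(year) if year else None,
                    frozenset(t for t in targets.split(",") if t),
                )
            )
    return records


def write_drug_table_tsv(path, drugs: Iterable[DrugRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("drug_id\tdrug_type\tapproval_year\ttargets\n")
        for d in drugs:
            year = "" if d.approval_year is None else str(d.approval_year)
            fh.write(f"{d.drug_id}\t{d.drug_type}\t{year}\t{','.join(sorted(d.targets))}\n")


def first_approval_years(drugs: Iterable[DrugRecord]) -> dict:
    """Year each target was first used by an approved drug (None when
    every drug using it has an unknown date)."""
    years: dict = {}
    for d in drugs:
        for t in d.targets:
            if d.approval_year is None:
                years.setdefault(t, None)
            elif years.get(t) is None:
                years[t] = d.approval_year
            else:
                years[t] = min(years[t], d.approval_year)
    return years


def time_split(
    target_years: Mapping[str, int | None], cutoff: int = 2010
) -> tuple[set, set]:
    """Split targets by first-approval year into (train, test) positives.

    Train: first approved before the cutoff, or unknown approval date.
    Test: targets first introduced by drugs approved in or after the
    cutoff.  The two sets are disjoint by construction.
    """
    train = {t for t, y in target_years.items() if y is None or y < cutoff}
    test = {t for t, y in target_years.items() if y is not None and y >= cutoff}
    return train, test


@dataclass
class InnovationStats:
    """Per-drug novelty calls plus per-bin summaries."""

    per_drug: "pd.DataFrame"  # drug_id, year, n_targets, n_new, jumping
    per_bin: "pd.DataFrame"   # bin_start, n_targets, n_new_targets, new_target_fraction,
                              # n_drugs, jumping_fraction


def innovation_stats(drugs: Sequence[DrugRecord], bin_years: int = 5) -> InnovationStats:
    """Target-innovation analysis of a dated drug table.

    A target is "new" for a drug iff no drug approved in an earlier
    year used it ("validated" otherwise); a drug is "jumping" iff all
    its targets are new, "crawling" otherwise.  Per 5-year bin the
    summary reports the fraction of that bin's distinct targets that
    are new and the fraction of its drugs that are jumping.  Drugs
    without an approval year or without targets are ignored.
    """
    import pandas as pd

    dated = sorted(
        (d for d in drugs if d.approval_year is not None and d.targets),
        key=lambda d: (d.approval_year, d.drug_id),
    )
    used_before: dict = {}  # target -> first year used
    rows = []
    for d in dated:
        new = {
            t
            for t in d.targets
            if t not in used_before or used_before[t] >= d.approval_year
        }
        rows.append(
            {
                "drug_id": d.drug_id,
                "year": d.approval_year,
                "n_targets": len(d.targets),
                "n_new": len(new),
                "jumping": len(new) == len(d.targets),
            }
        )
        for t in d.targets:
            used_before.setdefault(t, d.approval_year)
    per_drug = pd.DataFrame(rows)

    bins = []
    if not per_drug.empty:
        y0 = per_drug["year"].min()
        first_bin_year: dict = {}
        for d in dated:
            b = y0 + bin_years * ((d.approval_year - y0) // bin_years)
            for t in d.targets:
                first_bin_year.setdefault(t, b)
        for b, grp in per_drug.groupby(
            y0 + bin_years * ((per_drug["year"] - y0) // bin_years)
        ):
            drug_ids = set(grp["drug_id"])
            bin_targets = set().union(
                *(d.targets for d in dated if d.drug_id in drug_ids)
            )
            n_new = sum(1 for t in bin_targets if first_bin_year[t] == b)
            bins.append(
                {
                    "bin_start": int(b),
                    "n_targets": len(bin_targets),
                    "n_new_targets": n_new,
                    "new_target_fraction": n_new / len(bin_targets),
                    "n_drugs": len(grp),
                    "jumping_fraction": grp["jumping"].mean(),
                }
            )
    per_bin = pd.DataFrame(bins)
    return InnovationStats(per_drug, per_bin)


def drug_disease_overlap(
    drug_disease_pairs: Iterable[tuple[str, str]],
    drug_targets: Mapping[str, Iterable],
    disease_genes: Mapping[str, Iterable],
) -> float:
    """Fraction of drug-disease associations in which at least one of the
    drug's targets is a known related gene of the disease.

    Only pairs where the drug has >= 1 target and the disease >= 1 known
    gene are eligible.
    """
    eligible = overlapping = 0
    for drug, disease in drug_disease_pairs:
        targets = set(drug_targets.get(drug, ()))
        genes = set(disease_genes.get(disease, ()))
        if not targets or not genes:
            continue
        eligible += 1
        if targets & genes:
            overlapping += 1
    if eligible == 0:
        raise InvalidInputError("no eligible drug-disease pairs")
    return overlapping / eligible
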