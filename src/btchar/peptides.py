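"""Unique-tryptic-peptide protein inference for crystal protein mixtures.

Cry proteins within a family (e.g. Cry1) are so similar that a peptide-level
search cannot, on its own, tell homologs apart. The procedure implemented
here resolves the members actually present in a crystal: digest the
candidate references with trypsin, index every peptide by the family members
that contain it, filter the search-engine peptide evidence (length 6-20,
contribution score strictly > 2, unmodified, deduplicated), and call a
protein positively identified when it is supported by at least two peptides
unique to it and its protein-level unused score exceeds 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from pyteomics import parser as _pyt_parser

__all__ = [
    "CLEAVAGE_RULES",
    "PeptideRow",
    "ProteinEvidence",
    "UniquenessIndex",
    "IdentificationResult",
    "digest",
    "build_uniqueness_index",
    "filter_peptides",
    "classify_peptides",
    "identify_proteins",
    "coverage",
    "evidence_from_table",
    "results_to_table",
]

# Cleavage rules as zero-width regexes marking the position after the cut
# residue. "trypsin" is the simple Keil rule: after K or R, not before P.
CLEAVAGE_RULES: dict[str, str] = {
    "trypsin": r"[KR](?=[^P])",
    "trypsin/p": r"[KR]",
}

_AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PeptideRow:
    """One peptide row of a search-engine peptide summary."""

    protein_id: str
    peptide: str
    contribution: float
    modified: bool = False

    def __post_init__(self):
        if self.contribution < 0:
            raise ValueError("contribution score must be >= 0")

    @property
    def length(self) -> int:
        return len(self.peptide)


@dataclass
class ProteinEvidence:
    """All peptide rows attributed to one candidate protein, with its
    protein-level unused score."""

    protein_id: str
    unused_score: float
    rows: list[PeptideRow] = field(default_factory=list)

    def __post_init__(self):
        for row in self.rows:
            if row.protein_id != self.protein_id:
                raise ValueError(
                    f"row protein_id {row.protein_id!r} does not match evidence "
                    f"group {self.protein_id!r}"
                )


@dataclass
class UniquenessIndex:
    """Map from tryptic peptide to the set of family members containing it
    as a substring of their full sequence."""

    peptide_members: dict[str, frozenset[str]]
    family: dict[str, str]
    equate_il: bool = False

    def members_of(self, peptide: str) -> frozenset[str]:
        key = _il(peptide) if self.equate_il else peptide
        return self.peptide_members.get(key, frozenset())


@dataclass(frozen=True)
class IdentificationResult:
    protein_id: str
    status: str  # positive | not_positive | excluded_low_score
    unused_score: float
    n_unique: int
    n_shared: int
    coverage_pct: float
    unique_peptides: tuple[str, ...] = ()
    shared_peptides: tuple[str, ...] = ()


def _il(seq: str) -> str:
    return seq.replace("I", "L")


def _validate_protein(protein: str) -> None:
    if not protein:
        raise ValueError("empty protein sequence")
    bad = set(protein) - _AA20
    if bad:
        raise ValueError(f"non-standard residues in protein sequence: {sorted(bad)}")


def digest(
    protein: str, missed_cleavages: int = 0, rule: str = "trypsin"
) -> list[tuple[str, int, int]]:
    """Proteolytic digest with 1-based inclusive peptide coordinates.

    With ``missed_cleavages = 0`` the peptides tile the protein exactly in
    order; allowing missed cleavages adds the joined products.
    """
    _validate_protein(protein)
    try:
        regex = CLEAVAGE_RULES[rule]
    except KeyError:
        raise ValueError(
            f"unknown cleavage rule {rule!r}; known: {sorted(CLEAVAGE_RULES)}"
        ) from None
    out = [
        (pep, start + 1, start + len(pep))
        for start, pep in _pyt_parser.icleave(protein, regex, missed_cleavages)
    ]
    out.sort(key=lambda t: (t[1], t[2]))
    return out


def build_uniqueness_index(
    family: Mapping[str, str],
    equate_il: bool = False,
    missed_cleavages: int = 0,
    rule: str = "trypsin",
) -> UniquenessIndex:
    """Index every tryptic peptide of a protein family by the members that
    contain it.

    Membership is decided by substring occurrence against each member's full
    sequence (not digest-to-digest equality), so a peptide carrying a missed
    cleavage still maps to every member whose sequence contains it. With
    ``equate_il`` true, isoleucine and leucine are identified before
    matching, as their residue masses are indistinguishable to the
    spectrometer.
    """
    if not family:
        raise ValueError("family must contain at least one member")
    fam = {str(k): str(v) for k, v in family.items()}
    if len(fam) != len(family):
        raise ValueError("family member ids must be unique")
    norm = {mid: (_il(seq) if equate_il else seq) for mid, seq in fam.items()}
    peptides: set[str] = set()
    for seq in fam.values():
        for pep, _, _ in digest(seq, missed_cleavages, rule):
            peptides.add(_il(pep) if equate_il else pep)
    index = {
        pep: frozenset(mid for mid, seq in norm.items() if pep in seq)
        for pep in peptides
    }
    return UniquenessIndex(peptide_members=index, family=fam, equate_il=equate_il)


def filter_peptides(
    evidence: ProteinEvidence,
    min_len: int = 6,
    max_len: int = 20,
    min_contribution: float = 2.0,
) -> list[PeptideRow]:
    """Apply the peptide-evidence filter cascade.

    Retains rows with length in [min_len, max_len], contribution strictly
    greater than ``min_contribution`` and no modification, then collapses
    duplicate peptide strings to a single representative (the
    highest-contribution row, first occurrence on ties).
    """
    kept: dict[str, PeptideRow] = {}
    for row in evidence.rows:
        if row.modified:
            continue
        if not (min_len <= row.length <= max_len):
            continue
        if not row.contribution > min_contribution:
            continue
        prev = kept.get(row.peptide)
        if prev is None or row.contribution > prev.contribution:
            kept[row.peptide] = row
    return list(kept.values())


def classify_peptides(
    peptides: Sequence[PeptideRow], index: UniquenessIndex
) -> tuple[list[PeptideRow], list[PeptideRow]]:
    """Partition filtered peptides into (unique, shared) against the family.

    A peptide is unique when exactly one family member contains it. Peptides
    absent from the prebuilt index (e.g. semi-tryptic or more missed
    cleavages than indexed) are classified by direct substring search and a
    warning is recorded.
    """
    unique: list[PeptideRow] = []
    shared: list[PeptideRow] = []
    for row in peptides:
        members = index.members_of(row.peptide)
        if not members:
            warnings.warn(
                f"peptide {row.peptide!r} absent from uniqueness index; "
                "classifying by direct substring search",
                stacklevel=2,
            )
            pep = _il(row.peptide) if index.equate_il else row.peptide
            members = frozenset(
                mid
                for mid, seq in index.family.items()
                if pep in (_il(seq) if index.equate_il else seq)
            )
        (unique if len(members) == 1 else shared).append(row)
    return unique, shared


def coverage(protein: str, peptides: Sequence[PeptideRow]) -> float:
    """Percent of residues covered by at least one peptide occurrence.

    Every (possibly overlapping) substring occurrence of every peptide
    contributes; reported to 2 decimals.
    """
    _validate_protein(protein)
    if not peptides:
        return 0.0
    covered = [False] * len(protein)
    for row in peptides:
        pep = row.peptide
        start = protein.find(pep)
        while start != -1:
            for i in range(start, start + len(pep)):
                covered[i] = True
            start = protein.find(pep, start + 1)
    return round(100.0 * sum(covered) / len(protein), 2)


def identify_proteins(
    evidence_set: Sequence[ProteinEvidence],
    family: Mapping[str, str],
    min_unused: float = 2.0,
    min_unique: int = 2,
    min_len: int = 6,
    max_len: int = 20,
    min_contribution: float = 2.0,
    equate_il: bool = False,
    missed_cleavages: int = 0,
) -> list[IdentificationResult]:
    """Run the full unique-peptide identification procedure.

    Evidence with unused score <= ``min_unused`` is excluded outright; the
    rest is filtered, classified against the family uniqueness index, and a
    protein is called positive iff supported by at least ``min_unique``
    unique peptides. Coverage is computed from the retained (filtered)
    peptides.
    """
    fam = {str(k): str(v) for k, v in family.items()}
    for ev in evidence_set:
        if ev.protein_id not in fam:
            raise KeyError(
                f"evidence references protein {ev.protein_id!r} absent from the family"
            )
    index = build_uniqueness_index(fam, equate_il=equate_il, missed_cleavages=missed_cleavages)
    results: list[IdentificationResult] = []
    for ev in evidence_set:
        if not ev.unused_score > min_unused:
            results.append(
                IdentificationResult(ev.protein_id, "excluded_low_score",
                                     ev.unused_score, 0, 0, 0.0)
            )
            continue
        filtered = filter_peptides(ev, min_len, max_len, min_contribution)
        unique, shared = classify_peptides(filtered, index)
        cov = coverage(fam[ev.protein_id], filtered)
        status = "positive" if len(unique) >= min_unique else "not_positive"
        results.append(
            IdentificationResult(
                ev.protein_id, status, ev.unused_score,
                len(unique), len(shared), cov,
                tuple(sorted(r.peptide for r in unique)),
                tuple(sorted(r.peptide for r in shared)),
            )
        )
    return results


def evidence_from_table(table: pd.DataFrame) -> list[ProteinEvidence]:
    """Group a search-engine style peptide table into per-protein evidence.

    Expects columns ``protein_id, peptide, contribution, modified, unused``
    (a ``length`` column, if present, is ignored in favor of the peptide
    string itself).
    """
    required = {"protein_id", "peptide", "contribution", "modified", "unused"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"PSM table missing columns: {sorted(missing)}")
    out = []
    for pid, group in table.groupby("protein_id", sort=True):
        unused_vals = group["unused"].unique()
        if len(unused_vals) != 1:
            raise ValueError(f"conflicting unused scores for protein {pid!r}")
        rows = [
            PeptideRow(str(pid), str(r.peptide), float(r.contribution), bool(r.modified))
            for r in group.itertuples()
        ]
        out.append(ProteinEvidence(str(pid), float(unused_vals[0]), rows))
    return out


def results_to_table(results: Sequence[IdentificationResult]) -> pd.DataFrame:
    """Identification results as a protein-summary style table."""
    return pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "unused_score": r.unused_score,
                "coverage_pct": r.coverage_pct,
                "shared_peptides": r.n_shared,
                "unique_peptides": r.n_unique,
                "status": r.status,
            }
            for r in results
        ],
        columns=["protein_id", "unused_score", "coverage_pct",
                 "shared_peptides", "unique_peptides", "status"],
    )
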