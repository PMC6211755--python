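"""In-silico PCR with degenerate primers.

Degenerate-primer site finding, amplicon prediction, collection screening for
*vip3* genes, *vip3* typing by alternative reverse primers, suffix/prefix
contig merging, and pairwise percent identity.

Coordinates are 1-based inclusive throughout, so an amplicon spanning
positions ``start..end`` has length ``end - start + 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner

__all__ = [
    "IUPAC_EXPANSION",
    "PrimerPair",
    "AmpliconPrediction",
    "TypingResult",
    "IdentityReport",
    "ScreenResult",
    "VIP3_SCREENING_PAIR",
    "VIP3_TYPING_FORWARD",
    "VIP3_TYPING_REVERSE",
    "iupac_match",
    "reverse_complement",
    "find_primer_sites",
    "predict_amplicons",
    "screen_collection",
    "type_vip3",
    "merge_contigs",
    "percent_identity",
    "round_half_away",
]

# IUPAC nucleotide ambiguity codes and their expansion sets.
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "S": "S", "W": "W", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}


class PrimerError(ValueError):
    """Invalid primer or template input."""


class AmbiguousTypingError(ValueError):
    """More than one typing reverse primer yields an amplicon."""

    def __init__(self, candidates: Sequence[str]):
        self.candidates = list(candidates)
        super().__init__(
            f"ambiguous typing: reverse primers {sorted(self.candidates)} all "
            "yield an amplicon with the shared forward primer"
        )


class NoOverlapError(ValueError):
    """Contigs share no suffix/prefix overlap of the required length."""


def _validate_iupac(seq: str) -> None:
    for ch in seq:
        if ch not in IUPAC_EXPANSION:
            raise PrimerError(f"invalid IUPAC nucleotide symbol: {ch!r}")


def _validate_template(seq: str) -> None:
    for ch in seq:
        if ch not in "ACGT":
            raise PrimerError(f"invalid template nucleotide: {ch!r} (templates must be A/C/G/T)")


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse degenerate primer pair.

    ``expected_span`` holds the 1-based inclusive binding coordinates of the
    amplicon on the reference gene, when known.
    """

    name: str
    forward: str
    reverse: str
    expected_span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not seq:
                raise PrimerError(f"{label} primer of pair {self.name!r} is empty")
            _validate_iupac(seq)

    @property
    def expected_size(self) -> Optional[int]:
        if self.expected_span is None:
            return None
        start, end = self.expected_span
        return end - start + 1


@dataclass(frozen=True)
class AmpliconPrediction:
    template_id: str
    start: int
    end: int
    forward_primer: str
    reverse_primer: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TypingResult:
    isolate_id: str
    assigned_type: str  # reverse-primer label, or "none"
    amplicon: Optional[AmpliconPrediction] = None


@dataclass(frozen=True)
class IdentityReport:
    identity_pct: int
    query_cover_pct: int
    aligned_length: int


@dataclass
class ScreenResult:
    """Per-isolate presence/absence table plus collection summary."""

    table: pd.DataFrame  # columns: isolate_id, positive
    n_positive: int
    percent_positive: int

    def __iter__(self):  # allows  table, (n, pct) style unpacking
        yield self.table
        yield (self.n_positive, self.percent_positive)


# The screening pair amplifies the N-terminal part of the vip3 gene
# (expected product 1395 bp); the typing primers share one forward primer and
# distinguish vip3Aa / vip3Af / vip3Ag by alternative reverse primers on the
# C-terminal part.
VIP3_SCREENING_PAIR = PrimerPair(
    name="vip3-sc",
    forward="TGCCACTGGTATCAARGA",
    reverse="CCATTAATYGGAKTCAAAAATGTTTCACTGAT",
    expected_span=(78, 1472),
)

VIP3_TYPING_FORWARD = "ASTTTAAGATATGAGGYAACAGC"  # vip3A-F1

VIP3_TYPING_REVERSE: dict[str, PrimerPair] = {
    "vip3Aa": PrimerPair("vip3Aa", VIP3_TYPING_FORWARD,
                         "CATCGTAAAAATGTACAATAGGA", (1297, 2356)),
    "vip3Af": PrimerPair("vip3Af", VIP3_TYPING_FORWARD,
                         "TCAAATGATATATGACCACCA", (1297, 2348)),
    "vip3Ag": PrimerPair("vip3Ag", VIP3_TYPING_FORWARD,
                         "ATGTAAAACGAGAAAGCTCTACA", (1297, 2323)),
}


def iupac_match(pattern_base: str, template_base: str) -> bool:
    """True iff ``template_base`` lies in the expansion set of ``pattern_base``."""
    try:
        expansion = IUPAC_EXPANSION[pattern_base]
    except KeyError:
        raise PrimerError(f"invalid IUPAC nucleotide symbol: {pattern_base!r}") from None
    if template_base not in "ACGT":
        raise PrimerError(f"invalid template nucleotide: {template_base!r}")
    return template_base in expansion


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving IUPAC ambiguity codes."""
    _validate_iupac(seq)
    return "".join(_COMPLEMENT[ch] for ch in reversed(seq))


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (22.5 -> 23)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def find_primer_sites(
    template: str, primer: str, max_mismatch: int = 0
) -> list[tuple[int, str]]:
    """Locate primer binding sites on both strands of a template.

    Plus-strand hits are positions where the primer matches the template
    left-to-right; minus-strand hits are positions where the reverse
    complement of the primer matches, reported by the 1-based position of the
    site's leftmost base on the plus strand. A mismatch is any template base
    outside the expansion set of the corresponding (possibly degenerate)
    primer base; at most ``max_mismatch`` are tolerated.
    """
    if not primer:
        raise PrimerError("empty primer")
    _validate_iupac(primer)
    _validate_template(template)
    hits: list[tuple[int, str]] = []
    for pattern, strand in ((primer, "+"), (reverse_complement(primer), "-")):
        m = len(pattern)
        expansions = [IUPAC_EXPANSION[ch] for ch in pattern]
        for i in range(len(template) - m + 1):
            mism = 0
            window = template[i:i + m]
            for base, allowed in zip(window, expansions):
                if base not in allowed:
                    mism += 1
                    if mism > max_mismatch:
                        break
            else:
                hits.append((i + 1, strand))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def predict_amplicons(
    template: str,
    pair: PrimerPair,
    max_mismatch: int = 0,
    size_limits: tuple[int, int] = (50, 5000),
    template_id: str = "template",
) -> list[AmpliconPrediction]:
    """Predict PCR products for a primer pair on one template.

    One prediction per (forward plus-strand hit, reverse minus-strand hit)
    with the forward site left of the reverse site and product size within
    ``size_limits``. ``start`` is the forward hit position; ``end`` is the
    rightmost base of the reverse-primer site.
    """
    fwd_hits = [p for p, s in find_primer_sites(template, pair.forward, max_mismatch) if s == "+"]
    rev_hits = [p for p, s in find_primer_sites(template, pair.reverse, max_mismatch) if s == "-"]
    lo, hi = size_limits
    out = []
    for f in fwd_hits:
        for r in rev_hits:
            end = r + len(pair.reverse) - 1
            if f >= r:
                continue
            length = end - f + 1
            if lo <= length <= hi:
                out.append(AmpliconPrediction(template_id, f, end, pair.name, pair.name))
    out.sort(key=lambda a: (a.start, a.end))
    return out


def _as_genome_mapping(genomes) -> dict[str, str]:
    """Accept a mapping, an iterable of SeqRecords, or a FASTA path."""
    if isinstance(genomes, Mapping):
        return {str(k): str(v) for k, v in genomes.items()}
    if isinstance(genomes, (str, bytes)) or hasattr(genomes, "read"):
        records = list(SeqIO.parse(genomes, "fasta"))
    else:
        records = list(genomes)
    out: dict[str, str] = {}
    for rec in records:
        rid = str(getattr(rec, "id", rec[0]))
        seq = str(getattr(rec, "seq", rec[1]))
        if rid in out:
            raise ValueError(f"duplicate isolate id: {rid!r}")
        out[rid] = seq
    return out


def screen_collection(
    genomes,
    pair: PrimerPair = VIP3_SCREENING_PAIR,
    max_mismatch: int = 0,
    size_limits: tuple[int, int] = (50, 5000),
) -> ScreenResult:
    """Screen a collection of genomes for a gene by in-silico PCR.

    An isolate is positive iff the primer pair predicts at least one amplicon
    on its genome. The positive percentage is rounded half away from zero to
    the nearest integer (18/80 reports as 23%).
    """
    mapping = _as_genome_mapping(genomes)
    if not mapping:
        raise ValueError("no genomes supplied")
    rows = []
    for isolate_id, seq in mapping.items():
        amps = predict_amplicons(seq, pair, max_mismatch, size_limits, template_id=isolate_id)
        rows.append({"isolate_id": isolate_id, "positive": bool(amps)})
    table = pd.DataFrame(rows, columns=["isolate_id", "positive"])
    n_positive = int(table["positive"].sum())
    pct = round_half_away(100.0 * n_positive / len(table))
    return ScreenResult(table=table, n_positive=n_positive, percent_positive=pct)


def type_vip3(
    genome: str,
    forward: str = VIP3_TYPING_FORWARD,
    reverse_set: Optional[Mapping[str, str]] = None,
    isolate_id: str = "isolate",
    max_mismatch: int = 0,
    size_limits: tuple[int, int] = (50, 5000),
) -> TypingResult:
    """Assign a *vip3* type by which reverse primer co-amplifies with the
    shared forward primer.

    Exactly one productive reverse primer assigns its label; none assigns
    ``"none"``; two or more raise :class:`AmbiguousTypingError`.
    """
    if reverse_set is None:
        reverse_set = {label: p.reverse for label, p in VIP3_TYPING_REVERSE.items()}
    if not reverse_set:
        raise ValueError("reverse_set is empty")
    productive: dict[str, AmpliconPrediction] = {}
    for label, rev in reverse_set.items():
        pair = PrimerPair(label, forward, rev)
        amps = predict_amplicons(genome, pair, max_mismatch, size_limits, template_id=isolate_id)
        if amps:
            productive[label] = amps[0]
    if not productive:
        return TypingResult(isolate_id, "none", None)
    if len(productive) > 1:
        raise AmbiguousTypingError(list(productive))
    ((label, amp),) = productive.items()
    return TypingResult(isolate_id, label, amp)


def merge_contigs(n_term: str, c_term: str, min_overlap: int = 20) -> str:
    """Merge two sequenced contigs by their exact suffix/prefix overlap.

    Returns the shortest superstring in which a suffix of ``n_term`` equals a
    prefix of ``c_term`` with overlap >= ``min_overlap`` (i.e. the merge at
    the maximal valid overlap, which is unique).
    """
    if not n_term or not c_term:
        raise ValueError("contigs must be non-empty")
    max_k = min(len(n_term), len(c_term))
    for k in range(max_k, min_overlap - 1, -1):
        if n_term[-k:] == c_term[:k]:
            return n_term + c_term[k:]
    raise NoOverlapError(
        f"no exact suffix/prefix overlap of length >= {min_overlap} between contigs"
    )


def _make_aligner(match: float, mismatch: float, gap: float) -> PairwiseAligner:
    aligner = PairwiseAligner(
        mode="global",
        match_score=match,
        mismatch_score=mismatch,
        open_gap_score=gap,
        extend_gap_score=gap,
    )
    # end-gap-free global alignment (terminal gaps cost nothing)
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    return aligner


def percent_identity(
    query: str,
    reference: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> IdentityReport:
    """Percent identity of a global end-gap-free pairwise alignment.

    Identity is matches / aligned columns (terminal gaps excluded), x100,
    rounded to the nearest integer; query cover is the fraction of query
    residues inside the aligned region, x100. A minimal BLAST-like surrogate
    for reporting how closely an assembled amplicon matches a reference gene.
    """
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(match, mismatch, gap)
    aln = aligner.align(reference, query)[0]
    blocks = aln.aligned  # pairs of (reference blocks, query blocks)
    ref_blocks, q_blocks = blocks[0], blocks[1]
    matches = 0
    block_len = 0
    for (t0, t1), (q0, q1) in zip(ref_blocks, q_blocks):
        block_len += t1 - t0
        matches += sum(1 for a, b in zip(reference[t0:t1], query[q0:q1]) if a == b)
    internal_gaps = 0
    for i in range(1, len(ref_blocks)):
        internal_gaps += ref_blocks[i][0] - ref_blocks[i - 1][1]
        internal_gaps += q_blocks[i][0] - q_blocks[i - 1][1]
    columns = block_len + internal_gaps
    if columns == 0:
        return IdentityReport(0, 0, 0)
    identity = round_half_away(100.0 * matches / columns)
    q_span = q_blocks[-1][1] - q_blocks[0][0]
    cover = round_half_away(100.0 * q_span / len(query))
    return IdentityReport(identity, cover, columns)
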