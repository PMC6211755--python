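"""Protein-level characterization: ORF translation, molecular mass, residue
differences, and gel-filtration oligomeric state.

The gel-filtration half calibrates a size-exclusion column with standards of
known mass — the partition coefficient Kav = (Ve - V0)/(Vc - V0) is linear
in log10(mass) over the fractionation range — then reads the apparent native
mass of a query peak off the inverted line and infers the oligomer order as
the nearest multiple of the monomer mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight
from scipy import stats

__all__ = [
    "OrfTranslation",
    "ResidueDiff",
    "CalibrationCurve",
    "GelFiltrationResult",
    "PrematureStopError",
    "FrameError",
    "translate_orf",
    "molecular_mass",
    "residue_differences",
    "fit_calibration",
    "apparent_mw",
    "oligomer_order",
    "gel_filtration",
    "VIP3AA16_VIP3AA65_DIFFS",
    "vip3aa_difference_fixture",
    "load_single_fasta",
]

_AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")

_WATER_AVG = 18.0153
_WATER_MONO = 18.010565


class FrameError(ValueError):
    """ORF length not divisible by 3, or missing start codon."""


class PrematureStopError(ValueError):
    def __init__(self, codon_index: int):
        self.codon_index = codon_index  # 1-based codon position
        super().__init__(f"internal stop codon at codon {codon_index}")


@dataclass(frozen=True)
class OrfTranslation:
    dna_length: int
    protein: str
    had_terminal_stop: bool

    @property
    def protein_length(self) -> int:
        return len(self.protein)


@dataclass(frozen=True)
class ResidueDiff:
    position: int  # 1-based
    residue_a: str
    residue_b: str


@dataclass(frozen=True)
class CalibrationCurve:
    slope: float  # Kav per log10(kDa); negative on a working column
    intercept: float
    v0: float  # void volume, ml
    vc: float  # geometric column volume, ml
    r_squared: float


@dataclass(frozen=True)
class GelFiltrationResult:
    ve: float
    kav: float
    apparent_mass: float  # kDa
    monomer_mass: float  # kDa
    oligomer_order: int


def translate_orf(dna: str, table: str = "Standard", require_start: bool = True) -> OrfTranslation:
    """Translate a complete ORF with the standard genetic code.

    The terminal stop codon (when present) is consumed, so a stop-terminated
    ORF of 3(n+1) bp encodes n residues. Internal stops and frame violations
    raise with the offending position.
    """
    dna = dna.upper()
    if len(dna) == 0 or len(dna) % 3 != 0:
        raise FrameError(f"ORF length {len(dna)} is not a positive multiple of 3")
    codon_table = CodonTable.unambiguous_dna_by_name[table]
    if require_start and dna[:3] not in codon_table.start_codons:
        raise FrameError(f"ORF does not begin with a start codon ({dna[:3]})")
    protein = str(Seq(dna).translate(table=table))
    stop_at = protein.find("*")
    had_stop = False
    if stop_at != -1:
        if stop_at != len(protein) - 1:
            raise PrematureStopError(stop_at + 1)
        protein = protein[:-1]
        had_stop = True
    return OrfTranslation(dna_length=len(dna), protein=protein, had_terminal_stop=had_stop)


def molecular_mass(protein: str, mode: str = "average") -> float:
    """Molecular mass of a peptide/protein in Da.

    Sum of residue masses plus one water; ``mode`` selects average (default)
    or monoisotopic residue masses. The empty chain weighs one water.
    """
    if mode not in ("average", "monoisotopic"):
        raise ValueError("mode must be 'average' or 'monoisotopic'")
    bad = set(protein) - _AA20
    if bad:
        raise ValueError(f"unknown residues: {sorted(bad)}")
    if not protein:
        return _WATER_AVG if mode == "average" else _WATER_MONO
    return float(
        molecular_weight(protein, seq_type="protein", monoisotopic=(mode == "monoisotopic"))
    )


def residue_differences(a: str, b: str) -> list[ResidueDiff]:
    """All positions (1-based, in order) where two equal-length sequences differ."""
    if len(a) != len(b):
        raise ValueError(
            f"sequences differ in length ({len(a)} vs {len(b)}); no alignment is performed"
        )
    return [
        ResidueDiff(i + 1, ra, rb) for i, (ra, rb) in enumerate(zip(a, b)) if ra != rb
    ]


def fit_calibration(
    standards: Sequence[tuple[float, float]], v0: float, vc: float
) -> CalibrationCurve:
    """Least-squares Kav vs log10(mass) line from (mass_kDa, Ve_ml) standards."""
    if v0 >= vc:
        raise ValueError("void volume V0 must be smaller than column volume Vc")
    if len(standards) < 2:
        raise ValueError("need at least 2 calibration standards")
    masses = np.array([m for m, _ in standards], float)
    ves = np.array([v for _, v in standards], float)
    if np.any(masses <= 0):
        raise ValueError("standard masses must be positive")
    if len(set(masses)) < 2:
        raise ValueError("standards must include at least 2 distinct masses")
    if np.any(ves < v0) or np.any(ves > vc):
        raise ValueError("standard elution volumes must lie within [V0, Vc]")
    kav = (ves - v0) / (vc - v0)
    res = stats.linregress(np.log10(masses), kav)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        v0=float(v0),
        vc=float(vc),
        r_squared=float(res.rvalue**2),
    )


def apparent_mw(curve: CalibrationCurve, ve: float) -> float:
    """Apparent native mass (kDa) of a peak eluting at ``ve`` ml."""
    if not curve.v0 <= ve <= curve.vc:
        raise ValueError(f"Ve = {ve} ml outside the column range [{curve.v0}, {curve.vc}] ml")
    kav = (ve - curve.v0) / (curve.vc - curve.v0)
    return float(10 ** ((kav - curve.intercept) / curve.slope))


def oligomer_order(apparent_mass: float, monomer_mass: float) -> int:
    """Nearest-integer ratio of apparent native mass to monomer mass (>= 1)."""
    if apparent_mass <= 0 or monomer_mass <= 0:
        raise ValueError("masses must be positive")
    ratio = apparent_mass / monomer_mass
    return max(1, int(math.floor(ratio + 0.5)))


def gel_filtration(
    curve: CalibrationCurve, ve: float, monomer_mass: float
) -> GelFiltrationResult:
    """Full read-out for one query peak: Kav, apparent mass, oligomer order."""
    mass = apparent_mw(curve, ve)
    return GelFiltrationResult(
        ve=ve,
        kav=(ve - curve.v0) / (curve.vc - curve.v0),
        apparent_mass=mass,
        monomer_mass=monomer_mass,
        oligomer_order=oligomer_order(mass, monomer_mass),
    )


# Residue differences between the Vip3Aa16 reference protein (residue_a) and
# the newly described Vip3Aa65 (residue_b), 1-based positions on the
# 789-residue chain.
VIP3AA16_VIP3AA65_DIFFS: dict[int, tuple[str, str]] = {
    121: ("L", "I"),
    358: ("I", "V"),
    536: ("S", "K"),
    633: ("N", "T"),
    755: ("M", "I"),
    760: ("F", "L"),
    761: ("E", "G"),
    776: ("Y", "N"),
    782: ("H", "K"),
}


def vip3aa_difference_fixture(length: int = 789, backbone: str = "G") -> tuple[str, str]:
    """Synthetic stand-in pair carrying the published Vip3Aa16/Vip3Aa65
    residue differences on a neutral backbone.

    The full sequences are NOT the real proteins (those require the GenBank
    record); only the differing positions and residues are meaningful.
    """
    if backbone not in _AA20:
        raise ValueError("backbone must be a standard residue")
    if length < max(VIP3AA16_VIP3AA65_DIFFS):
        raise ValueError("length too short for the published difference positions")
    a = [backbone] * length
    b = [backbone] * length
    for pos, (ra, rb) in VIP3AA16_VIP3AA65_DIFFS.items():
        a[pos - 1] = ra
        b[pos - 1] = rb
    return "".join(a), "".join(b)


def load_single_fasta(path) -> tuple[str, str]:
    """Load exactly one record from a FASTA file; returns (id, sequence)."""
    records = list(SeqIO.parse(path, "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record in {path}, found {len(records)}")
    return records[0].id, str(records[0].seq)
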