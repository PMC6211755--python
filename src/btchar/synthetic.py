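"""Seeded synthetic inputs with the statistical structure each analysis
stage assumes.

Emulates the study's raw materials so the whole pipeline runs without any
download: a homologous crystal-protein family with controlled shared/unique
peptide structure, isolate genomes with planted degenerate-primer binding
sites (80 isolates, 18 carriers by default), search-engine style peptide
tables with every filterable defect represented, binomial mortality drawn
from a probit truth model (5 threefold dilutions, 16 larvae per dose), and
gel-filtration calibration tables generated from a known Kav line. Every
generator takes a seed and emits a ground-truth record that the matching
analysis stage must recover exactly on noiseless output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .primers import (
    IUPAC_EXPANSION,
    PrimerPair,
    VIP3_SCREENING_PAIR,
    VIP3_TYPING_FORWARD,
    VIP3_TYPING_REVERSE,
    reverse_complement,
    find_primer_sites,
)
from .peptides import digest
from .probit import BioassayDataset, DoseGroup

__all__ = [
    "AMINO_ACIDS",
    "SyntheticConfig",
    "BioassayDesign",
    "PSMNoise",
    "make_reference_family",
    "make_isolate_genomes",
    "make_psm_table",
    "make_bioassay",
    "make_calibration",
    "make_orf",
    "family_to_fasta",
    "genomes_to_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Master-seed stream labels; child RNGs are derived as default_rng([seed, label]).
_STREAMS = {
    "family": 0,
    "genomes": 1,
    "psm": 2,
    "bioassay": 3,
    "calibration": 4,
    "orf": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class BioassayDesign:
    """Dose-response design: geometric dilution series bracketing the LC50.

    Defaults reproduce the study's spore/crystal assays: HD1-level truth
    (slope 1.05 probits per log10 dose, LC50 48 ng/cm2), 5 threefold serial
    dilutions, 16 neonate larvae per concentration, no control mortality.
    """

    slope: float = 1.05
    lc50: float = 48.0
    dilution_factor: float = 3.0
    n_doses: int = 5
    larvae_per_dose: int = 16
    control_mortality: float = 0.0

    def __post_init__(self):
        if self.slope <= 0 or self.lc50 <= 0:
            raise ValueError("slope and lc50 must be positive")
        if self.dilution_factor <= 1:
            raise ValueError("dilution factor must exceed 1")
        if self.n_doses < 2:
            raise ValueError("need at least 2 doses")
        if self.larvae_per_dose < 1:
            raise ValueError("need at least 1 larva per dose")
        if not 0 <= self.control_mortality < 1:
            raise ValueError("control mortality must be a fraction in [0, 1)")

    def doses(self) -> np.ndarray:
        center = (self.n_doses - 1) / 2.0
        return self.lc50 * self.dilution_factor ** (np.arange(self.n_doses) - center)


@dataclass(frozen=True)
class PSMNoise:
    """Score-distribution parameters for synthetic peptide tables.

    True-peptide contribution scores are drawn from a shifted exponential
    above the filter cutoff; decoy rows from a low-mean exponential. Only
    the > 2 cutoff matters downstream.
    """

    contribution_shift: float = 2.0
    contribution_scale: float = 3.0
    decoy_scale: float = 0.8
    true_unused_range: tuple[float, float] = (10.0, 600.0)
    decoy_unused: float = 1.5


@dataclass
class SyntheticConfig:
    """Study-level generation parameters (defaults mirror the study design:
    80 isolates, 18 *vip3* carriers, Cry-like homolog family)."""

    seed: int = 0
    n_isolates: int = 80
    n_vip3_positive: int = 18
    family_size: int = 3
    base_protein_length: int = 600
    divergence: int = 25
    genome_length: int = 3000
    psm_noise: PSMNoise = field(default_factory=PSMNoise)
    bioassay_design: BioassayDesign = field(default_factory=BioassayDesign)

    def __post_init__(self):
        if self.n_vip3_positive > self.n_isolates:
            raise ValueError("n_vip3_positive cannot exceed n_isolates")
        if self.n_vip3_positive < 0 or self.n_isolates < 1:
            raise ValueError("counts must be non-negative (and at least one isolate)")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if self.family_size < 1:
            raise ValueError("family must have at least one member")
        if self.base_protein_length < 50:
            raise ValueError("base protein length must be >= 50")


def make_reference_family(
    base_length: int,
    n_members: int,
    divergence: int,
    seed: int,
) -> tuple[dict[str, str], dict[str, list[tuple[int, str, str]]]]:
    """Generate a homologous protein family by point substitution.

    One random base sequence; each member carries exactly ``divergence``
    substitutions at recorded positions. Substitutions avoid K, R and P (as
    original or replacement residue) so the tryptic cleavage pattern of the
    base is preserved and unique peptides are exactly those overlapping a
    substituted position.

    Returns (family mapping id -> sequence, truth mapping id -> list of
    (1-based position, old residue, new residue)).
    """
    if base_length < 50:
        raise ValueError("base_length must be >= 50")
    if n_members < 2:
        raise ValueError("n_members must be >= 2")
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    if divergence >= base_length:
        raise ValueError("divergence must be smaller than base_length")
    rng = _rng(seed, "family")
    aa = np.array(list(AMINO_ACIDS))
    base = rng.choice(aa, size=base_length)
    # Guarantee scattered tryptic sites so peptides have usable lengths.
    for i in range(9, base_length - 1, 10):
        base[i] = rng.choice(["K", "R"])
        if base[i + 1] == "P":
            base[i + 1] = "A"
    base_seq = "".join(base)
    eligible = [i for i, r in enumerate(base_seq) if r not in "KRP"]
    if divergence > len(eligible):
        raise ValueError("divergence exceeds the number of substitutable positions")
    neutral = [r for r in AMINO_ACIDS if r not in "KRP"]
    family: dict[str, str] = {}
    truth: dict[str, list[tuple[int, str, str]]] = {}
    for m in range(n_members):
        mid = f"FAM{m + 1}"
        positions = sorted(rng.choice(len(eligible), size=divergence, replace=False))
        seq = list(base_seq)
        subs = []
        for pos_idx in positions:
            pos = eligible[pos_idx]
            old = seq[pos]
            new = str(rng.choice([r for r in neutral if r != old]))
            seq[pos] = new
            subs.append((pos + 1, old, new))
        family[mid] = "".join(seq)
        truth[mid] = subs
    return family, truth


def _concrete_expansion(primer: str, rng: np.random.Generator) -> str:
    """One concrete A/C/G/T realization of a degenerate primer."""
    return "".join(str(rng.choice(sorted(IUPAC_EXPANSION[ch]))) for ch in primer)


def _plant(genome: list[str], site: str, start0: int) -> None:
    genome[start0:start0 + len(site)] = list(site)


def make_isolate_genomes(
    config: SyntheticConfig,
    screening_pair: PrimerPair = VIP3_SCREENING_PAIR,
    plant_typing_sites: bool = True,
    type_probs: Mapping[str, float] = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate isolate genomes; carriers get primer binding sites planted at
    the pair's expected coordinates.

    Exactly ``n_vip3_positive`` genomes contain a region matched by both
    screening primers; the rest contain neither site (verified, with
    regeneration on accidental matches). Carriers optionally also receive one
    typing-primer site pair so the typing stage can run; carrier types are
    drawn from ``type_probs`` (defaults approximating the observed
    vip3Aa/vip3Af/vip3Ag prevalence).

    Returns (genomes mapping, truth table with columns
    isolate_id / carrier / vip3_type).
    """
    if screening_pair.expected_span is None:
        raise ValueError("screening pair needs expected binding coordinates")
    span_start, span_end = screening_pair.expected_span
    needed = max(span_end, max(p.expected_span[1] for p in VIP3_TYPING_REVERSE.values())
                 if plant_typing_sites else span_end)
    if needed > config.genome_length:
        raise ValueError(
            f"genome_length {config.genome_length} too short for primer coordinates "
            f"(need >= {needed})"
        )
    if type_probs is None:
        type_probs = {"vip3Aa": 0.69, "vip3Af": 0.19, "vip3Ag": 0.12}
    rng = _rng(config.seed, "genomes")
    carrier_idx = set(
        rng.choice(config.n_isolates, size=config.n_vip3_positive, replace=False).tolist()
    )
    labels = list(type_probs)
    probs = np.array([type_probs[k] for k in labels], float)
    probs = probs / probs.sum()
    bases = np.array(list("ACGT"))
    genomes: dict[str, str] = {}
    rows = []
    for i in range(config.n_isolates):
        isolate_id = f"ISO{i + 1:03d}"
        carrier = i in carrier_idx
        vtype = str(rng.choice(labels, p=probs)) if carrier else "none"
        for _attempt in range(20):
            genome = list(rng.choice(bases, size=config.genome_length))
            if carrier:
                fwd_site = _concrete_expansion(screening_pair.forward, rng)
                rev_site = reverse_complement(_concrete_expansion(screening_pair.reverse, rng))
                _plant(genome, fwd_site, span_start - 1)
                _plant(genome, rev_site, span_end - len(rev_site))
                if plant_typing_sites:
                    tpair = VIP3_TYPING_REVERSE[vtype]
                    t_start, t_end = tpair.expected_span
                    t_fwd = _concrete_expansion(tpair.forward, rng)
                    t_rev = reverse_complement(_concrete_expansion(tpair.reverse, rng))
                    _plant(genome, t_fwd, t_start - 1)
                    _plant(genome, t_rev, t_end - len(t_rev))
            seq = "".join(genome)
            if _sites_consistent(seq, screening_pair, carrier, plant_typing_sites, vtype):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError(f"could not generate a consistent genome for {isolate_id}")
        genomes[isolate_id] = seq
        rows.append({"isolate_id": isolate_id, "carrier": carrier, "vip3_type": vtype})
    truth = pd.DataFrame(rows, columns=["isolate_id", "carrier", "vip3_type"])
    return genomes, truth


def _sites_consistent(
    seq: str, pair: PrimerPair, carrier: bool, check_typing: bool, vtype: str
) -> bool:
    fwd = [h for h in find_primer_sites(seq, pair.forward) if h[1] == "+"]
    rev = [h for h in find_primer_sites(seq, pair.reverse) if h[1] == "-"]
    if carrier:
        if not (len(fwd) == 1 and len(rev) == 1):
            return False
    elif fwd and rev:
        return False
    if check_typing:
        productive = []
        for label, tpair in VIP3_TYPING_REVERSE.items():
            tf = [h for h in find_primer_sites(seq, tpair.forward) if h[1] == "+"]
            tr = [h for h in find_primer_sites(seq, tpair.reverse) if h[1] == "-"]
            if tf and tr:
                productive.append(label)
        expected = [vtype] if carrier else []
        if productive != expected:
            return False
    return True


def make_psm_table(
    true_proteins: Sequence[str],
    family: Mapping[str, str],
    seed: int,
    noise: PSMNoise = PSMNoise(),
) -> pd.DataFrame:
    """Emulate a search-engine peptide summary from known crystal content.

    Peptide rows are drawn from the tryptic digests of the true proteins
    with high contribution scores, then defect rows are injected so that
    every individual filter is exercised: a duplicate, a modified row, a
    too-short (<6) and a too-long (>20) peptide, and a row at/below the
    contribution cutoff. If the family has members not in ``true_proteins``,
    the first such member becomes a low-unused decoy entry.

    Columns: protein_id, peptide, length, contribution, modified, unused.
    """
    fam = {str(k): str(v) for k, v in family.items()}
    unknown = [p for p in true_proteins if p not in fam]
    if unknown:
        raise KeyError(f"unknown protein ids in true_proteins: {unknown}")
    if not true_proteins:
        raise ValueError("true_proteins must be non-empty")
    rng = _rng(seed, "psm")
    rows: list[dict] = []
    lo_u, hi_u = noise.true_unused_range

    def add(pid, pep, contribution, modified, unused):
        rows.append({
            "protein_id": pid, "peptide": pep, "length": len(pep),
            "contribution": round(float(contribution), 4),
            "modified": bool(modified), "unused": round(float(unused), 2),
        })

    for pid in true_proteins:
        seq = fam[pid]
        unused = rng.uniform(lo_u, hi_u)
        peps = [p for p, _, _ in digest(seq)]
        usable = [p for p in peps if 6 <= len(p) <= 20] or peps
        for pep in usable:
            add(pid, pep, noise.contribution_shift + rng.exponential(noise.contribution_scale),
                False, unused)
        # defect rows exercising each filter
        pick = lambda: usable[int(rng.integers(len(usable)))]
        add(pid, pick(), noise.contribution_shift + rng.exponential(noise.contribution_scale),
            False, unused)  # duplicate peptide string
        add(pid, pick(), noise.contribution_shift + rng.exponential(noise.contribution_scale),
            True, unused)  # modified
        add(pid, seq[:5], noise.contribution_shift + rng.exponential(noise.contribution_scale),
            False, unused)  # too short
        add(pid, seq[:21], noise.contribution_shift + rng.exponential(noise.contribution_scale),
            False, unused)  # too long
        add(pid, pick(), min(2.0, rng.exponential(noise.decoy_scale)), False, unused)  # low score

    decoys = [p for p in fam if p not in set(true_proteins)]
    if decoys:
        pid = sorted(decoys)[0]
        peps = [p for p, _, _ in digest(fam[pid]) if 6 <= len(p) <= 20]
        for pep in peps[:3] or [fam[pid][:10]]:
            add(pid, pep, noise.contribution_shift + rng.exponential(noise.contribution_scale),
                False, noise.decoy_unused)

    table = pd.DataFrame(rows)
    return table.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)


def make_bioassay(
    design: BioassayDesign = BioassayDesign(),
    seed: int = 0,
    species: str = "S. exigua",
    treatment: str = "synthetic",
) -> BioassayDataset:
    """Draw binomial mortality from the probit truth model.

    For each dose d, dead ~ Binomial(n, c + (1-c) * Phi(slope*(log10 d -
    log10 LC50))) with c the control mortality; doses form a geometric
    series bracketing the LC50.
    """
    from scipy.stats import norm

    rng = _rng(seed, "bioassay")
    c = design.control_mortality
    records = []
    for dose in design.doses():
        p_model = float(norm.cdf(design.slope * (np.log10(dose) - np.log10(design.lc50))))
        p_obs = c + (1.0 - c) * p_model
        dead = int(rng.binomial(design.larvae_per_dose, p_obs))
        records.append(DoseGroup(float(dose), design.larvae_per_dose, dead))
    control = (design.larvae_per_dose, int(rng.binomial(design.larvae_per_dose, c)))
    return BioassayDataset(records=records, species=species, treatment=treatment,
                           control=control)


# High-molecular-weight calibration-kit standards (kDa).
HMW_STANDARDS = {
    "thyroglobulin": 669.0,
    "ferritin": 440.0,
    "aldolase": 158.0,
    "conalbumin": 75.0,
    "ovalbumin": 44.0,
}


def make_calibration(
    standard_masses: Mapping[str, float] = None,
    v0: float = 9.0,
    vc: float = 24.0,
    line: tuple[float, float] = (-0.36, 1.14),
    noise_sd: float = 0.0,
    seed: int = 0,
    query_mass: float = 346.0,
    on_out_of_range: str = "resample",
) -> tuple[pd.DataFrame, float]:
    """Generate a gel-filtration calibration table plus one query peak.

    Elution volumes follow Ve = V0 + (Vc - V0) * (slope*log10(M) +
    intercept) with Gaussian noise of ``noise_sd`` ml; volumes falling
    outside [V0, Vc] are resampled (or raise, per ``on_out_of_range``).
    Returns (table with columns standard / mass_kda / ve_ml, noiseless query
    elution volume for ``query_mass``).
    """
    if standard_masses is None:
        standard_masses = HMW_STANDARDS
    if v0 >= vc:
        raise ValueError("V0 must be smaller than Vc")
    masses = list(standard_masses.values())
    if len(set(masses)) != len(masses) or any(m <= 0 for m in masses):
        raise ValueError("standard masses must be positive and distinct")
    slope, intercept = line
    rng = _rng(seed, "calibration")

    def ve_of(mass: float, noisy: bool) -> float:
        base = v0 + (vc - v0) * (slope * np.log10(mass) + intercept)
        if not noisy or noise_sd == 0:
            if not v0 <= base <= vc:
                raise ValueError(f"noiseless Ve {base:.2f} ml outside [{v0}, {vc}]")
            return float(base)
        for _ in range(100):
            ve = base + rng.normal(0.0, noise_sd)
            if v0 <= ve <= vc:
                return float(ve)
            if on_out_of_range == "error":
                raise ValueError(f"generated Ve {ve:.2f} ml outside [{v0}, {vc}]")
        raise RuntimeError("could not draw an in-range elution volume")

    rows = [
        {"standard": name, "mass_kda": float(mass), "ve_ml": ve_of(mass, True)}
        for name, mass in standard_masses.items()
    ]
    query_ve = ve_of(query_mass, False)
    return pd.DataFrame(rows, columns=["standard", "mass_kda", "ve_ml"]), query_ve


_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"], "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"], "F": ["TTT", "TTC"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"], "W": ["TGG"], "Y": ["TAT", "TAC"],
}


def make_orf(protein_length: int = 789, seed: int = 0) -> tuple[str, str]:
    """Random stop-terminated ORF: 3*(protein_length+1) bp starting with ATG.

    Returns (dna, protein); the protein starts with M and contains no
    internal stops by construction.
    """
    if protein_length < 1:
        raise ValueError("protein_length must be >= 1")
    rng = _rng(seed, "orf")
    protein = "M" + "".join(
        rng.choice(list(AMINO_ACIDS)) for _ in range(protein_length - 1)
    )
    dna = "".join(str(rng.choice(_CODONS[res])) for res in protein) + "TAA"
    return dna, protein


def family_to_fasta(family: Mapping[str, str], path) -> None:
    """Write a protein family (or any id -> sequence mapping) as FASTA."""
    with open(path, "w") as fh:
        for mid, seq in family.items():
            fh.write(f">{mid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


genomes_to_fasta = family_to_fasta
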