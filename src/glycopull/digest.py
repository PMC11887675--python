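"""Chymotryptic in-silico digestion and peptide / glycopeptide masses.

Digestion follows the high-specificity chymotrypsin rule: cleavage
C-terminal to F, W, Y or L, suppressed when the next residue is proline.
Peptides are generated for 0..max_missed internal (uncleaved) sites and
filtered to a length window.  Coordinates are 0-based half-open on the
parent sequence.

Masses are neutral monoisotopic.  Cysteines are assumed fully
carbamidomethylated (+57.021 Da fixed modification, from iodoacetamide
alkylation); methionine oxidation (+15.995 Da) is a variable
modification counted per peptide.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mass as _pmass

from .glycan import Attachment, GlycanComposition, composition_delta_mass

__all__ = [
    "CARBAMIDOMETHYL_MASS",
    "OXIDATION_MASS",
    "PROTON_MASS",
    "WATER_MASS",
    "Peptide",
    "ProteinRecord",
    "chymotryptic_digest",
    "cleavage_sites",
    "glycopeptide_mass",
    "mass_from_mz",
    "mz_from_mass",
    "peptide_monoisotopic_mass",
    "read_fasta",
    "write_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

WATER_MASS = 18.010565  # Da, monoisotopic H2O
PROTON_MASS = 1.007276  # Da
CARBAMIDOMETHYL_MASS = 57.02146  # Da, fixed on Cys
OXIDATION_MASS = 15.99491  # Da, variable on Met

#: Chymotrypsin high-specificity cleavage residues (C-terminal side).
CHYMOTRYPSIN_SITES = "FWYL"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20 standard amino-acid letters."""

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValueError(
                f"{self.accession}: non-standard residue(s) {sorted(bad)!r} "
                "(sequence must be uppercase over the 20 standard letters)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Peptide:
    """A proteolytic peptide located on its parent protein.

    ``n_oxidized_met`` counts oxidized methionines (a variable
    modification); carbamidomethylation of every cysteine is implied by
    the sequence and not stored.
    """

    parent: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int = 0
    n_oxidized_met: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad peptide coordinates [{self.start}, {self.end})")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length disagrees with coordinates")
        if self.n_oxidized_met > self.sequence.count("M"):
            raise ValueError("more oxidized Met than Met residues in sequence")

    def __len__(self) -> int:
        return len(self.sequence)


def cleavage_sites(
    sequence: str,
    sites: str = CHYMOTRYPSIN_SITES,
    *,
    restrict_proline: bool = True,
) -> list[int]:
    """Positions (0-based, between residues i and i+1) where the protease cuts.

    A residue in *sites* at the C-terminus of the protein is not a
    cleavage position (there is nothing to cut off).
    """
    cuts = []
    for i in range(len(sequence) - 1):
        if sequence[i] in sites and not (restrict_proline and sequence[i + 1] == "P"):
            cuts.append(i + 1)
    return cuts


def chymotryptic_digest(
    protein: ProteinRecord,
    max_missed: int = 2,
    min_len: int = 5,
    max_len: int = 60,
    *,
    sites: str = CHYMOTRYPSIN_SITES,
    restrict_proline: bool = True,
) -> list[Peptide]:
    """All peptides with up to *max_missed* missed cleavages, length-filtered.

    Deterministic order: by start position, then end position.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = protein.sequence
    cuts = cleavage_sites(seq, sites, restrict_proline=restrict_proline)
    boundaries = [0] + cuts + [len(seq)]
    peptides = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(boundaries))):
            start, end = boundaries[i], boundaries[j]
            if min_len <= end - start <= max_len:
                peptides.append(
                    Peptide(
                        parent=protein.accession,
                        start=start,
                        end=end,
                        sequence=seq[start:end],
                        missed_cleavages=j - i - 1,
                    )
                )
    return peptides


def peptide_monoisotopic_mass(p: Peptide | str, n_oxidized_met: int | None = None) -> float:
    """Neutral monoisotopic mass with fixed Cys and variable Met-ox mods.

    Residue masses come from the standard monoisotopic amino-acid table;
    water for the termini; +57.02146 Da per cysteine (carbamidomethyl,
    fixed); +15.99491 Da per oxidized methionine.
    """
    if isinstance(p, Peptide):
        seq, n_ox = p.sequence, p.n_oxidized_met
    else:
        seq, n_ox = p, n_oxidized_met or 0
    base = sum(_pmass.std_aa_mass[aa] for aa in seq) + WATER_MASS
    return base + CARBAMIDOMETHYL_MASS * seq.count("C") + OXIDATION_MASS * n_ox


def glycopeptide_mass(p: Peptide | str, comp: GlycanComposition) -> float:
    """Neutral mass of a peptide carrying one glycan of composition *comp*.

    N-linked glycans require at least one asparagine in the peptide;
    O-linked glycans at least one serine or threonine.  (A single glycan
    per peptide; the composition is attached as one delta mass.)
    """
    seq = p.sequence if isinstance(p, Peptide) else p
    if comp.attachment == Attachment.N_LINKED and "N" not in seq:
        raise ValueError(
            f"N-linked glycan requires an asparagine; peptide {seq!r} has none"
        )
    if comp.attachment == Attachment.O_LINKED and not set(seq) & {"S", "T"}:
        raise ValueError(
            f"O-linked glycan requires a serine or threonine; peptide {seq!r} has neither"
        )
    return peptide_monoisotopic_mass(p) + composition_delta_mass(comp)


def mz_from_mass(neutral_mass: float, charge: int) -> float:
    """m/z of a [M + zH]^z+ ion."""
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def mass_from_mz(mz: float, charge: int) -> float:
    """Neutral mass from observed m/z and charge (inverse of mz_from_mass)."""
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return mz * charge - charge * PROTON_MASS


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA; the accession is the first whitespace token."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(
                accession=rec.id,
                sequence=str(rec.seq).upper(),
                description=rec.description,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description or "")
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")
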