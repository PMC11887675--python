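"""Simplified glycopeptide precursor search.

This is a transparent stand-in for a commercial search engine: an index
of (peptide x glycan x Met-oxidation state) candidates sorted by
theoretical neutral mass, precursor matching at a ppm tolerance via
binary search, and a plain counting score over singly charged b/y
backbone ions (the glycan treated as fully lost in fragmentation).
Matches are tiered into high/low confidence by backbone-ion count.

It deliberately does not model fragment-level probabilistic scoring,
FDR estimation or glycan site localization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

from .digest import (
    CARBAMIDOMETHYL_MASS,
    OXIDATION_MASS,
    PROTON_MASS,
    WATER_MASS,
    Peptide,
    ProteinRecord,
    chymotryptic_digest,
    glycopeptide_mass,
    mass_from_mz,
)
from .glycan import (
    Attachment,
    DEFAULT_GLYCAN_PANEL,
    GlycanComposition,
    format_composition,
    parse_composition,
)
from .spectra import (
    Ms2Spectrum,
    ToleranceSettings,
    passes_sle_oxonium_filter,
    ppm_error,
)

__all__ = [
    "Candidate",
    "CandidateIndex",
    "GlycopeptideMatch",
    "SearchSettings",
    "assign_confidence",
    "build_index",
    "match_precursor",
    "read_matches_tsv",
    "score_backbone",
    "search_spectra",
    "write_matches_tsv",
]

logger = logging.getLogger(__name__)

MATCH_TSV_COLUMNS = [
    "spectrum_id",
    "accession",
    "peptide",
    "start",
    "end",
    "missed_cleavages",
    "n_oxidized_met",
    "glycan",
    "attachment",
    "theoretical_mass",
    "mass_error_ppm",
    "backbone_ion_count",
    "oxonium_pass",
    "confidence",
]


@dataclass(frozen=True)
class SearchSettings:
    """Everything the search depends on, in one validated record."""

    glycan_panel: tuple[GlycanComposition, ...] = DEFAULT_GLYCAN_PANEL
    tolerances: ToleranceSettings = ToleranceSettings()
    max_missed: int = 2
    min_len: int = 5
    max_len: int = 60
    allow_oxidized_met: bool = True
    high_confidence_ions: int = 6

    def __post_init__(self) -> None:
        if not self.glycan_panel:
            raise ValueError("glycan panel must be non-empty")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")
        if self.high_confidence_ions < 0:
            raise ValueError("high_confidence_ions must be >= 0")


@dataclass(frozen=True)
class Candidate:
    """A theoretical glycopeptide: peptide + glycan + Met-ox state."""

    peptide: Peptide
    glycan: GlycanComposition
    neutral_mass: float


@dataclass(frozen=True)
class GlycopeptideMatch:
    """A spectrum-to-candidate assignment with its quality evidence."""

    spectrum_id: str
    peptide: Peptide
    glycan: GlycanComposition
    theoretical_mass: float
    mass_error_ppm: float
    backbone_ion_count: int = 0
    oxonium_pass: bool = False
    confidence: str = "low"


class CandidateIndex:
    """Candidates sorted by theoretical neutral mass, for binary search."""

    def __init__(self, candidates: Sequence[Candidate], settings: SearchSettings):
        ordered = sorted(
            candidates,
            key=lambda c: (c.neutral_mass, c.peptide.parent, c.peptide.start, c.peptide.end),
        )
        self.candidates: tuple[Candidate, ...] = tuple(ordered)
        self.masses = np.array([c.neutral_mass for c in ordered], dtype=float)
        self.settings = settings

    def __len__(self) -> int:
        return len(self.candidates)

    def window(self, lo: float, hi: float) -> Sequence[Candidate]:
        i = int(np.searchsorted(self.masses, lo, side="left"))
        j = int(np.searchsorted(self.masses, hi, side="right"))
        return self.candidates[i:j]


def build_index(proteins: Sequence[ProteinRecord], settings: SearchSettings) -> CandidateIndex:
    """Enumerate every admissible (peptide, glycan, Met-ox) candidate once.

    Attachment constraints are enforced: N-linked glycans only on peptides
    containing N, O-linked only on peptides containing S or T; unspecified
    glycans are allowed on any peptide.  With ``allow_oxidized_met`` every
    oxidation count 0..#Met is enumerated.
    """
    if not proteins:
        raise ValueError("empty proteome: at least one protein record is required")
    candidates: list[Candidate] = []
    for protein in proteins:
        for pep in chymotryptic_digest(
            protein, settings.max_missed, settings.min_len, settings.max_len
        ):
            max_ox = pep.sequence.count("M") if settings.allow_oxidized_met else 0
            for n_ox in range(max_ox + 1):
                modified = replace(pep, n_oxidized_met=n_ox)
                for glycan in settings.glycan_panel:
                    try:
                        neutral = glycopeptide_mass(modified, glycan)
                    except ValueError:
                        continue  # attachment residue absent
                    candidates.append(Candidate(modified, glycan, neutral))
    return CandidateIndex(candidates, settings)


def _match_sort_key(m: GlycopeptideMatch):
    return (
        abs(m.mass_error_ppm),
        -m.backbone_ion_count,
        m.peptide.parent,
        m.peptide.start,
        m.peptide.end,
        format_composition(m.glycan),
    )


def match_precursor(
    s: Ms2Spectrum, index: CandidateIndex, settings: SearchSettings | None = None
) -> list[GlycopeptideMatch]:
    """All candidates whose theoretical mass matches the spectrum's neutral
    precursor mass within the ppm tolerance; sorted by |ppm| ascending."""
    settings = settings or index.settings
    tol_ppm = settings.tolerances.precursor_ppm
    observed = mass_from_mz(s.precursor_mz, s.precursor_charge)
    half_width = observed * tol_ppm * 1e-6
    matches = [
        GlycopeptideMatch(
            spectrum_id=s.spectrum_id,
            peptide=c.peptide,
            glycan=c.glycan,
            theoretical_mass=c.neutral_mass,
            mass_error_ppm=ppm_error(observed, c.neutral_mass),
        )
        for c in index.window(observed - half_width, observed + half_width)
        if abs(ppm_error(observed, c.neutral_mass)) <= tol_ppm
    ]
    matches.sort(key=_match_sort_key)
    return matches


def backbone_ion_mz(p: Peptide | str, n_oxidized_met: int | None = None) -> list[float]:
    """Singly charged b- and y-ion m/z of the peptide backbone.

    The glycan is treated as entirely lost in HCD fragmentation, so
    backbone ions carry no glycan mass.  Fixed carbamidomethyl-Cys is
    applied per residue; oxidation mass is placed on the first
    ``n_oxidized_met`` methionines (position-agnostic counting, so this
    choice only affects which ions shift, not how many there are).
    """
    if isinstance(p, Peptide):
        seq, n_ox = p.sequence, p.n_oxidized_met
    else:
        seq, n_ox = p, n_oxidized_met or 0
    residue_masses = []
    ox_left = n_ox
    for aa in seq:
        m = _pmass.std_aa_mass[aa]
        if aa == "C":
            m += CARBAMIDOMETHYL_MASS
        if aa == "M" and ox_left > 0:
            m += OXIDATION_MASS
            ox_left -= 1
        residue_masses.append(m)
    ions = []
    prefix = 0.0
    for m in residue_masses[:-1]:
        prefix += m
        ions.append(prefix + PROTON_MASS)  # b ion
    suffix = 0.0
    for m in reversed(residue_masses[1:]):
        suffix += m
        ions.append(suffix + WATER_MASS + PROTON_MASS)  # y ion
    return ions


def score_backbone(
    s: Ms2Spectrum, p: Peptide | str, tol: ToleranceSettings = ToleranceSettings()
) -> int:
    """Count theoretical singly charged b/y ions with a peak within the
    product-ion tolerance.  Intensity plays no role."""
    if not s.peaks:
        return 0
    mz = s.mz_array
    count = 0
    for ion in backbone_ion_mz(p):
        i = int(np.searchsorted(mz, ion))
        nearest = min(
            (abs(mz[j] - ion) for j in (i - 1, i) if 0 <= j < len(mz)), default=np.inf
        )
        if nearest <= tol.product_da:
            count += 1
    return count


def assign_confidence(m: GlycopeptideMatch, settings: SearchSettings) -> str:
    """``high`` iff the backbone-ion count reaches the threshold (inclusive)
    and the precursor error is within tolerance; otherwise ``low``."""
    within = abs(m.mass_error_ppm) <= settings.tolerances.precursor_ppm
    if within and m.backbone_ion_count >= settings.high_confidence_ions:
        return "high"
    return "low"


def search_spectra(
    spectra: Iterable[Ms2Spectrum],
    index: CandidateIndex,
    settings: SearchSettings | None = None,
    *,
    keep_all: bool = False,
) -> list[GlycopeptideMatch]:
    """Full search: precursor match, backbone scoring, oxonium validation
    and confidence tiering for every spectrum.

    By default only the best-ranked candidate per spectrum is kept
    (rank order: |ppm| ascending, backbone count descending, accession);
    ``keep_all`` retains every in-tolerance candidate.
    """
    settings = settings or index.settings
    results: list[GlycopeptideMatch] = []
    for s in spectra:
        candidates = match_precursor(s, index, settings)
        if not candidates:
            continue
        oxonium = passes_sle_oxonium_filter(s, settings.tolerances)
        scored = []
        for m in candidates:
            m = replace(
                m,
                backbone_ion_count=score_backbone(s, m.peptide, settings.tolerances),
                oxonium_pass=oxonium,
            )
            m = replace(m, confidence=assign_confidence(m, settings))
            scored.append(m)
        scored.sort(key=_match_sort_key)
        results.extend(scored if keep_all else scored[:1])
    return results


def _match_to_row(m: GlycopeptideMatch) -> dict:
    return {
        "spectrum_id": m.spectrum_id,
        "accession": m.peptide.parent,
        "peptide": m.peptide.sequence,
        "start": m.peptide.start,
        "end": m.peptide.end,
        "missed_cleavages": m.peptide.missed_cleavages,
        "n_oxidized_met": m.peptide.n_oxidized_met,
        "glycan": format_composition(m.glycan),
        "attachment": m.glycan.attachment.value,
        "theoretical_mass": round(m.theoretical_mass, 6),
        "mass_error_ppm": round(m.mass_error_ppm, 4),
        "backbone_ion_count": m.backbone_ion_count,
        "oxonium_pass": m.oxonium_pass,
        "confidence": m.confidence,
    }


def write_matches_tsv(matches: Sequence[GlycopeptideMatch], path: str | Path) -> None:
    df = pd.DataFrame([_match_to_row(m) for m in matches], columns=MATCH_TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_matches_tsv(path: str | Path) -> list[GlycopeptideMatch]:
    df = pd.read_csv(path, sep="\t")
    matches = []
    for row in df.itertuples(index=False):
        peptide = Peptide(
            parent=row.accession,
            start=int(row.start),
            end=int(row.end),
            sequence=row.peptide,
            missed_cleavages=int(row.missed_cleavages),
            n_oxidized_met=int(row.n_oxidized_met),
        )
        glycan = parse_composition(row.glycan, Attachment(row.attachment))
        matches.append(
            GlycopeptideMatch(
                spectrum_id=row.spectrum_id,
                peptide=peptide,
                glycan=glycan,
                theoretical_mass=float(row.theoretical_mass),
                mass_error_ppm=float(row.mass_error_ppm),
                backbone_ion_count=int(row.backbone_ion_count),
                oxonium_pass=bool(row.oxonium_pass),
                confidence=row.confidence,
            )
        )
    return matches
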