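"""Ground-truth-bearing synthetic data for every pipeline stage.

The generator emulates the structure of a lectin affinity-pulldown
glycoproteomics experiment: a small proteome, MS/MS runs labelled
pulldown / IgG control / no-Ca2+ control, spectra of chymotryptic
glycopeptides carrying panel glycans, and an annotation table with a
planted dominant target.  Everything is driven by a single seeded
pseudo-random stream, so identical seeds give byte-identical fixtures.

Spectrum classes:

* **true** — planted glycopeptide of a target-pool protein in a pulldown
  run: precursor at the exact glycopeptide m/z (plus optional bounded
  jitter), the full singly charged b/y backbone series, and one marker
  ion from each of the three oxonium classes;
* **decoy** — constructed negatives in pulldown runs, either offset
  (precursor >10 ppm from every candidate) or unvalidated (precursor on
  a decoy-pool candidate but with a sparse backbone and a missing
  oxonium class, so it can only yield a low-confidence, non-validated
  match);
* **contaminant** — true-like spectra of background-pool proteins in
  control runs; a subset of contaminant proteins also appears in a
  pulldown run, exercising the differential subtraction.

Intensity model (documented constants): base peak 1.0 at the
glycan-loss [peptide+H]+ ion, backbone ions 0.1-0.5, oxonium ions
0.2-0.8, noise peaks <= 0.05.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .curation import RunManifest, write_manifest
from .digest import (
    AMINO_ACIDS,
    PROTON_MASS,
    Peptide,
    ProteinRecord,
    chymotryptic_digest,
    cleavage_sites,
    glycopeptide_mass,
    mz_from_mass,
    peptide_monoisotopic_mass,
    write_fasta,
)
from .glycan import (
    Attachment,
    DEFAULT_GLYCAN_PANEL,
    GlycanComposition,
    format_composition,
    write_glycan_panel,
)
from .match import SearchSettings, backbone_ion_mz, build_index
from .spectra import Ms2Spectrum, write_mgf
from .target_score import (
    ORGAN_VOCABULARY,
    ProteinAnnotation,
    write_annotations,
)

__all__ = [
    "DEFAULT_MANIFEST",
    "FixturePaths",
    "GroundTruth",
    "PlantedGlycopeptide",
    "generate_annotations",
    "generate_proteome",
    "make_fixture",
    "plant_and_synthesize",
]

#: Default run layout: two pulldown replicates and both negative controls.
DEFAULT_MANIFEST = RunManifest(
    {
        "eselectin_1": "eselectin_pulldown",
        "eselectin_2": "eselectin_pulldown",
        "igg_1": "igg_control",
        "noca_1": "no_calcium_control",
    }
)

# Planted peptides are kept reasonably long so that identical (or
# Leu/Ile-isobaric) peptides arising by chance in two different random
# proteins are vanishingly unlikely.
_PLANT_MIN_LEN = 7
_PLANT_MAX_LEN = 25

_OXONIUM_PRIMARY = {
    "hexnac_class": 204.0867,
    "neuac_class": 292.1027,
    "hexnac_hex_class": 366.1395,
}


@dataclass(frozen=True)
class PlantedGlycopeptide:
    """One spectrum's ground truth: where it was planted and what it encodes."""

    spectrum_id: str
    run_id: str
    accession: str
    peptide: str
    glycan: str
    attachment: str
    kind: str  # true | contaminant | decoy_offset | decoy_unvalidated


@dataclass
class GroundTruth:
    """Bookkeeping of everything the generator planted."""

    seed: int
    planted: list[PlantedGlycopeptide] = field(default_factory=list)
    contaminant_accessions: list[str] = field(default_factory=list)
    decoy_accessions: list[str] = field(default_factory=list)
    planted_top_target: str | None = None

    @property
    def true_accessions(self) -> set[str]:
        return {p.accession for p in self.planted if p.kind == "true"}

    def expected_linkage_partition(self) -> dict[str, int]:
        """The O/N/both Venn counts implied by the planted true spectra."""
        o_set = {
            p.accession for p in self.planted if p.kind == "true" and p.attachment == "O"
        }
        n_set = {
            p.accession for p in self.planted if p.kind == "true" and p.attachment == "N"
        }
        both = o_set & n_set
        return {
            "o_total": len(o_set),
            "n_total": len(n_set),
            "both": len(both),
            "union": len(o_set | n_set),
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "planted": [asdict(p) for p in self.planted],
            "contaminant_accessions": self.contaminant_accessions,
            "decoy_accessions": self.decoy_accessions,
            "planted_top_target": self.planted_top_target,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def generate_proteome(
    n_proteins: int = 40,
    length_range: tuple[int, int] = (80, 200),
    seed: int = 0,
) -> list[ProteinRecord]:
    """Random proteins over the 20-letter alphabet, each guaranteed to
    contain >= 1 internal chymotryptic site, >= 1 Asn and >= 1 Ser/Thr
    (so both linkage types are plantable).  Deterministic in *seed*."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = length_range
    if lo < 8 or hi < lo:
        raise ValueError(
            f"length_range {length_range} too small: need >= 8 residues to "
            "guarantee a cleavage site plus both attachment residues"
        )
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(AMINO_ACIDS))
    records = []
    for i in range(n_proteins):
        while True:
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(alphabet, size=length))
            if not cleavage_sites(seq):
                continue
            if "N" not in seq or not set(seq) & {"S", "T"}:
                continue
            break
        records.append(
            ProteinRecord(accession=f"SYN{i:04d}", sequence=seq, description=f"seed={seed}")
        )
    return records


def _plantable_peptides(
    protein: ProteinRecord, attachment: Attachment
) -> list[Peptide]:
    required = {"N"} if attachment == Attachment.N_LINKED else {"S", "T"}
    return [
        p
        for p in chymotryptic_digest(protein, max_missed=2, min_len=_PLANT_MIN_LEN,
                                     max_len=_PLANT_MAX_LEN)
        if set(p.sequence) & required
    ]


def _synthesize_spectrum(
    spectrum_id: str,
    peptide: Peptide,
    glycan: GlycanComposition,
    rng: np.random.Generator,
    *,
    noise: float = 0.0,
    charge: int | None = None,
    jitter_ppm_bound: float = 5.0,
    drop_oxonium: Sequence[str] = (),
    backbone_fraction: float = 1.0,
    offset_ppm: float = 0.0,
) -> Ms2Spectrum:
    """Build one spectrum around a glycopeptide candidate.

    *noise* in [0, 1] scales both the number of random peaks (up to 40)
    and the precursor m/z jitter (up to *jitter_ppm_bound* ppm, half the
    default precursor tolerance).  *offset_ppm* shifts the precursor
    deliberately (used for off-mass decoys).
    """
    charge = charge if charge is not None else int(rng.integers(2, 4))
    neutral = glycopeptide_mass(peptide, glycan)
    jitter = noise * jitter_ppm_bound * rng.uniform(-1.0, 1.0)
    mz = mz_from_mass(neutral * (1.0 + (offset_ppm + jitter) * 1e-6), charge)
    peaks: list[tuple[float, float]] = []
    # glycan-loss peptide ion as the base peak
    peaks.append((peptide_monoisotopic_mass(peptide) + PROTON_MASS, 1.0))
    ions = backbone_ion_mz(peptide)
    if backbone_fraction < 1.0:
        # Sparse backbone for unvalidated decoys.  Because several
        # theoretical b/y ions of one peptide can sit within the product
        # tolerance of a single peak, peaks are admitted under a budget on
        # the number of *matched theoretical ions*, so the decoy stays
        # unambiguously below any sensible high-confidence threshold.
        budget = 2
        matched: set[int] = set()
        kept: list[float] = []
        for ion in rng.permutation(ions):
            hits = {j for j, ref in enumerate(ions) if abs(ref - ion) <= 0.02}
            if len(matched | hits) <= budget:
                kept.append(float(ion))
                matched |= hits
            if len(matched) >= budget:
                break
        ions = kept
    for ion in ions:
        peaks.append((float(ion), float(rng.uniform(0.1, 0.5))))
    all_ions = backbone_ion_mz(peptide)
    for cls, ref in _OXONIUM_PRIMARY.items():
        if cls in drop_oxonium:
            continue
        if backbone_fraction < 1.0 and any(abs(ref - ion) <= 0.02 for ion in all_ions):
            continue  # would count as a backbone ion; keep the decoy sparse
        peaks.append((ref, float(rng.uniform(0.2, 0.8))))
    for _ in range(int(round(noise * 40))):
        peaks.append((float(rng.uniform(150.0, 2000.0)), float(rng.uniform(0.0, 0.05))))
    return Ms2Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=mz,
        precursor_charge=charge,
        peaks=tuple(peaks),
    )


def plant_and_synthesize(
    proteome: Sequence[ProteinRecord],
    glycan_panel: Sequence[GlycanComposition] = DEFAULT_GLYCAN_PANEL,
    n_true: int = 20,
    n_decoy: int = 10,
    manifest: RunManifest = DEFAULT_MANIFEST,
    noise: float = 0.0,
    seed: int = 0,
    *,
    n_contaminants: int | None = None,
) -> tuple[dict[str, list[Ms2Spectrum]], GroundTruth]:
    """Plant glycopeptide spectra across runs and return them per run.

    The proteome is split deterministically into a target pool (true
    spectra), a decoy pool (unvalidated decoys) and a background pool
    (contaminants); the pools are disjoint, so ground-truth labels are
    unambiguous.  Half of the contaminant proteins also receive one
    spectrum in a pulldown run — the differential filter must remove
    them regardless.
    """
    if not glycan_panel:
        raise ValueError("glycan panel must be non-empty")
    if n_true < 0 or n_decoy < 0:
        raise ValueError("n_true and n_decoy must be >= 0")
    rng = np.random.default_rng(seed)
    pulldown_runs = sorted(manifest.pulldown_runs)
    control_runs = sorted(manifest.control_runs)
    if not control_runs:
        raise ValueError("manifest must contain at least one control run for planting")

    accs = [p.accession for p in proteome]
    n = len(accs)
    n_target = max(1, int(0.5 * n))
    n_decoy_pool = max(1, int(0.25 * n))
    target_pool = list(proteome[:n_target])
    decoy_pool = list(proteome[n_target : n_target + n_decoy_pool])
    background_pool = list(proteome[n_target + n_decoy_pool :])
    if n_contaminants is None:
        n_contaminants = min(6, len(background_pool))
    if n_contaminants > len(background_pool):
        raise ValueError(
            f"n_contaminants={n_contaminants} exceeds background pool "
            f"({len(background_pool)} proteins)"
        )

    typed_panel = [g for g in glycan_panel if g.attachment != Attachment.UNSPECIFIED]
    if not typed_panel:
        raise ValueError("panel must contain at least one N- or O-linked composition")

    truth = GroundTruth(seed=seed)
    spectra_by_run: dict[str, list[Ms2Spectrum]] = {run: [] for run in manifest.runs}
    counter = 0

    # Index over the whole proteome at the default search settings, used to
    # certify that each planted glycopeptide is *unambiguous*: every
    # candidate within the widest reachable precursor window (tolerance
    # plus maximal jitter) belongs to the planted protein.  This keeps
    # ground-truth labels exact at every noise level.
    index = build_index(list(proteome), SearchSettings(glycan_panel=tuple(typed_panel)))
    # 10 ppm search tolerance + 5 ppm jitter bound, rounded up; off-mass
    # decoys reach further (25 ppm offset + tolerance + jitter)
    _AMBIGUITY_PPM = 16.0
    _OFFSET_AMBIGUITY_PPM = 41.0

    def _unambiguous(accession: str, neutral: float, window_ppm: float) -> bool:
        half = neutral * window_ppm * 1e-6
        return all(
            c.peptide.parent == accession
            for c in index.window(neutral - half, neutral + half)
        )

    def _pick_plantable(pool: Sequence[ProteinRecord], *, window_ppm: float = _AMBIGUITY_PPM):
        """A random (protein, peptide, glycan) triple with a compatible
        attachment site whose mass neighbourhood (within *window_ppm*)
        contains no other protein's candidates."""
        for _ in range(500):
            protein = pool[int(rng.integers(len(pool)))]
            glycan = typed_panel[int(rng.integers(len(typed_panel)))]
            options = _plantable_peptides(protein, glycan.attachment)
            if not options:
                continue
            peptide = options[int(rng.integers(len(options)))]
            if not _unambiguous(
                protein.accession, glycopeptide_mass(peptide, glycan), window_ppm
            ):
                continue
            return protein, peptide, glycan
        raise ValueError("could not find a plantable peptide; proteome too constrained")

    # --- true spectra in pulldown runs -------------------------------------
    for _ in range(n_true):
        protein, peptide, glycan = _pick_plantable(target_pool)
        run = pulldown_runs[int(rng.integers(len(pulldown_runs)))]
        sid = f"{run}:scan={counter:05d}"
        counter += 1
        spectra_by_run[run].append(
            _synthesize_spectrum(sid, peptide, glycan, rng, noise=noise)
        )
        truth.planted.append(
            PlantedGlycopeptide(
                sid, run, protein.accession, peptide.sequence,
                format_composition(glycan), glycan.attachment.value, "true",
            )
        )

    # --- contaminants in control runs (half also bleed into a pulldown) ----
    contaminants = background_pool[:n_contaminants]
    truth.contaminant_accessions = [p.accession for p in contaminants]
    for i, protein in enumerate(contaminants):
        try:
            _, peptide, glycan = _pick_plantable([protein])
        except ValueError:
            continue  # no unambiguous peptide; this protein is simply absent
        runs = [control_runs[int(rng.integers(len(control_runs)))]]
        if i % 2 == 0:
            runs.append(pulldown_runs[int(rng.integers(len(pulldown_runs)))])
        for run in runs:
            sid = f"{run}:scan={counter:05d}"
            counter += 1
            spectra_by_run[run].append(
                _synthesize_spectrum(sid, peptide, glycan, rng, noise=noise)
            )
            truth.planted.append(
                PlantedGlycopeptide(
                    sid, run, protein.accession, peptide.sequence,
                    format_composition(glycan), glycan.attachment.value, "contaminant",
                )
            )

    # --- decoys in pulldown runs -------------------------------------------
    truth.decoy_accessions = [p.accession for p in decoy_pool]
    oxonium_classes = list(_OXONIUM_PRIMARY)
    for k in range(n_decoy):
        protein, peptide, glycan = _pick_plantable(
            decoy_pool, window_ppm=_OFFSET_AMBIGUITY_PPM if k % 2 == 0 else _AMBIGUITY_PPM
        )
        run = pulldown_runs[int(rng.integers(len(pulldown_runs)))]
        sid = f"{run}:scan={counter:05d}"
        counter += 1
        if k % 2 == 0:
            # off-mass: precursor 25 ppm from the candidate, beyond tolerance;
            # an oxonium class is dropped too, so even an accidental match to
            # some other candidate cannot pass validation
            spectrum = _synthesize_spectrum(
                sid, peptide, glycan, rng, noise=noise,
                offset_ppm=float(rng.choice([-25.0, 25.0])),
                drop_oxonium=[oxonium_classes[int(rng.integers(len(oxonium_classes)))]],
            )
            kind = "decoy_offset"
        else:
            # unvalidated: on-mass but sparse backbone, one oxonium class missing
            spectrum = _synthesize_spectrum(
                sid, peptide, glycan, rng, noise=noise,
                drop_oxonium=[oxonium_classes[int(rng.integers(len(oxonium_classes)))]],
                backbone_fraction=0.15,
            )
            kind = "decoy_unvalidated"
        spectra_by_run[run].append(spectrum)
        truth.planted.append(
            PlantedGlycopeptide(
                sid, run, protein.accession, peptide.sequence,
                format_composition(glycan), glycan.attachment.value, kind,
            )
        )
    return spectra_by_run, truth


def generate_annotations(
    accessions: Sequence[str],
    planted_top: str,
    seed: int = 0,
) -> list[ProteinAnnotation]:
    """Annotation records with *planted_top* strictly dominant.

    The planted target gets the maximal reward fields (cancer 3, eight
    unfavorable-prognosis cancers, membrane-localized) and zero healthy
    expression, for a total of 12 at unit weights; every other protein
    draws cancer 0..2, prognosis 0..3, a fair membrane coin and uniform
    organ levels, bounding its total at 6.  Rank 1 is therefore
    guaranteed for any non-negative weights with w_cancer, w_prognosis
    or w_membrane positive.
    """
    if planted_top not in set(accessions):
        raise ValueError(f"planted_top {planted_top!r} not among the given accessions")
    rng = np.random.default_rng(seed)
    annotations = []
    for acc in accessions:
        if acc == planted_top:
            annotations.append(
                ProteinAnnotation(
                    accession=acc,
                    cancer_association=3,
                    n_unfavorable_prognosis=8,
                    membrane_localized=True,
                    healthy_expression={o: 0 for o in ORGAN_VOCABULARY},
                )
            )
        else:
            annotations.append(
                ProteinAnnotation(
                    accession=acc,
                    cancer_association=int(rng.integers(0, 3)),
                    n_unfavorable_prognosis=int(rng.integers(0, 4)),
                    membrane_localized=bool(rng.integers(0, 2)),
                    healthy_expression={
                        o: int(rng.integers(0, 4)) for o in ORGAN_VOCABULARY
                    },
                )
            )
    return annotations


@dataclass(frozen=True)
class FixturePaths:
    """Locations of a complete generated test bundle."""

    fasta: Path
    mgf_by_run: dict[str, Path]
    manifest: Path
    glycan_panel: Path
    annotations: Path
    ground_truth: Path


def make_fixture(
    outdir: str | Path,
    seed: int = 0,
    *,
    n_proteins: int = 40,
    length_range: tuple[int, int] = (80, 200),
    n_true: int = 20,
    n_decoy: int = 10,
    noise: float = 0.0,
    manifest: RunManifest = DEFAULT_MANIFEST,
    glycan_panel: Sequence[GlycanComposition] = DEFAULT_GLYCAN_PANEL,
) -> tuple[FixturePaths, GroundTruth]:
    """Write a complete pipeline input bundle (FASTA, per-run MGF, manifest,
    glycan panel, annotations, ground-truth JSON) under *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteome = generate_proteome(n_proteins, length_range, seed)
    spectra_by_run, truth = plant_and_synthesize(
        proteome, glycan_panel, n_true, n_decoy, manifest, noise, seed
    )
    # dominant target among the recovered (true) accessions
    planted_top = sorted(truth.true_accessions)[0] if truth.true_accessions else None
    truth.planted_top_target = planted_top

    fasta = outdir / "proteome.fasta"
    write_fasta(proteome, fasta)
    mgf_by_run = {}
    for run in sorted(manifest.runs):
        path = outdir / f"{run}.mgf"
        write_mgf(spectra_by_run[run], path)
        mgf_by_run[run] = path
    manifest_path = outdir / "manifest.tsv"
    write_manifest(manifest, manifest_path)
    panel_path = outdir / "glycan_panel.txt"
    write_glycan_panel(glycan_panel, panel_path)
    annotations_path = outdir / "annotations.tsv"
    if planted_top is not None:
        annotations = generate_annotations(
            sorted(truth.true_accessions), planted_top, seed
        )
        write_annotations(annotations, annotations_path)
    truth_path = outdir / "ground_truth.json"
    truth.to_json(truth_path)
    return (
        FixturePaths(fasta, mgf_by_run, manifest_path, panel_path,
                     annotations_path, truth_path),
        truth,
    )
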