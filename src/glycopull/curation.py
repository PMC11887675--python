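"""Final-list curation for differential affinity pulldowns.

The experiment compares lectin (E-selectin) pulldown runs against two
negative controls: an IgG isotype pulldown and a pulldown without
calcium (E-selectin binding is Ca2+-dependent, so the no-Ca2+ run
captures nonspecific binders).  Curation keeps only proteins detected
exclusively in the lectin pulldowns, then applies the confidence rule —
high-confidence identifications, or low-confidence ones backed by an
oxonium-validated glycopeptide spectrum — and finally partitions the
survivors by glycan linkage type (O, N, or both).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .glycan import Attachment
from .match import GlycopeptideMatch

__all__ = [
    "CONTROL_LABELS",
    "PULLDOWN_LABEL",
    "ProteinEvidence",
    "RunManifest",
    "aggregate_evidence",
    "differential_filter",
    "finalize_list",
    "linkage_partition",
    "read_manifest",
    "write_final_list",
]

logger = logging.getLogger(__name__)

PULLDOWN_LABEL = "eselectin_pulldown"
CONTROL_LABELS = frozenset({"igg_control", "no_calcium_control"})
RUN_LABELS = frozenset({PULLDOWN_LABEL}) | CONTROL_LABELS


@dataclass(frozen=True)
class RunManifest:
    """Mapping of run identifiers to their experimental label."""

    runs: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {label for label in self.runs.values() if label not in RUN_LABELS}
        if bad:
            raise ValueError(f"unknown run labels {sorted(bad)!r}; allowed: {sorted(RUN_LABELS)}")
        if not any(label == PULLDOWN_LABEL for label in self.runs.values()):
            raise ValueError("manifest must contain at least one E-selectin pulldown run")
        object.__setattr__(self, "runs", dict(self.runs))

    def label(self, run_id: str) -> str:
        return self.runs[run_id]

    def is_control(self, run_id: str) -> bool:
        return self.runs[run_id] in CONTROL_LABELS

    @property
    def pulldown_runs(self) -> frozenset[str]:
        return frozenset(r for r, l in self.runs.items() if l == PULLDOWN_LABEL)

    @property
    def control_runs(self) -> frozenset[str]:
        return frozenset(r for r, l in self.runs.items() if l in CONTROL_LABELS)


def read_manifest(path: str | Path) -> RunManifest:
    """Read a run manifest TSV with columns ``run_id`` and ``label``."""
    df = pd.read_csv(path, sep="\t")
    missing = {"run_id", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing column(s) {sorted(missing)}")
    return RunManifest(dict(zip(df["run_id"].astype(str), df["label"].astype(str))))


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    pd.DataFrame(
        sorted(manifest.runs.items()), columns=["run_id", "label"]
    ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ProteinEvidence:
    """Per-protein aggregation of glycopeptide matches across runs."""

    accession: str
    runs_observed: frozenset[str]
    matches: tuple[GlycopeptideMatch, ...]
    n_linked_evidence: bool
    o_linked_evidence: bool
    best_confidence: str
    any_oxonium_pass: bool

    def __post_init__(self) -> None:
        if not self.runs_observed:
            raise ValueError(f"{self.accession}: evidence with no runs observed")


def aggregate_evidence(
    matches: Sequence[GlycopeptideMatch],
    spectrum_runs: Mapping[str, str],
    manifest: RunManifest,
) -> list[ProteinEvidence]:
    """Group matches by protein accession; one evidence record each.

    *spectrum_runs* maps every spectrum id to its run id.  A match whose
    spectrum is not in the mapping, or whose run is not in the manifest,
    is an error (orphan spectrum).  Output is ordered by accession.
    """
    by_accession: dict[str, list[GlycopeptideMatch]] = {}
    for m in matches:
        run = spectrum_runs.get(m.spectrum_id)
        if run is None:
            raise ValueError(f"spectrum {m.spectrum_id!r} is not mapped to any run")
        if run not in manifest.runs:
            raise ValueError(f"spectrum {m.spectrum_id!r} maps to unknown run {run!r}")
        by_accession.setdefault(m.peptide.parent, []).append(m)
    evidence = []
    for accession in sorted(by_accession):
        group = by_accession[accession]
        evidence.append(
            ProteinEvidence(
                accession=accession,
                runs_observed=frozenset(spectrum_runs[m.spectrum_id] for m in group),
                matches=tuple(group),
                n_linked_evidence=any(
                    m.glycan.attachment == Attachment.N_LINKED for m in group
                ),
                o_linked_evidence=any(
                    m.glycan.attachment == Attachment.O_LINKED for m in group
                ),
                best_confidence="high" if any(m.confidence == "high" for m in group) else "low",
                any_oxonium_pass=any(m.oxonium_pass for m in group),
            )
        )
    return evidence


def differential_filter(
    evidence: Sequence[ProteinEvidence], manifest: RunManifest
) -> list[ProteinEvidence]:
    """Keep proteins detected in >= 1 pulldown run and in zero control runs.

    Proteins observed only in controls are silently dropped (debug log),
    not errors: they are the expected nonspecific background.
    """
    kept = []
    for ev in evidence:
        in_pulldown = bool(ev.runs_observed & manifest.pulldown_runs)
        in_control = bool(ev.runs_observed & manifest.control_runs)
        if in_pulldown and not in_control:
            kept.append(ev)
        elif in_control:
            logger.debug("dropping %s: observed in control run(s) %s",
                         ev.accession, sorted(ev.runs_observed & manifest.control_runs))
    return kept


def finalize_list(evidence: Sequence[ProteinEvidence]) -> list[ProteinEvidence]:
    """Apply the confidence/validation rule to the differential survivors:
    retain high-confidence proteins, or low-confidence ones with at least
    one oxonium-validated match."""
    return [
        ev
        for ev in evidence
        if ev.best_confidence == "high" or ev.any_oxonium_pass
    ]


def linkage_partition(final: Sequence[ProteinEvidence]) -> dict[str, int]:
    """Venn counts by linkage evidence: ``o_total``, ``n_total``, ``both``,
    ``union``.  ``union == o_total + n_total - both`` holds whenever every
    protein carries at least one linkage flag (guaranteed for evidence
    built from glycopeptide matches with typed glycans)."""
    o_total = sum(ev.o_linked_evidence for ev in final)
    n_total = sum(ev.n_linked_evidence for ev in final)
    both = sum(ev.o_linked_evidence and ev.n_linked_evidence for ev in final)
    return {
        "o_total": o_total,
        "n_total": n_total,
        "both": both,
        "union": o_total + n_total - both,
    }


FINAL_LIST_COLUMNS = [
    "accession",
    "o_linked_evidence",
    "n_linked_evidence",
    "best_confidence",
    "any_oxonium_pass",
    "n_runs",
    "n_matches",
]


def write_final_list(final: Sequence[ProteinEvidence], path: str | Path) -> None:
    rows = [
        {
            "accession": ev.accession,
            "o_linked_evidence": ev.o_linked_evidence,
            "n_linked_evidence": ev.n_linked_evidence,
            "best_confidence": ev.best_confidence,
            "any_oxonium_pass": ev.any_oxonium_pass,
            "n_runs": len(ev.runs_observed),
            "n_matches": len(ev.matches),
        }
        for ev in final
    ]
    pd.DataFrame(rows, columns=FINAL_LIST_COLUMNS).to_csv(path, sep="\t", index=False)


def write_venn_json(counts: Mapping[str, int], path: str | Path) -> None:
    Path(path).write_text(json.dumps(dict(counts), indent=2, sort_keys=True) + "\n")
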