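"""End-to-end orchestration: digest -> search -> curate -> partition -> score.

A :class:`PipelineConfig` (flat YAML-compatible mapping) names the
inputs and settings; :func:`run_pipeline` executes every stage and
writes a stable result bundle.  All stage outputs are pure functions of
the inputs plus config — rerunning the same config over the same files
produces byte-identical TSV/JSON outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import yaml

from . import __version__
from .curation import (
    aggregate_evidence,
    differential_filter,
    finalize_list,
    linkage_partition,
    read_manifest,
    write_final_list,
    write_venn_json,
)
from .glycan import load_glycan_panel
from .match import SearchSettings, build_index, search_spectra, write_matches_tsv
from .digest import read_fasta
from .spectra import ToleranceSettings, read_mgf
from .target_score import (
    DEFAULT_VITAL_ORGANS,
    ScoreWeights,
    load_annotations,
    rank_proteins,
    write_ranked_tsv,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and offending record."""


@dataclass
class PipelineConfig:
    """Paths and settings for one pipeline run."""

    fasta: Path
    mgf: list[Path]
    manifest: Path
    glycan_panel: Path
    outdir: Path
    annotations: Path | None = None
    precursor_ppm: float = 10.0
    product_da: float = 0.02
    max_missed: int = 2
    min_len: int = 5
    max_len: int = 60
    allow_oxidized_met: bool = True
    high_confidence_ions: int = 6
    w_cancer: float = 1.0
    w_prognosis: float = 1.0
    w_membrane: float = 1.0
    w_healthy: float = 1.0
    vital_organs: tuple[str, ...] = DEFAULT_VITAL_ORGANS
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.fasta = Path(self.fasta)
        self.mgf = [Path(p) for p in self.mgf]
        self.manifest = Path(self.manifest)
        self.glycan_panel = Path(self.glycan_panel)
        self.outdir = Path(self.outdir)
        if self.annotations is not None:
            self.annotations = Path(self.annotations)
        self.vital_organs = tuple(self.vital_organs)

    def validate(self) -> None:
        """Check every referenced input exists before any compute."""
        for name in ("fasta", "manifest", "glycan_panel"):
            path = getattr(self, name)
            if not path.is_file():
                raise PipelineError(f"config: {name} path {path} does not exist")
        if not self.mgf:
            raise PipelineError("config: at least one MGF file is required")
        for path in self.mgf:
            if not path.is_file():
                raise PipelineError(f"config: MGF path {path} does not exist")
        if self.annotations is not None and not self.annotations.is_file():
            raise PipelineError(f"config: annotations path {self.annotations} does not exist")

    def search_settings(self, panel) -> SearchSettings:
        return SearchSettings(
            glycan_panel=tuple(panel),
            tolerances=ToleranceSettings(self.precursor_ppm, self.product_da),
            max_missed=self.max_missed,
            min_len=self.min_len,
            max_len=self.max_len,
            allow_oxidized_met=self.allow_oxidized_met,
            high_confidence_ions=self.high_confidence_ions,
        )

    def weights(self) -> ScoreWeights:
        return ScoreWeights(self.w_cancer, self.w_prognosis, self.w_membrane, self.w_healthy)

    def to_dict(self) -> dict:
        return {
            "fasta": str(self.fasta),
            "mgf": [str(p) for p in self.mgf],
            "manifest": str(self.manifest),
            "glycan_panel": str(self.glycan_panel),
            "outdir": str(self.outdir),
            "annotations": None if self.annotations is None else str(self.annotations),
            "precursor_ppm": self.precursor_ppm,
            "product_da": self.product_da,
            "max_missed": self.max_missed,
            "min_len": self.min_len,
            "max_len": self.max_len,
            "allow_oxidized_met": self.allow_oxidized_met,
            "high_confidence_ions": self.high_confidence_ions,
            "w_cancer": self.w_cancer,
            "w_prognosis": self.w_prognosis,
            "w_membrane": self.w_membrane,
            "w_healthy": self.w_healthy,
            "vital_organs": list(self.vital_organs),
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise PipelineError(f"config file {path} must hold a key/value mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"config file {path}: unknown key(s) {sorted(unknown)}")
        missing = {"fasta", "mgf", "manifest", "glycan_panel", "outdir"} - set(data)
        if missing:
            raise PipelineError(f"config file {path}: missing required key(s) {sorted(missing)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Short digest identifying the analysis configuration.  The output
        directory is excluded: the same inputs and settings produce the
        same hash wherever the results land."""
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _atomic_write(path: Path, writer: Callable[[Path], None]) -> None:
    """Write via a sibling temp file and rename, so partial outputs never
    appear under the final name."""
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    tmp = Path(tmp)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        tmp.unlink(missing_ok=True)


def _stage(name: str):
    """Decorator: re-raise stage failures with the stage name attached."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write the result bundle to
    ``config.outdir``: ``matches.tsv``, ``final_list.tsv``, ``venn.json``,
    ``targets_ranked.tsv`` (if annotations given) and ``run.log``.

    Returns a summary dict with the Venn counts, output paths and sizes.
    """
    config.validate()
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"glycopull {__version__}",
        f"config_hash {config.config_hash()}",
        f"seed {config.seed}",
    ]

    manifest = _stage("manifest")(read_manifest)(config.manifest)
    proteome = _stage("fasta")(read_fasta)(config.fasta)
    panel = _stage("glycan_panel")(load_glycan_panel)(config.glycan_panel)
    settings = config.search_settings(panel)

    index = _stage("index")(build_index)(proteome, settings)
    log_lines.append(f"candidates {len(index)}")

    spectrum_runs: dict[str, str] = {}
    all_matches = []
    for mgf_path in sorted(config.mgf):
        run_id = mgf_path.stem
        if run_id not in manifest.runs:
            raise PipelineError(
                f"stage 'search' failed: MGF {mgf_path} implies run {run_id!r} "
                "absent from the manifest"
            )
        spectra = _stage("mgf")(read_mgf)(mgf_path)
        for s in spectra:
            spectrum_runs[s.spectrum_id] = run_id
        all_matches.extend(_stage("search")(search_spectra)(spectra, index, settings))
    log_lines.append(f"matches {len(all_matches)}")

    evidence = _stage("curation")(aggregate_evidence)(all_matches, spectrum_runs, manifest)
    differential = differential_filter(evidence, manifest)
    final = finalize_list(differential)
    venn = linkage_partition(final)
    log_lines.append(
        "venn o_total={o_total} n_total={n_total} both={both} union={union}".format(**venn)
    )

    _atomic_write(outdir / "matches.tsv", lambda p: write_matches_tsv(all_matches, p))
    _atomic_write(outdir / "final_list.tsv", lambda p: write_final_list(final, p))
    _atomic_write(outdir / "venn.json", lambda p: write_venn_json(venn, p))

    ranked = None
    if config.annotations is not None:
        annotations = _stage("annotations")(load_annotations)(config.annotations)
        final_accessions = {ev.accession for ev in final}
        scored = [a for a in annotations if a.accession in final_accessions]
        if scored:
            ranked = _stage("target_score")(rank_proteins)(
                scored, config.weights(), config.vital_organs
            )
            _atomic_write(
                outdir / "targets_ranked.tsv", lambda p: write_ranked_tsv(ranked, p)
            )
            log_lines.append(f"ranked {len(ranked)}")
        else:
            logger.warning("no annotated protein appears in the final list; skipping scoring")
            log_lines.append("ranked 0")

    _atomic_write(outdir / "run.log", lambda p: p.write_text("\n".join(log_lines) + "\n"))
    return {
        "venn": venn,
        "n_matches": len(all_matches),
        "n_final": len(final),
        "final_accessions": sorted(ev.accession for ev in final),
        "ranked": ranked,
        "outdir": outdir,
    }
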