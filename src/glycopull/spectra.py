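"""MGF spectrum I/O, ppm matching and the oxonium-ion filter.

Glycopeptide MS/MS spectra carry low-mass *oxonium ions* — glycan
fragment cations diagnostic of the attached sugar.  A spectrum is
accepted as sLe-informative only when all three marker classes are
present: a hexosamine (HexNAc) oxonium, a sialic-acid (NeuAc) oxonium,
and the HexNAc-Hex disaccharide oxonium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from pyteomics import mgf as _mgf

__all__ = [
    "Ms2Spectrum",
    "MgfError",
    "OXONIUM_IONS",
    "ToleranceSettings",
    "oxonium_scan",
    "passes_sle_oxonium_filter",
    "ppm_error",
    "ppm_match",
    "read_mgf",
    "write_mgf",
]

logger = logging.getLogger(__name__)


class MgfError(ValueError):
    """Malformed MGF input."""


@dataclass(frozen=True)
class ToleranceSettings:
    """Mass-matching tolerances: relative (ppm) for the precursor, absolute
    (Da) for product ions."""

    precursor_ppm: float = 10.0
    product_da: float = 0.02

    def __post_init__(self) -> None:
        if self.precursor_ppm <= 0 or self.product_da <= 0:
            raise ValueError("tolerances must be strictly positive")


@dataclass(frozen=True)
class Ms2Spectrum:
    """One MS/MS spectrum: precursor (m/z, charge) plus a centroided peak
    list sorted ascending by m/z."""

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    peaks: tuple[tuple[float, float], ...] = ()
    retention_time: float | None = None

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"{self.spectrum_id}: precursor m/z must be positive")
        if self.precursor_charge < 1:
            raise ValueError(f"{self.spectrum_id}: precursor charge must be >= 1")
        peaks = tuple(sorted((float(mz), float(i)) for mz, i in self.peaks))
        if any(i < 0 for _, i in peaks):
            raise ValueError(f"{self.spectrum_id}: negative peak intensity")
        object.__setattr__(self, "peaks", peaks)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([mz for mz, _ in self.peaks], dtype=float)

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks], dtype=float)

    @property
    def base_peak_intensity(self) -> float:
        return max((i for _, i in self.peaks), default=0.0)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def ppm_match(observed: float, theoretical: float, tol_ppm: float) -> bool:
    return abs(ppm_error(observed, theoretical)) <= tol_ppm


#: Singly protonated oxonium reference m/z per marker class.  The HexNAc
#: class includes the intact ion at 204.087 and its water/2x-water/
#: cross-ring losses; the NeuAc class the intact ion at 292.103 and its
#: water loss; the disaccharide class the HexNAc-Hex ion at 366.140.
OXONIUM_IONS: Mapping[str, tuple[float, ...]] = {
    "hexnac_class": (204.0867, 186.0761, 168.0655, 138.0550, 126.0550),
    "neuac_class": (292.1027, 274.0921),
    "hexnac_hex_class": (366.1395,),
}


def oxonium_scan(
    s: Ms2Spectrum,
    tol: ToleranceSettings = ToleranceSettings(),
    *,
    min_relative_intensity: float = 0.01,
    reference: Mapping[str, tuple[float, ...]] = OXONIUM_IONS,
) -> dict[str, list[tuple[float, float]]]:
    """Detect oxonium marker ions, one peak list per class.

    A detection is a peak within ``tol.product_da`` of any reference m/z
    of the class with intensity at least *min_relative_intensity* of the
    base peak (a relative floor, so the decision is invariant to uniform
    intensity scaling).
    """
    floor = min_relative_intensity * s.base_peak_intensity
    detections: dict[str, list[tuple[float, float]]] = {name: [] for name in reference}
    for name, refs in reference.items():
        for mz, intensity in s.peaks:
            if intensity < floor:
                continue
            if any(abs(mz - ref) <= tol.product_da for ref in refs):
                detections[name].append((mz, intensity))
    return detections


def passes_sle_oxonium_filter(
    s: Ms2Spectrum,
    tol: ToleranceSettings = ToleranceSettings(),
    *,
    min_relative_intensity: float = 0.01,
) -> bool:
    """True iff all three oxonium classes have at least one detection."""
    detections = oxonium_scan(s, tol, min_relative_intensity=min_relative_intensity)
    return all(len(v) >= 1 for v in detections.values())


def _validate_mgf_blocks(path: Path) -> None:
    """Cheap structural pass: every BEGIN IONS must have a matching END IONS."""
    depth = 0
    block = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        token = line.strip().upper()
        if token == "BEGIN IONS":
            if depth:
                raise MgfError(f"{path}: block {block} (line {lineno}) missing END IONS")
            depth = 1
            block += 1
        elif token == "END IONS":
            if not depth:
                raise MgfError(f"{path}: stray END IONS at line {lineno}")
            depth = 0
    if depth:
        raise MgfError(f"{path}: block {block} not terminated by END IONS")


def read_mgf(path: str | Path, *, default_charge: int = 2) -> list[Ms2Spectrum]:
    """Read an MGF file into spectra; peak lists are sorted on read.

    Spectrum identifiers come from TITLE.  Spectra without a CHARGE line
    are assumed charge *default_charge* (logged as a warning); spectra
    without PEPMASS are rejected.
    """
    path = Path(path)
    _validate_mgf_blocks(path)
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            title = str(params.get("title", f"index={i}"))
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise MgfError(f"{path}: spectrum {title!r} lacks PEPMASS")
            charges = params.get("charge")
            if charges:
                charge = int(charges[0])
            else:
                logger.warning("%s: spectrum %r lacks CHARGE; assuming %d+",
                               path, title, default_charge)
                charge = default_charge
            rt = params.get("rtinseconds")
            spectra.append(
                Ms2Spectrum(
                    spectrum_id=title,
                    precursor_mz=float(pepmass[0]),
                    precursor_charge=charge,
                    peaks=tuple(zip(entry["m/z array"], entry["intensity array"])),
                    retention_time=float(rt) if rt is not None else None,
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Ms2Spectrum], path: str | Path) -> None:
    """Write spectra to MGF (TITLE, PEPMASS, CHARGE, optional RTINSECONDS)."""
    entries = []
    for s in spectra:
        params = {
            "title": s.spectrum_id,
            "pepmass": s.precursor_mz,
            "charge": [s.precursor_charge],
        }
        if s.retention_time is not None:
            params["rtinseconds"] = s.retention_time
        entries.append(
            {
                "params": params,
                "m/z array": np.array([mz for mz, _ in s.peaks], dtype=float),
                "intensity array": np.array([i for _, i in s.peaks], dtype=float),
            }
        )
    _mgf.write(entries, str(path), file_mode="w")
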