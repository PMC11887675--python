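"""Glycan composition arithmetic.

A glycan *composition* records how many residues of each monosaccharide
class a glycan contains — Hex (hexose), HexNAc (N-acetylhexosamine),
dHex (deoxyhexose, i.e. fucose) and NeuAc (N-acetylneuraminic / sialic
acid) — without saying anything about topology or linkage.  Compositions
are the unit of mass arithmetic in glycopeptide searches: attaching a
glycan to a peptide adds the sum of its residue masses to the peptide's
neutral monoisotopic mass.

Two textual dialects are supported and auto-detected:

* shorthand — single letters ``H``/``N``/``F``/``S`` each followed by a
  count, e.g. ``H5N4F1S1``;
* long form — residue names with parenthesized counts, e.g.
  ``Hex(2)HexNAc(2)NeuAc(1)dHex(1)``.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from types import MappingProxyType
from typing import Iterable, Mapping

__all__ = [
    "Attachment",
    "GlycanComposition",
    "GlycanError",
    "GlycanParseError",
    "MONOSACCHARIDE_MASSES",
    "composition_delta_mass",
    "format_composition",
    "is_sle_compatible",
    "load_glycan_panel",
    "n_glycan_class",
    "parse_composition",
]

#: Monoisotopic residue masses in Da (free monosaccharide minus water),
#: i.e. the mass a residue contributes inside a glycosidic chain.
MONOSACCHARIDE_MASSES: Mapping[str, float] = MappingProxyType(
    {
        "Hex": 162.052824,
        "HexNAc": 203.079373,
        "dHex": 146.057909,
        "NeuAc": 291.095417,
    }
)

_SHORT_SYMBOLS = {"H": "hex", "N": "hexnac", "F": "dhex", "S": "neuac"}
_LONG_NAMES = {"Hex": "hex", "HexNAc": "hexnac", "dHex": "dhex", "NeuAc": "neuac"}
_FIELD_TO_TABLE = {"hex": "Hex", "hexnac": "HexNAc", "dhex": "dHex", "neuac": "NeuAc"}


class GlycanError(ValueError):
    """Invalid glycan composition."""


class GlycanParseError(GlycanError):
    """Unparseable composition string; the message names the offending token."""


class Attachment(str, enum.Enum):
    """Attachment class of a glycan composition."""

    N_LINKED = "N"
    O_LINKED = "O"
    UNSPECIFIED = "unspecified"


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Monosaccharide counts plus an attachment class.

    Counts must be non-negative integers.  A composition intended for use
    as a peptide modification must contain at least one residue; the
    all-zero composition is only valid through :meth:`empty`, which exists
    for the additive identity in mass arithmetic.
    """

    hex: int = 0
    hexnac: int = 0
    dhex: int = 0
    neuac: int = 0
    attachment: Attachment = field(default=Attachment.UNSPECIFIED, compare=False)

    def __post_init__(self) -> None:
        for name in ("hex", "hexnac", "dhex", "neuac"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise GlycanError(f"{name} count must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.hex + self.hexnac + self.dhex + self.neuac

    def counts(self) -> dict[str, int]:
        """Counts keyed by table symbol (Hex, HexNAc, dHex, NeuAc)."""
        return {
            "Hex": self.hex,
            "HexNAc": self.hexnac,
            "dHex": self.dhex,
            "NeuAc": self.neuac,
        }

    @classmethod
    def empty(cls, attachment: Attachment = Attachment.UNSPECIFIED) -> "GlycanComposition":
        return cls(0, 0, 0, 0, attachment)

    def with_attachment(self, attachment: Attachment) -> "GlycanComposition":
        return replace(self, attachment=attachment)

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        if not isinstance(other, GlycanComposition):
            return NotImplemented
        att = self.attachment if self.attachment == other.attachment else Attachment.UNSPECIFIED
        return GlycanComposition(
            self.hex + other.hex,
            self.hexnac + other.hexnac,
            self.dhex + other.dhex,
            self.neuac + other.neuac,
            att,
        )

    def __str__(self) -> str:
        return format_composition(self, "short")


_SHORT_TOKEN = re.compile(r"([A-Za-z]+)(\d+)")
_LONG_TOKEN = re.compile(r"([A-Za-z]+)\((\d+)\)")


def _tokenize(text: str, pattern: re.Pattern, symbols: Mapping[str, str]) -> dict[str, int]:
    counts = {"hex": 0, "hexnac": 0, "dhex": 0, "neuac": 0}
    pos = 0
    while pos < len(text):
        m = pattern.match(text, pos)
        if m is None:
            raise GlycanParseError(f"unparseable token at {text[pos:]!r} in {text!r}")
        symbol = m.group(1)
        if symbol not in symbols:
            raise GlycanParseError(f"unknown monosaccharide symbol {symbol!r} in {text!r}")
        counts[symbols[symbol]] += int(m.group(2))
        pos = m.end()
    return counts


def parse_composition(
    text: str,
    attachment: Attachment = Attachment.UNSPECIFIED,
    *,
    allow_empty: bool = False,
) -> GlycanComposition:
    """Parse a composition string in either dialect.

    The dialect is auto-detected: a ``(`` anywhere selects the long form.
    Symbols absent from the string mean a count of zero.  An all-zero
    composition is rejected unless *allow_empty* is set, because an empty
    glycan is meaningless as a peptide modification.
    """
    stripped = text.strip()
    if not stripped:
        raise GlycanParseError("empty composition string")
    if "(" in stripped:
        counts = _tokenize(stripped, _LONG_TOKEN, _LONG_NAMES)
    else:
        counts = _tokenize(stripped, _SHORT_TOKEN, _SHORT_SYMBOLS)
    comp = GlycanComposition(attachment=attachment, **counts)
    if comp.total == 0 and not allow_empty:
        raise GlycanError(f"composition {text!r} contains no residues")
    return comp


def format_composition(comp: GlycanComposition, dialect: str = "short") -> str:
    """Render a composition in the requested dialect, omitting zero counts.

    ``parse_composition(format_composition(c, d)) == c`` for any non-empty
    composition and either dialect.
    """
    if dialect == "short":
        parts = [
            f"{letter}{getattr(comp, name)}"
            for letter, name in _SHORT_SYMBOLS.items()
            if getattr(comp, name) > 0
        ]
    elif dialect == "long":
        parts = [
            f"{symbol}({getattr(comp, name)})"
            for symbol, name in _LONG_NAMES.items()
            if getattr(comp, name) > 0
        ]
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'short' or 'long'")
    return "".join(parts)


def composition_delta_mass(
    comp: GlycanComposition,
    table: Mapping[str, float] = MONOSACCHARIDE_MASSES,
) -> float:
    """Monoisotopic delta mass in Da added by attaching *comp* to a peptide.

    Plain residue-mass sum: ``sum(count * table[residue])``.  Glycosidic
    condensation water is already accounted for by using residue (not free
    sugar) masses, so the sum is exactly the neutral-mass increment of the
    glycopeptide over the bare peptide.
    """
    total = 0.0
    for field_name, symbol in _FIELD_TO_TABLE.items():
        count = getattr(comp, field_name)
        if count == 0:
            continue
        if symbol not in table:
            raise GlycanError(f"monosaccharide {symbol!r} missing from mass table")
        total += count * table[symbol]
    return total


def is_sle_compatible(comp: GlycanComposition) -> tuple[bool, str]:
    """Composition-level necessary condition for a sialyl-Lewis terminus.

    A sialylated Lewis antigen (sLeA/X) is a NeuAc-Hex-(Fuc)HexNAc
    terminal motif, so any glycan carrying one must contain at least one
    residue of each of Hex, HexNAc, dHex and NeuAc.  This is necessary but
    not sufficient — topology cannot be inferred from a composition — and
    the reason string says so.
    """
    checks = [
        ("hex", "no Hex residue (sLe requires a galactose arm)"),
        ("hexnac", "no HexNAc residue (sLe requires a fucosylated GlcNAc)"),
        ("dhex", "no dHex/fucose residue (sLe requires core or antenna fucose)"),
        ("neuac", "no NeuAc residue (sLe requires a terminal sialic acid)"),
    ]
    for field_name, reason in checks:
        if getattr(comp, field_name) < 1:
            return False, reason
    return True, (
        "composition permits a NeuAc-Hex-(Fuc)HexNAc terminus "
        "(necessary condition only; topology unknown)"
    )


def n_glycan_class(comp: GlycanComposition) -> str:
    """Coarse N-glycan class from composition alone.

    Rule table (a documented, replaceable heuristic — true classification
    needs topology):

    * ``oligomannose`` — exactly 2 HexNAc (the chitobiose core), ≥ 4 Hex,
      no fucose or sialic acid;
    * ``paucimannose`` — ≤ 2 HexNAc and ≤ 3 Hex;
    * ``complex`` — ≥ 4 HexNAc (both arms carry antennae);
    * ``hybrid`` — exactly 3 HexNAc with ≥ 4 Hex;
    * ``other`` — anything else.
    """
    if comp.attachment == Attachment.O_LINKED:
        raise GlycanError("n_glycan_class applies to N-linked or unspecified compositions")
    if comp.hexnac == 2 and comp.hex >= 4 and comp.dhex == 0 and comp.neuac == 0:
        return "oligomannose"
    if comp.hexnac <= 2 and comp.hex <= 3:
        return "paucimannose"
    if comp.hexnac >= 4:
        return "complex"
    if comp.hexnac == 3 and comp.hex >= 4:
        return "hybrid"
    return "other"


def load_glycan_panel(path: str | Path) -> list[GlycanComposition]:
    """Read a glycan panel file: one composition per line, either dialect.

    ``#`` starts a comment.  An optional second whitespace-delimited token
    ``N`` or ``O`` sets the attachment class (default unspecified).
    """
    panel: list[GlycanComposition] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        attachment = Attachment.UNSPECIFIED
        if len(tokens) == 2:
            try:
                attachment = Attachment(tokens[1].upper())
            except ValueError:
                raise GlycanParseError(
                    f"line {lineno}: unknown attachment {tokens[1]!r} (expected N or O)"
                ) from None
        elif len(tokens) != 1:
            raise GlycanParseError(f"line {lineno}: expected 'COMPOSITION [N|O]', got {raw!r}")
        try:
            panel.append(parse_composition(tokens[0], attachment))
        except GlycanError as exc:
            raise GlycanParseError(f"line {lineno}: {exc}") from exc
    return panel


def write_glycan_panel(panel: Iterable[GlycanComposition], path: str | Path) -> None:
    lines = []
    for comp in panel:
        suffix = "" if comp.attachment == Attachment.UNSPECIFIED else f" {comp.attachment.value}"
        lines.append(format_composition(comp, "short") + suffix)
    Path(path).write_text("\n".join(lines) + "\n")


#: The glycan panel used throughout as the default search space: two
#: sLe-compatible complex N-glycan compositions and three extended,
#: fucosylated-sialylated O-glycan core compositions.
DEFAULT_GLYCAN_PANEL: tuple[GlycanComposition, ...] = (
    parse_composition("H5N4F1S1", Attachment.N_LINKED),
    parse_composition("H5N4F1S2", Attachment.N_LINKED),
    parse_composition("Hex(2)HexNAc(2)NeuAc(1)dHex(1)", Attachment.O_LINKED),
    parse_composition("Hex(2)HexNAc(2)NeuAc(2)dHex(1)", Attachment.O_LINKED),
    parse_composition("Hex(3)HexNAc(3)NeuAc(2)dHex(2)", Attachment.O_LINKED),
)
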