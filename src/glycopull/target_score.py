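"""Target Score: annotation-driven prioritization of candidate glycoproteins.

Proteins surviving pulldown curation are ranked for therapeutic
targetability from a Human-Protein-Atlas-style annotation table.  The
score rewards cancer association, the number of cancers where the
protein predicts unfavorable prognosis, and cell-membrane localization
(accessible to antibodies and CAR constructs), and penalizes expression
in a configurable list of vital healthy organs (off-target risk):

    total = w_c * cancer_association
          + w_p * n_unfavorable_prognosis
          + w_m * [membrane_localized]
          - w_h * sum over vital organs of expression level

with expression levels encoded not_detected=0 < low=1 < medium=2 <
high=3.  All four weights default to 1; setting a weight to 0 removes
its term, and indicator-style scoring is obtained by capping the
ordinal inputs upstream, so the parameterization subsumes the common
variants of additive prioritization scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "DEFAULT_VITAL_ORGANS",
    "EXPRESSION_LEVELS",
    "ORGAN_VOCABULARY",
    "ProteinAnnotation",
    "ScoreWeights",
    "TargetScoreResult",
    "load_annotations",
    "rank_proteins",
    "score_protein",
    "write_annotations",
    "write_ranked_tsv",
]

#: Ordinal encoding of per-organ healthy expression.
EXPRESSION_LEVELS: Mapping[str, int] = {
    "not_detected": 0,
    "low": 1,
    "medium": 2,
    "high": 3,
}
_LEVEL_NAMES = {v: k for k, v in EXPRESSION_LEVELS.items()}

#: Controlled vocabulary of organ columns in the annotation table.
ORGAN_VOCABULARY: tuple[str, ...] = (
    "brain",
    "heart",
    "lung",
    "liver",
    "kidney",
    "pancreas",
    "colon",
)

#: Organs whose healthy expression is penalized by default.
DEFAULT_VITAL_ORGANS: tuple[str, ...] = ORGAN_VOCABULARY


@dataclass(frozen=True)
class ScoreWeights:
    """Non-negative weights for the four score components."""

    w_cancer: float = 1.0
    w_prognosis: float = 1.0
    w_membrane: float = 1.0
    w_healthy: float = 1.0

    def __post_init__(self) -> None:
        for name in ("w_cancer", "w_prognosis", "w_membrane", "w_healthy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def scaled(self, c: float) -> "ScoreWeights":
        return ScoreWeights(
            self.w_cancer * c, self.w_prognosis * c, self.w_membrane * c, self.w_healthy * c
        )


@dataclass(frozen=True)
class ProteinAnnotation:
    """One protein's targetability-relevant annotation record.

    ``cancer_association`` is an ordinal 0 (no evidence) .. 3 (strong
    evidence); ``n_unfavorable_prognosis`` counts cancer types where the
    protein is an unfavorable prognostic marker; ``healthy_expression``
    maps organ names (controlled vocabulary) to ordinal levels.
    """

    accession: str
    cancer_association: int
    n_unfavorable_prognosis: int
    membrane_localized: bool
    healthy_expression: Mapping[str, int]

    def __post_init__(self) -> None:
        if not 0 <= self.cancer_association <= 3:
            raise ValueError(f"{self.accession}: cancer_association must be in 0..3")
        if self.n_unfavorable_prognosis < 0:
            raise ValueError(f"{self.accession}: n_unfavorable_prognosis must be >= 0")
        unknown = set(self.healthy_expression) - set(ORGAN_VOCABULARY)
        if unknown:
            raise ValueError(f"{self.accession}: unknown organ(s) {sorted(unknown)}")
        for organ, level in self.healthy_expression.items():
            if level not in _LEVEL_NAMES:
                raise ValueError(
                    f"{self.accession}: organ {organ!r} level {level!r} outside 0..3"
                )
        object.__setattr__(self, "healthy_expression", dict(self.healthy_expression))


@dataclass(frozen=True)
class TargetScoreResult:
    """Component-wise score for one protein; rank assigned by rank_proteins."""

    accession: str
    cancer_term: float
    prognosis_term: float
    membrane_term: float
    healthy_penalty: float
    total: float
    rank: int = 0


def score_protein(
    a: ProteinAnnotation,
    w: ScoreWeights = ScoreWeights(),
    vital_organs: Sequence[str] = DEFAULT_VITAL_ORGANS,
) -> TargetScoreResult:
    """Compute the additive score for one protein (rank left at 0)."""
    missing = [o for o in vital_organs if o not in a.healthy_expression]
    if missing:
        raise ValueError(
            f"{a.accession}: vital organ(s) {missing} absent from healthy_expression"
        )
    cancer_term = w.w_cancer * a.cancer_association
    prognosis_term = w.w_prognosis * a.n_unfavorable_prognosis
    membrane_term = w.w_membrane * (1.0 if a.membrane_localized else 0.0)
    healthy_penalty = w.w_healthy * sum(a.healthy_expression[o] for o in vital_organs)
    return TargetScoreResult(
        accession=a.accession,
        cancer_term=cancer_term,
        prognosis_term=prognosis_term,
        membrane_term=membrane_term,
        healthy_penalty=healthy_penalty,
        total=cancer_term + prognosis_term + membrane_term - healthy_penalty,
    )


def rank_proteins(
    annotations: Sequence[ProteinAnnotation],
    w: ScoreWeights = ScoreWeights(),
    vital_organs: Sequence[str] = DEFAULT_VITAL_ORGANS,
) -> list[TargetScoreResult]:
    """Score and rank proteins: descending total, ties broken by lower
    healthy penalty, then accession; ranks 1..n."""
    if not annotations:
        raise ValueError("cannot rank an empty annotation list")
    accessions = [a.accession for a in annotations]
    if len(set(accessions)) != len(accessions):
        dupes = sorted({a for a in accessions if accessions.count(a) > 1})
        raise ValueError(f"duplicate accession(s): {dupes}")
    scored = [score_protein(a, w, vital_organs) for a in annotations]
    scored.sort(key=lambda r: (-r.total, r.healthy_penalty, r.accession))
    return [
        TargetScoreResult(
            r.accession,
            r.cancer_term,
            r.prognosis_term,
            r.membrane_term,
            r.healthy_penalty,
            r.total,
            rank=i,
        )
        for i, r in enumerate(scored, start=1)
    ]


ANNOTATION_COLUMNS = (
    ["accession", "cancer_association", "n_unfavorable_prognosis", "membrane_localized"]
    + list(ORGAN_VOCABULARY)
)


def load_annotations(path: str | Path) -> list[ProteinAnnotation]:
    """Read an annotation TSV with the documented header.

    Columns: accession, cancer_association (0..3),
    n_unfavorable_prognosis (int >= 0), membrane_localized (True/False),
    then one column per organ in the controlled vocabulary holding a
    level name.  Unknown organ columns and unknown level names are
    rejected with row-addressed errors.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    organ_cols = [c for c in df.columns if c not in ANNOTATION_COLUMNS[:4]]
    unknown = set(organ_cols) - set(ORGAN_VOCABULARY)
    if unknown:
        raise ValueError(f"{path}: unknown organ column(s) {sorted(unknown)}")
    annotations = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        levels = {}
        for organ in organ_cols:
            name = str(getattr(row, organ))
            if name not in EXPRESSION_LEVELS:
                raise ValueError(
                    f"{path}: row {i}, column {organ!r}: unknown level {name!r} "
                    f"(allowed: {sorted(EXPRESSION_LEVELS)})"
                )
            levels[organ] = EXPRESSION_LEVELS[name]
        try:
            annotations.append(
                ProteinAnnotation(
                    accession=str(row.accession),
                    cancer_association=int(row.cancer_association),
                    n_unfavorable_prognosis=int(row.n_unfavorable_prognosis),
                    membrane_localized=_parse_bool(row.membrane_localized),
                    healthy_expression=levels,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    return annotations


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise ValueError(f"unparseable boolean {value!r}")


def write_annotations(annotations: Sequence[ProteinAnnotation], path: str | Path) -> None:
    rows = []
    for a in annotations:
        row = {
            "accession": a.accession,
            "cancer_association": a.cancer_association,
            "n_unfavorable_prognosis": a.n_unfavorable_prognosis,
            "membrane_localized": a.membrane_localized,
        }
        for organ in ORGAN_VOCABULARY:
            row[organ] = _LEVEL_NAMES[a.healthy_expression.get(organ, 0)]
        rows.append(row)
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def write_ranked_tsv(results: Sequence[TargetScoreResult], path: str | Path) -> None:
    rows = [
        {
            "rank": r.rank,
            "accession": r.accession,
            "total": r.total,
            "cancer_term": r.cancer_term,
            "prognosis_term": r.prognosis_term,
            "membrane_term": r.membrane_term,
            "healthy_penalty": r.healthy_penalty,
        }
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=[
            "rank",
            "accession",
            "total",
            "cancer_term",
            "prognosis_term",
            "membrane_term",
            "healthy_penalty",
        ],
    ).to_csv(path, sep="\t", index=False)
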