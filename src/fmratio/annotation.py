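"""Annotation evidence integration for high-ratio variants.

High-ratio candidates are reconciled with static annotation evidence —
clinical-significance class (ClinVar), QC status in an independent dataset
(gnomAD genomes), gene–phenotype links (OMIM), protein-structure predictions
(VENUS), and regulatory evidence (RegulomeDB rank and score) — and five
tallies are reported over the candidate set:

1. variants labelled Benign or Likely Benign despite the high ratio;
2. variants flagged as QC failures in the second dataset;
3. genes with a specific phenotype link;
4. variants for which a structural prediction was possible at all;
5. variants with some indication of regulatory function, defined as a
   RegulomeDB rank stratum below 3 (any of 1a–1f, 2a–2c) **or** a
   probability score strictly above 0.5.

All annotation sources are consumed as static tables; no live queries.
"""

from __future__ import annotations

import functools
import importlib.resources
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

import pandas as pd

from .ratio import RatioResult

__all__ = [
    "ClinvarClass",
    "QcStatus",
    "StructuralPrediction",
    "OmimLink",
    "RegulomeRank",
    "AnnotationRecord",
    "FindingsSummary",
    "parse_regulome_rank",
    "regulatory_evidence_flag",
    "read_annotation_table",
    "summarize_findings",
    "join_annotations",
    "packaged_annotations",
]

#: The 15 RegulomeDB rank categories, best evidence first.
REGULOME_RANK_ORDER = (
    "1a", "1b", "1c", "1d", "1e", "1f",
    "2a", "2b", "2c",
    "3a", "3b",
    "4", "5", "6", "7",
)


class ClinvarClass(str, Enum):
    BENIGN = "BENIGN"
    LIKELY_BENIGN = "LIKELY_BENIGN"
    BENIGN_OR_LIKELY_BENIGN = "BENIGN_OR_LIKELY_BENIGN"
    UNCERTAIN = "UNCERTAIN"
    CONFLICTING = "CONFLICTING"
    LIKELY_PATHOGENIC = "LIKELY_PATHOGENIC"
    PATHOGENIC = "PATHOGENIC"
    ABSENT = "ABSENT"


#: Classes counted as "Benign or Likely Benign" (includes the combined label).
BENIGN_LIKE = frozenset(
    {ClinvarClass.BENIGN, ClinvarClass.LIKELY_BENIGN, ClinvarClass.BENIGN_OR_LIKELY_BENIGN}
)


class QcStatus(str, Enum):
    YES = "yes"
    NO = "no"
    NOT_ASSESSED = "not_assessed"


class StructuralPrediction(str, Enum):
    """VENUS-style protein-structure effect call.

    ``NOT_APPLICABLE`` covers variants with no single amino-acid change
    (synonymous, intronic, UTR, splice); ``UNCLEAR`` covers variants whose
    exact substitution could not be resolved against an isoform.  Only
    explicit calls (neutral / stabilizing / destabilizing) count as
    "prediction possible".
    """

    NEUTRAL = "NEUTRAL"
    STABILIZING = "STABILIZING"
    DESTABILIZING = "DESTABILIZING"
    UNCLEAR = "UNCLEAR"
    NOT_APPLICABLE = "NOT_APPLICABLE"


EXPLICIT_STRUCTURAL_CALLS = frozenset(
    {StructuralPrediction.NEUTRAL, StructuralPrediction.STABILIZING, StructuralPrediction.DESTABILIZING}
)


class OmimLink(str, Enum):
    SPECIFIC = "SPECIFIC"
    TENTATIVE = "TENTATIVE"
    NONE = "NONE"


@functools.total_ordering
@dataclass(frozen=True)
class RegulomeRank:
    """A RegulomeDB rank: integer stratum 1–7 plus optional letter sub-rank.

    Ordered by evidence strength: ``1a < 1b < … < 2c < … < 7`` (smaller
    means *stronger* evidence of regulatory function).
    """

    stratum: int
    sub: Optional[str] = None

    def __str__(self) -> str:
        return f"{self.stratum}{self.sub or ''}"

    def _key(self) -> int:
        return REGULOME_RANK_ORDER.index(str(self))

    def __lt__(self, other: "RegulomeRank") -> bool:
        return self._key() < other._key()


def parse_regulome_rank(text: Union[str, "RegulomeRank"]) -> RegulomeRank:
    """Parse a rank string such as ``"2b"`` or ``" 1A "`` into a RegulomeRank."""
    if isinstance(text, RegulomeRank):
        return text
    norm = str(text).strip().lower()
    if norm not in REGULOME_RANK_ORDER:
        raise ValueError(
            f"unknown RegulomeDB rank {text!r}; valid ranks: {', '.join(REGULOME_RANK_ORDER)}"
        )
    stratum = int(norm[0])
    sub = norm[1:] or None
    return RegulomeRank(stratum=stratum, sub=sub)


def regulatory_evidence_flag(rank: Union[str, RegulomeRank, None], score: Optional[float]) -> bool:
    """Some indication of regulatory function: rank stratum < 3 or score > 0.5.

    The rank comparison is on the numeric stratum (1a–1f and 2a–2c all
    qualify); the score comparison is strict.  A missing rank or score
    simply contributes nothing to the disjunction.
    """
    by_rank = False
    if rank is not None and str(rank).strip() != "":
        by_rank = parse_regulome_rank(rank).stratum < 3
    by_score = False
    if score is not None and not pd.isna(score):
        if not (0.0 <= float(score) <= 1.0):
            raise ValueError(f"regulome score must lie in [0, 1], got {score}")
        by_score = float(score) > 0.5
    return by_rank or by_score


@dataclass(frozen=True)
class AnnotationRecord:
    """Static annotation evidence for one variant."""

    variant_id: str
    clinvar_class: ClinvarClass = ClinvarClass.ABSENT
    qc_fail_genomes: QcStatus = QcStatus.NOT_ASSESSED
    regulome_rank: Optional[RegulomeRank] = None
    regulome_score: Optional[float] = None
    structural_prediction: StructuralPrediction = StructuralPrediction.NOT_APPLICABLE
    omim_link: OmimLink = OmimLink.NONE
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.regulome_score is not None and not (0.0 <= self.regulome_score <= 1.0):
            raise ValueError(f"regulome_score must lie in [0, 1], got {self.regulome_score}")


@dataclass(frozen=True)
class FindingsSummary:
    """The five evidence tallies over a set of annotated variants."""

    n_variants: int
    n_benign_or_likely: int
    n_qc_fail: int
    n_omim_specific: int
    n_structural_predictable: int
    n_regulatory_evidence: int

    def fraction(self, tally: int) -> float:
        return tally / self.n_variants

    def to_dict(self) -> dict:
        d = {
            "n_variants": self.n_variants,
            "n_benign_or_likely": self.n_benign_or_likely,
            "n_qc_fail": self.n_qc_fail,
            "n_omim_specific": self.n_omim_specific,
            "n_structural_predictable": self.n_structural_predictable,
            "n_regulatory_evidence": self.n_regulatory_evidence,
        }
        for key in list(d):
            if key != "n_variants":
                d[f"frac{key[1:]}"] = d[key] / self.n_variants
        return d

    def to_text(self) -> str:
        n = self.n_variants
        lines = [
            f"Findings over {n} high-ratio variants:",
            f"  Benign or Likely Benign in ClinVar : {self.n_benign_or_likely}/{n}"
            f" ({100 * self.n_benign_or_likely / n:.0f}%)",
            f"  Failing QC in the genomes dataset  : {self.n_qc_fail}/{n}"
            f" ({100 * self.n_qc_fail / n:.0f}%)",
            f"  Specific OMIM gene-phenotype link  : {self.n_omim_specific}/{n}"
            f" ({100 * self.n_omim_specific / n:.0f}%)",
            f"  Structural prediction possible     : {self.n_structural_predictable}/{n}"
            f" ({100 * self.n_structural_predictable / n:.0f}%)",
            f"  Regulatory evidence (rank<3 or >0.5): {self.n_regulatory_evidence}/{n}"
            f" ({100 * self.n_regulatory_evidence / n:.0f}%)",
        ]
        return "\n".join(lines)


def summarize_findings(annotations: Sequence[AnnotationRecord]) -> FindingsSummary:
    """Apply the five counting rules to a non-empty annotation set."""
    records = list(annotations)
    if not records:
        raise ValueError("cannot summarize an empty annotation collection")
    return FindingsSummary(
        n_variants=len(records),
        n_benign_or_likely=sum(a.clinvar_class in BENIGN_LIKE for a in records),
        n_qc_fail=sum(a.qc_fail_genomes is QcStatus.YES for a in records),
        n_omim_specific=sum(a.omim_link is OmimLink.SPECIFIC for a in records),
        n_structural_predictable=sum(
            a.structural_prediction in EXPLICIT_STRUCTURAL_CALLS for a in records
        ),
        n_regulatory_evidence=sum(
            regulatory_evidence_flag(a.regulome_rank, a.regulome_score) for a in records
        ),
    )


def read_annotation_table(
    path: Union[str, Path],
    regulome_path: Optional[Union[str, Path]] = None,
) -> List[AnnotationRecord]:
    """Read annotation evidence from one or two tab-separated tables.

    The main table must carry ``variant_id`` and any of ``clinvar_class``,
    ``qc_fail_genomes``, ``structural_prediction``, ``omim_link``, ``gene``.
    Regulome evidence (``regulome_rank``, ``regulome_score``) may live in
    the same table or in a separate one joined on ``variant_id``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"variant_id": str})
    if "variant_id" not in df.columns:
        raise ValueError(f"annotation table {path} lacks a variant_id column")
    if regulome_path is not None:
        reg = pd.read_csv(regulome_path, sep="\t", comment="#", dtype={"variant_id": str})
        dup = reg["variant_id"][reg["variant_id"].duplicated()].tolist()
        if dup:
            raise ValueError(f"duplicate variant ids in regulome table: {', '.join(dup)}")
        df = df.merge(reg, on="variant_id", how="outer", validate="one_to_one")
    dup = df["variant_id"][df["variant_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate variant ids in annotation table: {', '.join(dup)}")

    def _get(row, col, default=None):
        value = row.get(col, default)
        if value is None or (isinstance(value, float) and pd.isna(value)):
            return default
        return value

    records = []
    for _, row in df.iterrows():
        rank_text = _get(row, "regulome_rank")
        records.append(
            AnnotationRecord(
                variant_id=str(row["variant_id"]),
                clinvar_class=ClinvarClass(_get(row, "clinvar_class", "ABSENT")),
                qc_fail_genomes=QcStatus(_get(row, "qc_fail_genomes", "not_assessed")),
                regulome_rank=parse_regulome_rank(rank_text) if rank_text is not None else None,
                regulome_score=(
                    float(_get(row, "regulome_score"))
                    if _get(row, "regulome_score") is not None
                    else None
                ),
                structural_prediction=StructuralPrediction(
                    _get(row, "structural_prediction", "NOT_APPLICABLE")
                ),
                omim_link=OmimLink(_get(row, "omim_link", "NONE")),
                gene=_get(row, "gene"),
            )
        )
    return records


def join_annotations(
    results: Sequence[RatioResult],
    annotations: Sequence[AnnotationRecord],
) -> pd.DataFrame:
    """Left-join scored/flagged variants to annotation evidence.

    Unmatched variants carry ABSENT / not_assessed placeholders and are
    marked ``annotated = False``.  Duplicate annotation ids raise.
    """
    seen = set()
    dup = [a.variant_id for a in annotations if a.variant_id in seen or seen.add(a.variant_id)]
    if dup:
        raise ValueError(f"duplicate annotation ids: {', '.join(sorted(set(dup)))}")
    by_id = {a.variant_id: a for a in annotations}
    placeholder = AnnotationRecord(variant_id="")
    rows = []
    for res in results:
        ann = by_id.get(res.variant_id, placeholder)
        rows.append(
            {
                "variant_id": res.variant_id,
                "ratio": res.ratio,
                "log2_ratio": res.log2_ratio,
                "high_ratio": res.high_ratio,
                "carrier_profile": res.carrier_profile.value,
                "annotated": res.variant_id in by_id,
                "gene": ann.gene,
                "clinvar_class": ann.clinvar_class.value,
                "qc_fail_genomes": ann.qc_fail_genomes.value,
                "regulome_rank": str(ann.regulome_rank) if ann.regulome_rank else None,
                "regulome_score": ann.regulome_score,
                "structural_prediction": ann.structural_prediction.value,
                "omim_link": ann.omim_link.value,
                "regulatory_evidence": regulatory_evidence_flag(
                    ann.regulome_rank, ann.regulome_score
                ),
            }
        )
    return pd.DataFrame(rows)


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("fmratio").joinpath("data", name))


def packaged_annotations() -> List[AnnotationRecord]:
    """The packaged annotation evidence for the 25 ClinVar-annotated
    high-ratio X-chromosome variants from the gnomAD exome screen."""
    return read_annotation_table(
        _data_path("high_ratio_clinvar_annotations.tsv"),
        regulome_path=_data_path("high_ratio_regulome.tsv"),
    )


def packaged_annotation_paths() -> dict:
    """Paths to the packaged annotation fixtures (for the CLI and scripts)."""
    return {
        "annotations": _data_path("high_ratio_clinvar_annotations.tsv"),
        "regulome": _data_path("high_ratio_regulome.tsv"),
        "counts": _data_path("worked_example_counts.tsv"),
    }
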