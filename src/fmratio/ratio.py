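"""Female-to-male allele proportion ratio.

The central statistic is the pseudocount-adjusted ratio of the female
minor-allele proportion to the male minor-allele proportion at a locus::

    R = ((V_f + 1) / (A_f + 1)) / ((V_m + 1) / (A_m + 1))

where ``V`` are minor-allele counts and ``A`` total allele counts, stratified
by sex.  Adding 1 to every term keeps R finite and positive even when a sex
has no observed carriers (or no observations at all), which is exactly the
situation of interest: a variant that is lethal in hemizygous males will have
V_m = 0 however many male X chromosomes were genotyped, and R then scales
with the male denominator — the more males genotyped without a single
carrier, the larger the ratio and the stronger the evidence of male-specific
depletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "CarrierProfile",
    "CountValidationError",
    "SexStratifiedCounts",
    "RatioResult",
    "RatioSummary",
    "compute_ratio",
    "log2_ratio",
    "classify_carrier_profile",
    "summarize_ratios",
]

#: Default carrier frequency below which males / homozygous females are
#: called "rare" by :func:`classify_carrier_profile`.
DEFAULT_RARITY_FRACTION = 1e-4


class CountValidationError(ValueError):
    """Raised when sex-stratified allele counts violate their invariants."""


class CarrierProfile(str, Enum):
    """Who carries the variant, inferred from sex-stratified counts.

    ``ONLY_HET_FEMALES`` is the signature of a variant lethal in males and
    homozygous females; it requires explicit zygosity information
    (``hom_f = 0``), not just the absence of male carriers.
    """

    ONLY_HET_FEMALES = "ONLY_HET_FEMALES"
    NO_MALES = "NO_MALES"
    MALES_AND_HOM_FEMALES_RARE = "MALES_AND_HOM_FEMALES_RARE"
    UNRESTRICTED = "UNRESTRICTED"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class SexStratifiedCounts:
    """The four allele-count terms of the ratio, plus optional zygosity.

    Parameters
    ----------
    v_f, a_f
        Minor-allele count and total allele count in females.
    v_m, a_m
        Minor-allele count and total allele count in males.  On the
        non-pseudoautosomal X, ``a_m`` equals the number of genotyped males
        (one allele each).
    hom_f
        Number of females homozygous for the minor allele, if known.
    hemi_m
        Number of males hemizygous for the minor allele, if known.  On the
        non-pseudoautosomal X this equals ``v_m``.
    """

    v_f: int
    a_f: int
    v_m: int
    a_m: int
    hom_f: Optional[int] = None
    hemi_m: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("v_f", "a_f", "v_m", "a_m"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)):
                raise CountValidationError(f"{name} must be an integer, got {value!r}")
            if value < 0:
                raise CountValidationError(f"{name} must be non-negative, got {value}")
        if self.v_f > self.a_f:
            raise CountValidationError(
                f"v_f ({self.v_f}) exceeds total female allele count a_f ({self.a_f})"
            )
        if self.v_m > self.a_m:
            raise CountValidationError(
                f"v_m ({self.v_m}) exceeds total male allele count a_m ({self.a_m})"
            )
        for name in ("hom_f", "hemi_m"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise CountValidationError(f"{name} must be non-negative, got {value}")
        if self.hom_f is not None and 2 * self.hom_f > self.v_f:
            raise CountValidationError(
                f"hom_f ({self.hom_f}) implies more than v_f ({self.v_f}) female minor alleles"
            )
        if self.hemi_m is not None and self.hemi_m > self.v_m:
            raise CountValidationError(
                f"hemi_m ({self.hemi_m}) exceeds male minor allele count v_m ({self.v_m})"
            )

    @property
    def combined_minor_count(self) -> int:
        """Sex-combined minor allele count ``v_f + v_m`` (the AC filter term)."""
        return self.v_f + self.v_m


def compute_ratio(counts: SexStratifiedCounts) -> float:
    """Pseudocount-adjusted female-to-male allele proportion ratio.

    Always finite and strictly positive; valid even when ``a_m = 0``.

    Examples
    --------
    >>> round(compute_ratio(SexStratifiedCounts(18736, 104056, 0, 38527)), 1)
    6937.5
    """
    return ((counts.v_f + 1) / (counts.a_f + 1)) / ((counts.v_m + 1) / (counts.a_m + 1))


def log2_ratio(ratio: float) -> float:
    """Base-2 logarithm of a ratio; raises for non-positive input."""
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    return math.log2(ratio)


def classify_carrier_profile(
    counts: SexStratifiedCounts,
    rarity_fraction: float = DEFAULT_RARITY_FRACTION,
) -> CarrierProfile:
    """Categorise who carries the variant.

    Rules, in order:

    * no carriers in either sex, or zygosity unknown where it matters →
      ``UNKNOWN``;
    * ``v_m = 0`` and ``hom_f = 0`` with female carriers → ``ONLY_HET_FEMALES``;
    * ``v_m = 0`` with homozygous females present or zygosity unknown →
      ``NO_MALES``;
    * male carriers and homozygous females both rarer than
      ``rarity_fraction`` of their denominators →
      ``MALES_AND_HOM_FEMALES_RARE``;
    * otherwise ``UNRESTRICTED``.
    """
    if counts.v_f == 0 and counts.v_m == 0:
        return CarrierProfile.UNKNOWN
    if counts.v_m == 0:
        if counts.hom_f == 0 and counts.v_f > 0:
            return CarrierProfile.ONLY_HET_FEMALES
        return CarrierProfile.NO_MALES
    # v_m > 0: rarity judgement needs zygosity in females.
    if counts.hom_f is None:
        return CarrierProfile.UNKNOWN
    male_freq = counts.v_m / counts.a_m if counts.a_m else 0.0
    n_females = counts.a_f / 2
    hom_freq = counts.hom_f / n_females if n_females else 0.0
    if male_freq < rarity_fraction and hom_freq < rarity_fraction:
        return CarrierProfile.MALES_AND_HOM_FEMALES_RARE
    return CarrierProfile.UNRESTRICTED


@dataclass(frozen=True)
class RatioResult:
    """Per-variant result: the ratio, its log2, and derived flags."""

    variant_id: str
    ratio: float
    log2_ratio: float = field(default=float("nan"))
    high_ratio: bool = False
    carrier_profile: CarrierProfile = CarrierProfile.UNKNOWN

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError(f"ratio must be positive, got {self.ratio}")
        if math.isnan(self.log2_ratio):
            object.__setattr__(self, "log2_ratio", math.log2(self.ratio))


def score_counts(
    variant_id: str,
    counts: SexStratifiedCounts,
    rarity_fraction: float = DEFAULT_RARITY_FRACTION,
) -> RatioResult:
    """Build a :class:`RatioResult` (unflagged) from raw counts."""
    r = compute_ratio(counts)
    return RatioResult(
        variant_id=variant_id,
        ratio=r,
        log2_ratio=math.log2(r),
        high_ratio=False,
        carrier_profile=classify_carrier_profile(counts, rarity_fraction),
    )


@dataclass(frozen=True)
class RatioSummary:
    """Cohort summary on both the ratio and the log2-ratio scale.

    The standard deviation uses the sample (n−1) denominator and is NaN for
    a single observation.  Full precision is retained here; one-decimal
    rounding is applied only in the report layer.
    """

    n: int
    mean_ratio: float
    sd_ratio: float
    min_ratio: float
    max_ratio: float
    mean_log2: float
    sd_log2: float
    min_log2: float
    max_log2: float

    REPORT_COLUMNS = (
        "n",
        "mean_ratio",
        "sd_ratio",
        "min_ratio",
        "max_ratio",
        "mean_log2",
        "sd_log2",
        "min_log2",
        "max_log2",
    )

    def to_report_row(self, decimals: int = 1) -> dict:
        """Rounded values for delimited reports (internal precision kept)."""
        row = {"n": self.n}
        for col in self.REPORT_COLUMNS[1:]:
            row[col] = round(getattr(self, col), decimals)
        return row


def summarize_ratios(ratios: Iterable[float]) -> RatioSummary:
    """Mean / sample SD / min / max of ratios and their log2 values.

    Raises ``ValueError`` on an empty collection or any non-positive ratio.
    """
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty collection of ratios")
    if np.any(arr <= 0):
        raise ValueError("all ratios must be positive")
    log2 = np.log2(arr)

    def _sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if x.size > 1 else float("nan")

    return RatioSummary(
        n=int(arr.size),
        mean_ratio=float(arr.mean()),
        sd_ratio=_sd(arr),
        min_ratio=float(arr.min()),
        max_ratio=float(arr.max()),
        mean_log2=float(log2.mean()),
        sd_log2=_sd(log2),
        min_log2=float(log2.min()),
        max_log2=float(log2.max()),
    )
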