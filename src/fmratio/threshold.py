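"""Empirical high-ratio threshold calibration against the pseudoautosomal null.

Pseudoautosomal (PAR) variants have no sex asymmetry in copy number, so
their female-to-male allele proportion ratios form an empirical null
distribution for the statistic.  The default calibration takes the maximum
PAR ratio and rounds up to the next integer strictly above it; a variant is
"high ratio" only when its ratio is *strictly* greater than the threshold
and it lies on the non-pseudoautosomal X (autosomal flagging is opt-in,
since autosomal discovery thresholds are not yet established).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from fractions import Fraction
from enum import Enum
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .io import VariantRecord
from .ratio import RatioResult, compute_ratio, score_counts
from .regions import Region

__all__ = [
    "ThresholdMethod",
    "ThresholdResult",
    "calibrate_threshold",
    "flag_high_ratio",
    "score_and_flag",
]

PAR_REGIONS = (Region.PAR1, Region.PAR2)


class ThresholdMethod(str, Enum):
    PAR_MAX = "par-max"
    PAR_QUANTILE = "par-quantile"
    FIXED = "fixed"


@dataclass(frozen=True)
class ThresholdResult:
    """A calibrated high-ratio threshold and its provenance."""

    threshold: float
    n_par: int
    max_par_ratio: float
    method: ThresholdMethod
    quantile: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_par": self.n_par,
            "max_par_ratio": self.max_par_ratio,
            "method": self.method.value,
            "quantile": self.quantile,
        }


def calibrate_threshold(
    records: Sequence[VariantRecord],
    method: ThresholdMethod = ThresholdMethod.PAR_MAX,
    quantile: Optional[float] = None,
    fixed_value: Optional[float] = None,
    integer_ceiling: bool = True,
) -> ThresholdResult:
    """Derive the high-ratio threshold from the pseudoautosomal null.

    ``PAR_MAX`` returns the smallest integer strictly greater than the
    maximum PAR ratio (``integer_ceiling=False`` returns the raw maximum);
    ``PAR_QUANTILE`` returns the requested upper quantile of the PAR ratios;
    ``FIXED`` echoes ``fixed_value``.
    """
    method = ThresholdMethod(method)
    # Exact rational arithmetic: the integer-ceiling rule must not be
    # perturbed by float rounding when a PAR ratio is exactly integral.
    par_counts = [r.counts for r in records if r.region in PAR_REGIONS]
    par_exact = [
        Fraction((c.v_f + 1) * (c.a_m + 1), (c.a_f + 1) * (c.v_m + 1)) for c in par_counts
    ]
    par_ratios = [compute_ratio(c) for c in par_counts]
    n_par = len(par_ratios)
    max_par = float(max(par_exact)) if par_exact else float("nan")

    if method is ThresholdMethod.FIXED:
        if fixed_value is None or fixed_value <= 0:
            raise ValueError("FIXED method requires a positive fixed_value")
        return ThresholdResult(float(fixed_value), n_par, max_par, method)

    if n_par == 0:
        raise ValueError(
            "no pseudoautosomal records available for PAR-based calibration; "
            "supply PAR variants or use the FIXED method with an explicit threshold"
        )

    if method is ThresholdMethod.PAR_MAX:
        exact_max = max(par_exact)
        threshold = float(math.floor(exact_max) + 1) if integer_ceiling else max_par
        return ThresholdResult(threshold, n_par, max_par, method)

    if quantile is None or not (0 < quantile <= 1):
        raise ValueError("PAR_QUANTILE requires a quantile in (0, 1]")
    threshold = float(np.quantile(np.asarray(par_ratios), quantile))
    return ThresholdResult(threshold, n_par, max_par, method, quantile=quantile)


def flag_high_ratio(
    results: Sequence[Tuple[VariantRecord, RatioResult]],
    threshold: float,
    include_autosomes: bool = False,
) -> List[RatioResult]:
    """Set ``high_ratio`` on scored results: strictly above threshold, non-PAR X.

    "Above" is strict: a ratio exactly equal to the threshold is not
    flagged.  PAR variants are never flagged (they define the null);
    ``include_autosomes`` extends flagging to autosomal variants.
    """
    flagged_regions = {Region.NONPAR_X}
    if include_autosomes:
        flagged_regions.add(Region.AUTOSOME)
    out: List[RatioResult] = []
    for record, result in results:
        flag = record.region in flagged_regions and result.ratio > threshold
        out.append(replace(result, high_ratio=flag))
    return out


def score_and_flag(
    records: Sequence[VariantRecord],
    threshold: float,
    include_autosomes: bool = False,
    rarity_fraction: float = 1e-4,
) -> List[RatioResult]:
    """Compute ratio, log2 ratio and carrier profile, then apply the flag."""
    scored = [(r, score_counts(r.variant_id, r.counts, rarity_fraction)) for r in records]
    return flag_high_ratio(scored, threshold, include_autosomes=include_autosomes)
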