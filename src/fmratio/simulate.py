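"""Synthetic gnomAD-style cohorts under sex- and genotype-specific viability.

The generative model: each variant has a population minor-allele frequency
``p``; genotypes are drawn under Hardy–Weinberg proportions; viability
selection then acts once, before ascertainment, mimicking premature death
depleting an adult sequencing cohort.  For a causal non-pseudoautosomal X
variant, hemizygous carrier males survive with probability ``w_m``,
homozygous females with ``w_f_hom`` and heterozygous females with
``w_f_het``; the defaults (``w_m = 0``, ``w_f_hom = 0``, ``w_f_het = 1``)
encode a variant that is fully lethal in males and homozygous females but
harmless in heterozygous females — the mechanism the high-ratio statistic
is designed to detect.  Null variants (all of PAR, and the non-causal
remainder of non-PAR X) experience no selection.

Pseudoautosomal variants are simulated with diploid males (the gnomAD
structure: ``a_m = 2 x`` surviving males), non-PAR X with hemizygous males.
An optional autosomal mode emulates sex-differential carrier viability on
chromosome 21.

All randomness flows through one ``numpy.random.Generator`` (PCG64) seeded
from the config, so identical configs give identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .io import VariantRecord, filter_by_allele_count
from .ratio import SexStratifiedCounts
from .regions import GenomicRegionMap, Region
from .threshold import score_and_flag

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "DetectionPerformance",
    "simulate_cohort",
    "evaluate_detection",
    "write_truth_table",
]

RNG_ALGORITHM = "PCG64"  # pinned for cross-platform determinism


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated cohort.

    ``freq_dist`` is ``(kind, low, high)`` with kind ``"log_uniform"`` or
    ``"uniform"``; the default spectrum is log-uniform over [1e-4, 0.2].
    ``frac_par`` of variants are pseudoautosomal (always null);
    ``frac_causal`` of the non-PAR variants receive the sex-effect
    viabilities, the remainder are null.
    """

    n_males: int = 10_000
    n_females: int = 10_000
    n_variants: int = 1_000
    freq_dist: Tuple[str, float, float] = ("log_uniform", 1e-4, 0.2)
    w_m: float = 0.0
    w_f_het: float = 1.0
    w_f_hom: float = 0.0
    frac_par: float = 0.2
    frac_causal: float = 0.1
    seed: int = 0
    autosomal: bool = False

    def __post_init__(self) -> None:
        if self.n_males < 1 or self.n_females < 1:
            raise ValueError("population sizes must be >= 1")
        if self.n_variants < 0:
            raise ValueError("n_variants must be non-negative")
        for name in ("w_m", "w_f_het", "w_f_hom", "frac_par", "frac_causal"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        kind, low, high = self.freq_dist
        if kind not in ("log_uniform", "uniform"):
            raise ValueError(f"unknown freq_dist kind {kind!r}")
        if not (0.0 < low <= high < 1.0):
            raise ValueError(f"freq_dist bounds must satisfy 0 < low <= high < 1, got {low}, {high}")

    def metadata(self) -> dict:
        meta = {k: getattr(self, k) for k in self.__dataclass_fields__}
        meta["freq_dist"] = list(self.freq_dist)
        meta["rng_algorithm"] = RNG_ALGORITHM
        return meta


@dataclass(frozen=True)
class SimulatedTruth:
    """Ground truth for one simulated variant."""

    variant_id: str
    true_freq: float
    causal: bool
    region: Region


def _draw_freqs(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    kind, low, high = config.freq_dist
    if kind == "uniform":
        return rng.uniform(low, high, size=config.n_variants)
    return np.exp(rng.uniform(math.log(low), math.log(high), size=config.n_variants))


def _spread_positions(interval: Tuple[int, int], count: int) -> np.ndarray:
    """Evenly spaced integer positions inside a half-open interval."""
    if count == 0:
        return np.empty(0, dtype=int)
    return np.linspace(interval[0], interval[1] - 1, num=count, dtype=int)


def simulate_cohort(
    config: SimulationConfig,
) -> Tuple[List[VariantRecord], List[SimulatedTruth]]:
    """Simulate sex-stratified allele counts for a cohort of variants.

    Returns per-variant records (with region labels and zygosity counts)
    and the aligned ground truth.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_variants
    if n == 0:
        return [], []

    region_map = GenomicRegionMap.grch38()
    if config.autosomal:
        n_par1 = n_par2 = 0
        regions = [Region.AUTOSOME] * n
    else:
        n_par = int(round(config.frac_par * n))
        n_par1 = (n_par + 1) // 2
        n_par2 = n_par - n_par1
        regions = (
            [Region.PAR1] * n_par1 + [Region.PAR2] * n_par2 + [Region.NONPAR_X] * (n - n_par1 - n_par2)
        )
    causal_region = Region.AUTOSOME if config.autosomal else Region.NONPAR_X
    nonpar_idx = np.array([i for i, r in enumerate(regions) if r is causal_region], dtype=int)
    n_causal = int(round(config.frac_causal * nonpar_idx.size))

    p = _draw_freqs(rng, config)
    causal = np.zeros(n, dtype=bool)
    if n_causal:
        causal[rng.choice(nonpar_idx, size=n_causal, replace=False)] = True

    w_m_eff = np.where(causal, config.w_m, 1.0)
    w_het_eff = np.where(causal, config.w_f_het, 1.0)
    w_hom_eff = np.where(causal, config.w_f_hom, 1.0)
    het_given_not_hom = 2.0 * p / (1.0 + p)  # HWE: 2p(1-p) / (1 - p^2)

    # Females: always diploid.
    hom0 = rng.binomial(config.n_females, p * p)
    het0 = rng.binomial(config.n_females - hom0, het_given_not_hom)
    surv_hom_f = rng.binomial(hom0, w_hom_eff)
    surv_het_f = rng.binomial(het0, w_het_eff)
    wt_f = config.n_females - hom0 - het0
    a_f = 2 * (wt_f + surv_hom_f + surv_het_f)
    v_f = 2 * surv_hom_f + surv_het_f

    # Males, hemizygous branch (non-PAR X).
    carrier_m = rng.binomial(config.n_males, p)
    surv_carrier_m = rng.binomial(carrier_m, w_m_eff)
    a_m_hemi = config.n_males - carrier_m + surv_carrier_m
    v_m_hemi = surv_carrier_m

    # Males, diploid branch (PAR and autosomes); carrier viability w_m in
    # the autosomal mode, no effect for PAR nulls (causal is never PAR).
    hom0_m = rng.binomial(config.n_males, p * p)
    het0_m = rng.binomial(config.n_males - hom0_m, het_given_not_hom)
    surv_hom_m = rng.binomial(hom0_m, w_m_eff)
    surv_het_m = rng.binomial(het0_m, w_m_eff)
    wt_m = config.n_males - hom0_m - het0_m
    a_m_dip = 2 * (wt_m + surv_hom_m + surv_het_m)
    v_m_dip = 2 * surv_hom_m + surv_het_m

    hemizygous = np.array([r is Region.NONPAR_X for r in regions], dtype=bool)
    a_m = np.where(hemizygous, a_m_hemi, a_m_dip)
    v_m = np.where(hemizygous, v_m_hemi, v_m_dip)

    # Positions by region class (GRCh38 geometry; chr21 in autosomal mode).
    pos = np.zeros(n, dtype=int)
    if config.autosomal:
        pos[:] = _spread_positions((5_010_000, 46_700_000), n)
        chroms = np.array(["21"] * n, dtype=object)
    else:
        nonpar_x = (region_map.par1[1], region_map.par2[0])
        pos[:n_par1] = _spread_positions(region_map.par1, n_par1)
        pos[n_par1 : n_par1 + n_par2] = _spread_positions(region_map.par2, n_par2)
        pos[hemizygous] = _spread_positions(nonpar_x, int(hemizygous.sum()))
        chroms = np.array(["X"] * n, dtype=object)

    records: List[VariantRecord] = []
    truths: List[SimulatedTruth] = []
    for i in range(n):
        vid = f"sim{i:06d}"
        counts = SexStratifiedCounts(
            v_f=int(v_f[i]),
            a_f=int(a_f[i]),
            v_m=int(v_m[i]),
            a_m=int(a_m[i]),
            hom_f=int(surv_hom_f[i]),
            hemi_m=int(v_m[i]) if hemizygous[i] else None,
        )
        records.append(
            VariantRecord(
                variant_id=vid,
                chrom=str(chroms[i]),
                pos=int(pos[i]),
                ref="A",
                alt="G",
                counts=counts,
                region=regions[i],
            )
        )
        truths.append(
            SimulatedTruth(
                variant_id=vid, true_freq=float(p[i]), causal=bool(causal[i]), region=regions[i]
            )
        )
    return records, truths


def write_truth_table(truths: Sequence[SimulatedTruth], path: Union[str, Path]) -> None:
    """Write the ground-truth companion table (tab-separated)."""
    df = pd.DataFrame(
        {
            "variant_id": [t.variant_id for t in truths],
            "true_freq": [t.true_freq for t in truths],
            "causal": [t.causal for t in truths],
            "region": [t.region.value for t in truths],
        }
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class DetectionPerformance:
    """Operating characteristics of the high-ratio flag against ground truth.

    ``specificity`` is computed over all non-causal variants passing the
    allele-count filter; ``specificity_flaggable`` restricts the denominator
    to non-causal variants in flag-eligible regions (non-PAR X by default),
    the stringent calibration view (PAR variants can never be flagged under
    the default policy, so including them only dilutes the false-positive
    rate).
    """

    sensitivity: float
    specificity: float
    specificity_flaggable: float
    n_causal_eligible: int
    n_null_eligible: int
    n_null_flaggable: int
    flagged_causal: int
    flagged_null: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def evaluate_detection(
    records: Sequence[VariantRecord],
    truths: Sequence[SimulatedTruth],
    threshold: float,
    min_ac: int = 5,
    include_autosomes: bool = False,
) -> DetectionPerformance:
    """Sensitivity and specificity of flagging at a threshold.

    Only variants passing the allele-count filter enter the denominators.
    Sensitivity is NaN when no causal variant is eligible.
    """
    record_ids = {r.variant_id for r in records}
    truth_by_id = {t.variant_id: t for t in truths}
    if record_ids != set(truth_by_id):
        missing = record_ids.symmetric_difference(truth_by_id)
        raise ValueError(
            f"records and truth tables disagree on {len(missing)} variant ids "
            f"(e.g. {sorted(missing)[:3]})"
        )

    eligible = filter_by_allele_count(records, min_ac=min_ac)
    results = score_and_flag(eligible, threshold, include_autosomes=include_autosomes)
    flag_regions = {Region.NONPAR_X} | ({Region.AUTOSOME} if include_autosomes else set())

    n_causal = n_null = n_null_flaggable = flagged_causal = flagged_null = 0
    for record, result in zip(eligible, results):
        truth = truth_by_id[record.variant_id]
        if truth.causal:
            n_causal += 1
            flagged_causal += result.high_ratio
        else:
            n_null += 1
            n_null_flaggable += record.region in flag_regions
            flagged_null += result.high_ratio

    return DetectionPerformance(
        sensitivity=flagged_causal / n_causal if n_causal else float("nan"),
        specificity=1.0 - flagged_null / n_null if n_null else float("nan"),
        specificity_flaggable=(
            1.0 - flagged_null / n_null_flaggable if n_null_flaggable else float("nan")
        ),
        n_causal_eligible=n_causal,
        n_null_eligible=n_null,
        n_null_flaggable=n_null_flaggable,
        flagged_causal=flagged_causal,
        flagged_null=flagged_null,
    )
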