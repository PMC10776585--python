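"""The allele proportion ratio statistic and its derived quantities."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fmratio import (
    CarrierProfile,
    CountValidationError,
    SexStratifiedCounts,
    classify_carrier_profile,
    compute_ratio,
    log2_ratio,
    summarize_ratios,
)


def rational_ratio(v_f, a_f, v_m, a_m) -> Fraction:
    """Independent exact-arithmetic evaluation of the pseudocount ratio."""
    return (Fraction(v_f + 1, a_f + 1)) / (Fraction(v_m + 1, a_m + 1))


@st.composite
def counts_strategy(draw, max_total=2000):
    a_f = draw(st.integers(0, max_total))
    a_m = draw(st.integers(0, max_total))
    v_f = draw(st.integers(0, a_f))
    v_m = draw(st.integers(0, a_m))
    return SexStratifiedCounts(v_f=v_f, a_f=a_f, v_m=v_m, a_m=a_m)


class TestComputeRatio:
    @pytest.mark.parametrize(
        "v_f, a_f, v_m, a_m, expected, decimals",
        [
            (18736, 104056, 0, 38527, 6937.5, 1),  # male-lethal FMR1 variant
            (0, 100, 0, 100, 1.0, 10),  # symmetric zero-carrier case
            (5, 1000, 5, 500, 501 / 1001, 10),  # direct arithmetic
        ],
    )
    def test_known_values(self, v_f, a_f, v_m, a_m, expected, decimals):
        counts = SexStratifiedCounts(v_f=v_f, a_f=a_f, v_m=v_m, a_m=a_m)
        assert round(compute_ratio(counts), decimals) == pytest.approx(expected)

    def test_finite_at_all_zero_denominators(self):
        assert compute_ratio(SexStratifiedCounts(0, 0, 0, 0)) == 1.0

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(v_f=-1, a_f=10, v_m=0, a_m=10), "v_f"),
            (dict(v_f=11, a_f=10, v_m=0, a_m=10), "v_f"),
            (dict(v_f=0, a_f=10, v_m=5, a_m=4), "v_m"),
            (dict(v_f=4, a_f=10, v_m=0, a_m=10, hom_f=3), "hom_f"),
            (dict(v_f=4, a_f=10, v_m=2, a_m=10, hemi_m=3), "hemi_m"),
        ],
    )
    def test_invalid_counts_name_offending_field(self, kwargs, field):
        with pytest.raises(CountValidationError, match=field):
            SexStratifiedCounts(**kwargs)

    @given(counts_strategy())
    def test_swap_symmetry(self, counts):
        """Swapping sexes inverts the ratio exactly."""
        swapped = SexStratifiedCounts(counts.v_m, counts.a_m, counts.v_f, counts.a_f)
        assert compute_ratio(counts) * compute_ratio(swapped) == pytest.approx(1.0, rel=1e-12)

    @given(counts_strategy(max_total=500))
    def test_monotonicity_and_bound(self, counts):
        r = compute_ratio(counts)
        if counts.v_f < counts.a_f:
            more_f = SexStratifiedCounts(counts.v_f + 1, counts.a_f, counts.v_m, counts.a_m)
            assert compute_ratio(more_f) > r
        if counts.v_m < counts.a_m:
            more_m = SexStratifiedCounts(counts.v_f, counts.a_f, counts.v_m + 1, counts.a_m)
            assert compute_ratio(more_m) < r
        # exact in rational arithmetic; allow a few ulps of float slack
        assert r <= (counts.a_m + 1) * (1 + 1e-12)

    @given(counts_strategy())
    def test_matches_rational_oracle(self, counts):
        expected = rational_ratio(counts.v_f, counts.a_f, counts.v_m, counts.a_m)
        assert compute_ratio(counts) == pytest.approx(float(expected), rel=1e-12)


class TestLog2Ratio:
    @pytest.mark.parametrize("ratio, expected", [(1.0, 0.0), (2.0, 1.0), (0.5, -1.0)])
    def test_exact_values(self, ratio, expected):
        assert log2_ratio(ratio) == expected

    def test_worked_example_scale(self):
        assert log2_ratio(6937.5) == pytest.approx(math.log2(6937.5))
        assert 12.7 < log2_ratio(6937.5) < 12.8

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            log2_ratio(bad)


class TestCarrierProfile:
    def test_male_lethal_signature(self, rs201580891_counts):
        assert classify_carrier_profile(rs201580891_counts) is CarrierProfile.ONLY_HET_FEMALES

    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(v_f=0, a_f=100, v_m=0, a_m=100, hom_f=0), CarrierProfile.UNKNOWN),
            (dict(v_f=10, a_f=1000, v_m=0, a_m=500), CarrierProfile.NO_MALES),
            (dict(v_f=10, a_f=1000, v_m=0, a_m=500, hom_f=2), CarrierProfile.NO_MALES),
            # males and hom females both below the 1e-4 rarity default
            (dict(v_f=5, a_f=200000, v_m=1, a_m=100000, hom_f=1), CarrierProfile.MALES_AND_HOM_FEMALES_RARE),
            (dict(v_f=500, a_f=2000, v_m=300, a_m=1000, hom_f=100), CarrierProfile.UNRESTRICTED),
            # zygosity unknown with male carriers: rarity cannot be judged
            (dict(v_f=5, a_f=200000, v_m=1, a_m=100000), CarrierProfile.UNKNOWN),
        ],
    )
    def test_rule_table(self, kwargs, expected):
        assert classify_carrier_profile(SexStratifiedCounts(**kwargs)) is expected

    def test_rarity_fraction_is_configurable(self):
        counts = SexStratifiedCounts(v_f=500, a_f=2000, v_m=300, a_m=1000, hom_f=100)
        assert (
            classify_carrier_profile(counts, rarity_fraction=0.9)
            is CarrierProfile.MALES_AND_HOM_FEMALES_RARE
        )


class TestSummarizeRatios:
    def test_constant_collection(self):
        s = summarize_ratios([1.0, 1.0, 1.0])
        assert (s.n, s.mean_ratio, s.sd_ratio, s.min_ratio, s.max_ratio) == (3, 1.0, 0.0, 1.0, 1.0)
        assert s.mean_log2 == 0.0

    def test_hand_computed_pair(self):
        s = summarize_ratios([0.5, 2.0])
        assert s.mean_ratio == pytest.approx(1.25)
        assert s.sd_ratio == pytest.approx(np.std([0.5, 2.0], ddof=1))
        assert s.sd_ratio == pytest.approx(1.0607, abs=1e-4)
        assert (s.min_ratio, s.max_ratio) == (0.5, 2.0)
        assert s.mean_log2 == pytest.approx(0.0)  # log2 0.5 and 2 cancel

    def test_report_rounding_is_one_decimal(self):
        row = summarize_ratios([1.234, 2.345]).to_report_row()
        assert row["mean_ratio"] == round((1.234 + 2.345) / 2, 1)

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            summarize_ratios([])
        with pytest.raises(ValueError):
            summarize_ratios([1.0, 0.0])
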