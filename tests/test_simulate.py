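"""The viability-selection cohort simulator and its operating characteristics."""

import math

import numpy as np
import pytest

from fmratio import (
    CarrierProfile,
    SimulationConfig,
    classify_carrier_profile,
    compute_ratio,
    evaluate_detection,
    filter_by_allele_count,
    simulate_cohort,
    write_count_table,
    write_truth_table,
)
from fmratio.regions import Region


def null_config(**kw):
    defaults = dict(
        n_variants=2000,
        n_males=10_000,
        n_females=10_000,
        freq_dist=("log_uniform", 0.01, 0.2),
        w_m=1.0,
        w_f_het=1.0,
        w_f_hom=1.0,
        frac_par=0.2,
        frac_causal=0.0,
        seed=11,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSimulateCohort:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(w_m=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(n_males=0)
        with pytest.raises(ValueError):
            SimulationConfig(freq_dist=("log_uniform", 0.0, 0.2))

    def test_empty_cohort_yields_valid_artifacts(self, tmp_path):
        records, truths = simulate_cohort(null_config(n_variants=0))
        assert records == [] and truths == []
        write_count_table(records, tmp_path / "counts.tsv")
        write_truth_table(truths, tmp_path / "truth.tsv")
        assert (tmp_path / "counts.tsv").exists()

    def test_seed_reproducibility(self):
        config = null_config(frac_causal=0.3, w_m=0.1, w_f_hom=0.2, n_variants=500)
        a = simulate_cohort(config)
        b = simulate_cohort(config)
        assert a == b
        c = simulate_cohort(null_config(frac_causal=0.3, w_m=0.1, w_f_hom=0.2, n_variants=500, seed=12))
        assert c != a

    def test_conservation_and_region_invariants(self):
        records, truths = simulate_cohort(null_config(n_variants=1000, frac_causal=0.2, w_m=0.0))
        assert len(records) == 1000
        for rec, truth in zip(records, truths):
            c = rec.counts
            assert 0 <= c.v_m <= c.a_m and 0 <= c.v_f <= c.a_f
            assert 2 * c.hom_f <= c.v_f
            if rec.region is Region.NONPAR_X:
                assert c.hemi_m == c.v_m
            else:
                assert c.hemi_m is None
                assert c.a_m == 2 * 10_000  # diploid males in PAR
            if truth.causal:
                assert truth.region is Region.NONPAR_X
        par_frac = sum(r.region in (Region.PAR1, Region.PAR2) for r in records) / 1000
        assert par_frac == pytest.approx(0.2)

    def test_male_lethal_variant_reproduces_het_female_signature(self):
        """A fully male-lethal variant at p=0.09 leaves only het females,
        with a ratio of order 1e3 matching the analytic expectation."""
        config = SimulationConfig(
            n_variants=1,
            n_males=38_527,
            n_females=52_028,
            freq_dist=("uniform", 0.09, 0.09),
            w_m=0.0,
            w_f_hom=0.0,
            w_f_het=1.0,
            frac_par=0.0,
            frac_causal=1.0,
            seed=3,
        )
        records, truths = simulate_cohort(config)
        c = records[0].counts
        assert c.v_m == 0 and c.hom_f == 0
        assert classify_carrier_profile(c) is CarrierProfile.ONLY_HET_FEMALES
        ratio = compute_ratio(c)
        # E[R] ~ (2p(1-p)/(1-p^2)) / 2 * (a_m + 1) with a_m ~ n_m(1-p)
        p = 0.09
        a_m = config.n_males * (1 - p)
        expected = (2 * p / (1 + p)) / 2 * (a_m + 1)
        assert 1e3 < ratio < 1e4
        assert ratio == pytest.approx(expected, rel=0.1)

    def test_autosomal_mode_places_variants_on_chr21(self):
        records, truths = simulate_cohort(
            null_config(n_variants=100, autosomal=True, frac_causal=0.5, w_m=0.0)
        )
        assert all(r.chrom == "21" and r.region is Region.AUTOSOME for r in records)
        assert all(r.counts.a_m <= 2 * 10_000 for r in records)
        assert sum(t.causal for t in truths) == 50


class TestNullCalibrationProperties:
    def test_null_log2_ratios_symmetric_about_zero(self):
        """Sign test on non-zero log2 ratios under the no-effect null."""
        from scipy.stats import binomtest

        records, _ = simulate_cohort(null_config(n_variants=10_000))
        filtered = filter_by_allele_count(records)
        log2 = np.array([math.log2(compute_ratio(r.counts)) for r in filtered])
        nonzero = log2[log2 != 0]
        result = binomtest(int((nonzero > 0).sum()), len(nonzero), 0.5)
        assert result.pvalue > 0.01

    def test_median_causal_ratio_increases_with_male_lethality(self):
        medians = []
        for w_m in (1.0, 0.5, 0.1, 0.0):
            records, truths = simulate_cohort(
                null_config(n_variants=400, frac_causal=1.0, frac_par=0.0, w_m=w_m, seed=5)
            )
            causal_ids = {t.variant_id for t in truths if t.causal}
            ratios = [compute_ratio(r.counts) for r in records if r.variant_id in causal_ids]
            medians.append(float(np.median(ratios)))
        assert medians == sorted(medians)


class TestEvaluateDetection:
    def test_infinite_threshold_degenerate_case(self):
        records, truths = simulate_cohort(null_config(n_variants=500, frac_causal=0.5, w_m=0.0))
        perf = evaluate_detection(records, truths, threshold=math.inf)
        assert perf.sensitivity == 0.0
        assert perf.specificity == 1.0 and perf.specificity_flaggable == 1.0

    def test_id_mismatch_rejected(self):
        records, truths = simulate_cohort(null_config(n_variants=10))
        with pytest.raises(ValueError, match="variant ids"):
            evaluate_detection(records[:-1], truths, threshold=11.0)

    def test_confusion_counts_sum_to_eligible(self):
        records, truths = simulate_cohort(null_config(n_variants=2000, frac_causal=0.2, w_m=0.0))
        perf = evaluate_detection(records, truths, threshold=11.0)
        eligible = len(filter_by_allele_count(records))
        assert perf.n_causal_eligible + perf.n_null_eligible == eligible
        assert perf.flagged_causal <= perf.n_causal_eligible
        assert perf.flagged_null <= perf.n_null_flaggable <= perf.n_null_eligible
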