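"""Per-guide aggregation, bias census, stratification, knock-in statistics."""

import math

import numpy as np
import pytest

from mmejtools import (
    EmbryoProfile,
    StatsParams,
    TrialRecord,
    bias_census,
    hdr_fold_change,
    positive_rate,
    stratify_by_efficiency,
    summarize_guide,
)


def profile(guide_id, f_nhej, f_mmej, f_hdr=0.0, embryo_id="e1", f_unattributable=0.0):
    f_unedited = max(0.0, 100.0 - f_nhej - f_mmej - f_hdr - f_unattributable)
    return EmbryoProfile(
        embryo_id=embryo_id,
        guide_id=guide_id,
        f_nhej=f_nhej,
        f_mmej=f_mmej,
        f_hdr=f_hdr,
        f_unedited=f_unedited,
        f_unattributable=f_unattributable,
    )


class TestSummarizeGuide:
    def test_strong_mmej_bias_reference_point(self):
        """Mean frequencies 5.615 / 72.385 give a ratio printed as 0.077."""
        summary = summarize_guide([profile("g", 5.615, 72.385)])
        assert summary.ratio == pytest.approx(5.615 / 72.385)
        assert abs(summary.ratio - 0.077) <= 1e-3  # printed 3-decimal precision
        assert summary.bias_class == "MMEJ-biased"

    def test_zero_mmej_is_infinite_ratio_nhej_biased(self):
        summary = summarize_guide([profile("g", 20.0, 0.0)])
        assert summary.ratio == math.inf
        assert summary.bias_class == "NHEJ-biased"

    def test_both_zero_is_undefined(self):
        summary = summarize_guide([profile("g", 0.0, 0.0)])
        assert summary.ratio is None
        assert summary.bias_class == "undefined"

    def test_two_embryo_means(self):
        summaries = summarize_guide(
            [
                profile("g", 10.0, 30.0, embryo_id="e1"),
                profile("g", 20.0, 10.0, embryo_id="e2"),
            ]
        )
        assert summaries.mean_f_nhej == pytest.approx(15.0)
        assert summaries.mean_f_mmej == pytest.approx(20.0)
        assert summaries.ratio == pytest.approx(0.75)
        assert summaries.bias_class == "balanced"

    def test_ratio_invariant_under_proportional_mosaicism(self):
        """Uniformly rescaling allele frequencies leaves the ratio unchanged."""
        base = [
            profile("g", 10.0, 30.0, embryo_id="e1"),
            profile("g", 24.0, 12.0, embryo_id="e2"),
        ]
        scaled = [
            profile("g", p.f_nhej * 0.4, p.f_mmej * 0.4, embryo_id=p.embryo_id)
            for p in base
        ]
        assert summarize_guide(base).ratio == pytest.approx(
            summarize_guide(scaled).ratio
        )

    def test_empty_profiles_rejected(self):
        with pytest.raises(ValueError):
            summarize_guide([])

    def test_mixed_guides_rejected(self):
        with pytest.raises(ValueError):
            summarize_guide([profile("g1", 10, 10), profile("g2", 10, 10)])


def make_cohort(n_mmej, n_balanced, n_nhej, efficiencies=None):
    """Synthetic guide summaries with prescribed bias classes."""
    summaries = []
    specs = (
        [("MMEJ", 10.0, 40.0)] * n_mmej
        + [("BAL", 20.0, 20.0)] * n_balanced
        + [("NHEJ", 40.0, 10.0)] * n_nhej
    )
    for i, (label, f_nhej, f_mmej) in enumerate(specs):
        profiles = [profile(f"g{i:03d}", f_nhej, f_mmej)]
        if efficiencies is not None:
            # pin the mean efficiency by adjusting the unedited mass
            edited = efficiencies[i]
            scale = edited / (f_nhej + f_mmej)
            profiles = [profile(f"g{i:03d}", f_nhej * scale, f_mmej * scale)]
        summaries.append(summarize_guide(profiles))
    return summaries


class TestBiasCensus:
    def test_cohort_census_proportions(self):
        summaries = make_cohort(18, 31, 39)
        census = bias_census(summaries)
        assert census.counts["MMEJ-biased"] == 18
        assert census.n_total == 88
        assert census.proportion("MMEJ-biased") == 20.45
        assert census.proportion("balanced", of=("balanced", "NHEJ-biased")) == 44.29

    def test_single_class_is_100_percent(self):
        census = bias_census(make_cohort(5, 0, 0))
        assert census.proportion("MMEJ-biased") == 100.0

    def test_counts_sum_to_cohort_size(self):
        summaries = make_cohort(3, 4, 5)
        census = bias_census(summaries)
        assert sum(census.counts.values()) == len(summaries)


class TestStratifyByEfficiency:
    def test_low_and_high_strata_with_printed_counts(self):
        # 50 guides below the 66.7% split (8 MMEJ-biased), 38 at or above (10)
        efficiencies = [50.0] * 8 + [80.0] * 10 + [50.0] * 42 + [80.0] * 28
        summaries = make_cohort(18, 31, 39, efficiencies=efficiencies)
        strata = stratify_by_efficiency(summaries)
        assert (strata.n_low, strata.n_high) == (50, 38)
        assert strata.mmej_biased_low == 8
        assert strata.mmej_biased_high == 10
        assert strata.pct_low == 16.0
        assert round(strata.pct_high) == 26

    def test_strata_partition_the_cohort(self):
        summaries = make_cohort(4, 6, 2, efficiencies=list(np.linspace(10, 95, 12)))
        for threshold in (20.0, 50.0, 66.7, 90.0):
            strata = stratify_by_efficiency(
                summaries, StatsParams(efficiency_threshold=threshold)
            )
            assert strata.n_low + strata.n_high == len(summaries)

    def test_moving_threshold_shifts_guides_monotonically(self):
        summaries = make_cohort(4, 6, 2, efficiencies=list(np.linspace(10, 95, 12)))
        lows = [
            stratify_by_efficiency(summaries, StatsParams(efficiency_threshold=t)).n_low
            for t in (10.0, 30.0, 50.0, 70.0, 96.0)
        ]
        assert lows == sorted(lows)


class TestPositiveRate:
    @pytest.mark.parametrize(
        "positives,total,expected",
        [(6, 11, 54.55), (1, 16, 6.25), (4, 10, 40.0), (3, 7, 42.86), (0, 9, 0.0)],
    )
    def test_printed_rates(self, positives, total, expected):
        trial = TrialRecord("locus", "cati", "r1", positives, total)
        assert positive_rate(trial) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            TrialRecord("locus", "cati", "r1", 0, 0)


class TestHdrFoldChange:
    def test_single_pair_fold(self):
        trials = [
            TrialRecord("locusA", "baseline", "r1", 20, 100),
            TrialRecord("locusA", "cati", "r1", 48, 100),
        ]
        result = hdr_fold_change(trials)
        assert result.overall_fold == pytest.approx(2.4)

    def test_equal_arms_give_unit_fold(self):
        trials = []
        for locus in ("a", "b"):
            for rep in ("r1", "r2"):
                trials.append(TrialRecord(locus, "baseline", rep, 10, 50))
                trials.append(TrialRecord(locus, "cati", rep, 10, 50))
        assert hdr_fold_change(trials).overall_fold == pytest.approx(1.0)

    def test_zero_baseline_locus_excluded_and_reported(self):
        trials = [
            TrialRecord("dead", "baseline", "r1", 0, 50),
            TrialRecord("dead", "cati", "r1", 10, 50),
            TrialRecord("live", "baseline", "r1", 10, 50),
            TrialRecord("live", "cati", "r1", 25, 50),
        ]
        result = hdr_fold_change(trials)
        assert result.excluded_loci == ("dead",)
        assert result.overall_fold == pytest.approx(2.5)

    def test_no_valid_pairs_is_an_error(self):
        with pytest.raises(ValueError):
            hdr_fold_change([TrialRecord("only", "cati", "r1", 5, 10)])

    def test_recovers_known_fold_from_simulated_trials(self):
        """33 simulated replicate pairs with true fold 2.4 recover it within CI."""
        from mmejtools.synthetic_data import simulate_knockin_trials

        trials = simulate_knockin_trials(seed=5, true_fold=2.4)
        result = hdr_fold_change(trials)
        folds = result.per_replicate["fold"].to_numpy()
        se = folds.std(ddof=1) / np.sqrt(len(folds))
        assert result.n_pairs == 33
        assert abs(result.overall_fold - 2.4) <= 3 * se + 0.05


class TestConsistency:
    def test_recovery_error_shrinks_with_more_embryos(self):
        """Mean absolute error of recovered category means shrinks from n=10 to n=100."""
        from mmejtools.repair_classifier import classify_cohort
        from mmejtools.synthetic_data import SimulationConfig, simulate_cohort

        def mae(n_embryos):
            cohort = simulate_cohort(
                SimulationConfig(seed=31, n_guides=12, n_embryos=n_embryos)
            )
            _, profiles = classify_cohort(
                cohort.alleles, cohort.loci, cohort.guides, cohort.classifier_params
            )
            weights = cohort.config.category_weights
            expected = {
                "nhej": 100 * (weights["nhej_insertion"] + weights["nhej_deletion"]),
                "mmej": 100 * weights["mmej_deletion"],
                "hdr": 100 * weights["hdr"],
            }
            by_guide = {}
            for p in profiles:
                by_guide.setdefault(p.guide_id, []).append(p)
            errors = []
            for group in by_guide.values():
                summary = summarize_guide(group)
                errors += [
                    abs(summary.mean_f_nhej - expected["nhej"]),
                    abs(summary.mean_f_mmej - expected["mmej"]),
                    abs(summary.mean_f_hdr - expected["hdr"]),
                ]
            return float(np.mean(errors))

        assert mae(100) < mae(10)
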