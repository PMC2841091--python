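"""Performance metrics: call rate arithmetic, truth comparison, triage."""

import numpy as np
import pytest

from resarray.design import BASES
from resarray.report import (
    call_rate,
    compare_to_truth,
    exons_to_sequence,
    gstack_intensity_summary,
)
from resarray.simulate import SimParams, simulate_batch
from tests.test_filters import calls_from_pattern
from tests.test_simulate import NOISELESS, hom_ref_truth


class TestCallRate:
    @pytest.mark.parametrize(
        "n_nocalls, n_bases, expected",
        [
            (563, 26292, 97.9),
            (103, 26292, 99.6),
            (781, 25187, 96.9),
            (101, 25187, 99.6),
            (0, 25187, 100.0),
        ],
    )
    def test_reported_rates_recompute_from_their_fractions(
        self, n_nocalls, n_bases, expected
    ):
        assert call_rate(n_nocalls, n_bases) == expected

    def test_zero_bases_rejected(self):
        with pytest.raises(ValueError):
            call_rate(0, 0)


class TestCompareToTruth:
    def test_perfect_calls_score_perfectly(self, small_design):
        truth = hom_ref_truth(small_design)
        calls = calls_from_pattern(small_design, ["w"] * small_design.n_positions)
        rep = compare_to_truth(calls, truth, small_design)
        assert rep.call_rate == 100.0
        assert rep.accuracy == 100.0
        assert rep.fp_total == rep.fn_total == 0

    def test_hand_counted_toy(self, small_design):
        """10 effective outcomes: 1 FP, 1 N, 8 correct on the first 10 positions
        (remaining positions wild-type and correct)."""
        truth = hom_ref_truth(small_design)
        n = small_design.n_positions
        pattern = ["w"] * n
        pattern[0] = "v"      # false positive (truth hom-ref)
        pattern[1] = "N"
        calls = calls_from_pattern(small_design, pattern)
        rep = compare_to_truth(calls, truth, small_design)
        assert rep.n_nocalls == 1
        assert rep.fp_total == 1
        assert rep.accuracy == pytest.approx(100.0 * (n - 2) / (n - 1))
        assert rep.variant_fp_rate == 100.0

    def test_batch_average_variant_fn_rate_matches_fraction(self, small_design):
        """15 true variants per array, one called wild-type on one of five
        arrays: mean variant FN rate = 0.2/15 = 1.3%."""
        rates = []
        rng = np.random.default_rng(5)
        sites = rng.choice(small_design.n_positions, size=15, replace=False)
        for k in range(5):
            truth = hom_ref_truth(small_design)
            pattern = ["w"] * small_design.n_positions
            for j, i in enumerate(sites):
                truth.zygosity[i] = 2
                truth.alt_idx[i] = (small_design.ref_idx[i] + 1) % 4
                pattern[i] = "v"
            if k == 0:
                pattern[sites[0]] = "w"      # one variant called wild-type
            calls = calls_from_pattern(small_design, pattern)
            rep = compare_to_truth(calls, truth, small_design)
            assert rep.n_true_variants == 15
            rates.append(rep.variant_fn_rate)
        assert round(float(np.mean(rates)), 1) == 1.3

    def test_zygosity_miss_not_counted_as_fp_or_fn(self, small_design):
        truth = hom_ref_truth(small_design)
        i = 4
        ref = small_design.ref_idx[i]
        alt = (ref + 1) % 4
        truth.zygosity[i] = 1                 # true het
        truth.alt_idx[i] = alt
        pattern = ["w"] * small_design.n_positions
        calls = calls_from_pattern(small_design, pattern)
        calls.loc[i, "call"] = BASES[alt]     # called hom-alt: right allele, wrong zygosity
        rep = compare_to_truth(calls, truth, small_design)
        assert rep.fp_total == 0 and rep.fn_total == 0
        assert rep.variant_breakdown["rare"]["het_hom_miss"] == 1
        assert rep.accuracy < 100.0

    def test_breakdown_partitions_true_variants(self, default_batch):
        _, result = default_batch
        for rep in result.reports:
            total = sum(
                sum(cats.values()) for cats in rep.variant_breakdown.values()
            )
            assert total == rep.n_true_variants

    def test_invariant_to_call_ordering(self, small_design, rng):
        truth = hom_ref_truth(small_design)
        pattern = ["w"] * small_design.n_positions
        pattern[3] = "N"
        pattern[9] = "v"
        calls = calls_from_pattern(small_design, pattern)
        shuffled = calls.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a = compare_to_truth(calls, truth, small_design)
        b = compare_to_truth(shuffled, truth, small_design)
        assert a.to_series().equals(b.to_series())


class TestExonTriage:
    def test_all_wildtype_needs_no_followup(self, small_design):
        calls = calls_from_pattern(small_design, ["w"] * small_design.n_positions)
        followup, total = exons_to_sequence(calls, small_design)
        assert followup == 0 and total == 3

    def test_single_nocall_flags_its_exon(self, small_design):
        pattern = ["w"] * small_design.n_positions
        pattern[60] = "N"              # inside the second fragment
        followup, _ = exons_to_sequence(calls_from_pattern(small_design, pattern), small_design)
        assert followup == 1

    def test_rescue_reduces_followup_exons(self, default_batch):
        _, result = default_batch
        before = np.mean(
            [exons_to_sequence(c, result.design)[0] for c in result.primary_calls]
        )
        after = np.mean([r.exons_followup for r in result.reports])
        assert after < before


class TestGStackSummary:
    def test_uniform_affinity_noiseless_groups_equal(self, small_design):
        params = SimParams(
            seed=3, beta_g=1e-12, beta_c=0.0, beta_stack=1.0, **NOISELESS
        )
        (sample,) = simulate_batch(small_design, [hom_ref_truth(small_design)], params)
        summary = gstack_intensity_summary(sample, small_design)
        means = summary.by_content["mean_peak"]
        assert means.max() - means.min() < 1e-6 * means.mean()

    def test_peak_declines_faster_in_g_than_in_c(self, default_batch):
        """The G-content slope of log mean peak intensity is steeper
        (more negative) than the C-content slope."""
        _, result = default_batch
        summary = gstack_intensity_summary(result.samples[0], result.design)
        df = summary.by_content[summary.by_content["n"] >= 30]

        def mean_slope(var, other):
            slopes = []
            for _, grp in df.groupby(other):
                if grp[var].nunique() >= 4:
                    slopes.append(
                        np.polyfit(grp[var], np.log(grp["mean_peak"]), 1)[0]
                    )
            return float(np.mean(slopes))

        slope_g = mean_slope("g_count", "c_count")
        slope_c = mean_slope("c_count", "g_count")
        assert slope_g < slope_c <= 0.05
        assert slope_g < 0

    def test_gstack_group_below_no_stack_at_matched_g(self, default_batch):
        _, result = default_batch
        summary = gstack_intensity_summary(result.samples[0], result.design)
        df = summary.by_stack
        pivot = df.pivot_table(index="g_count", columns="stack_class",
                               values="mean_peak")
        counts = df.pivot_table(index="g_count", columns="stack_class", values="n")
        both = pivot.dropna(subset=["g_stack", "none"])
        both = both[(counts.loc[both.index, "g_stack"] >= 20)
                    & (counts.loc[both.index, "none"] >= 20)]
        assert len(both) >= 2
        assert (both["g_stack"] < both["none"]).all()
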