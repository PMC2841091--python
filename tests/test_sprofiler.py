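"""sPROFILER: threshold fitting, w-scaling, rescue and stretch re-examination."""

import numpy as np
import pandas as pd
import pytest

from resarray.caller import CALL_COLUMNS, N_CALL
from resarray.design import BASES
from resarray.simulate import SampleIntensities
from resarray.sprofiler import (
    FittingError,
    ThresholdModel,
    fit_thresholds,
    reexamine_wildtype_in_stretches,
    resolve_no_calls,
    wildtype_proportion,
)


def oracle_quantile(xs, q):
    """Sort-and-interpolate order-statistic quantile, written from scratch."""
    xs = sorted(xs)
    h = q * (len(xs) - 1)
    lo = int(np.floor(h))
    if lo + 1 == len(xs):
        return xs[-1]
    return xs[lo] + (h - lo) * (xs[lo + 1] - xs[lo])


def make_ratio_sample(design, ratios):
    """Intensities whose per-strand peak/second ratio at position i is ratios[i],
    with the reference base always ranked first."""
    n = design.n_positions
    values = np.zeros((n, 2, 4))
    for i in range(n):
        ref = design.ref_idx[i]
        others = [b for b in range(4) if b != ref]
        for s in range(2):
            values[i, s, ref] = 100.0 * ratios[i]
            values[i, s, others[0]] = 100.0
            values[i, s, others[1]] = 50.0
            values[i, s, others[2]] = 25.0
    return SampleIntensities(array_id="t", values=values)


def wildtype_calls(design, array_id="t"):
    refs = [BASES[b] for b in design.ref_idx]
    return pd.DataFrame(
        {
            "array_id": array_id,
            "pos": design.positions,
            "ref": refs,
            "call": refs,
            "quality": 10.0,
            "source": "primary",
            "flags": "",
        },
        columns=CALL_COLUMNS,
    )


class TestFitThresholds:
    def test_degenerate_distribution_returns_that_ratio(self, small_design):
        sample = make_ratio_sample(small_design, np.full(small_design.n_positions, 4.0))
        calls = wildtype_calls(small_design)
        for q in (0.01, 0.05, 0.5):
            t_fwd, t_rev = fit_thresholds(sample, calls, small_design, q=q)
            assert t_fwd == pytest.approx(4.0)
            assert t_rev == pytest.approx(4.0)

    def test_quantile_matches_sort_and_interpolate_oracle(self, small_design, rng):
        ratios = rng.uniform(1.5, 30.0, size=small_design.n_positions)
        sample = make_ratio_sample(small_design, ratios)
        calls = wildtype_calls(small_design)
        for q in (0.02, 0.05, 0.25, 0.5):
            t_fwd, t_rev = fit_thresholds(sample, calls, small_design, q=q)
            expected = oracle_quantile(ratios, q)
            assert t_fwd == pytest.approx(expected)
            assert t_rev == pytest.approx(expected)

    def test_variant_called_positions_do_not_enter(self, small_design, rng):
        ratios = rng.uniform(1.5, 30.0, size=small_design.n_positions)
        sample = make_ratio_sample(small_design, ratios)
        calls = wildtype_calls(small_design)
        before = fit_thresholds(sample, calls, small_design)
        # give one position an extreme ratio but a variant call
        ratios2 = ratios.copy()
        ratios2[7] = 1000.0
        sample2 = make_ratio_sample(small_design, ratios2)
        calls2 = calls.copy()
        alt = BASES[(small_design.ref_idx[7] + 1) % 4]
        calls2.loc[7, "call"] = alt
        ratios_wt = np.delete(ratios, 7)
        expected = oracle_quantile(ratios_wt, 0.05)
        t_fwd, _ = fit_thresholds(sample2, calls2, small_design)
        assert t_fwd == pytest.approx(expected)
        assert abs(t_fwd - before[0]) < 0.5  # removing one mid ratio barely moves t

    def test_bad_quantile_rejected(self, small_design):
        sample = make_ratio_sample(small_design, np.full(small_design.n_positions, 4.0))
        calls = wildtype_calls(small_design)
        for q in (0, -0.1, 0.6, 1.0):
            with pytest.raises(ValueError):
                fit_thresholds(sample, calls, small_design, q=q)

    def test_too_few_wildtype_bases_raises(self, small_design):
        sample = make_ratio_sample(small_design, np.full(small_design.n_positions, 4.0))
        calls = wildtype_calls(small_design)
        calls.loc[calls.index[50:], "call"] = N_CALL
        with pytest.raises(FittingError):
            fit_thresholds(sample, calls, small_design)


class TestWildtypeProportion:
    def _batch(self, calls_per_array):
        out = []
        for spec in calls_per_array:
            out.append(pd.DataFrame({"ref": ["A"], "call": [spec]}))
        return out

    def test_all_wildtype(self):
        w = wildtype_proportion(self._batch(["A"] * 10))
        assert w[0] == pytest.approx(11 / 12)

    def test_all_variant_maximally_conservative(self):
        w = wildtype_proportion(self._batch(["C"] * 10))
        assert w[0] == pytest.approx(1 / 12)
        model = ThresholdModel(t_fwd=4, t_rev=4, alpha=1.0, w=w)
        # effective threshold approaches (1 + alpha) * t
        assert 4 * (1 + 1.0 * (1 - 1 / 12)) == pytest.approx(7.667, abs=1e-3)

    def test_uncalled_positions_get_half(self):
        w = wildtype_proportion(self._batch([N_CALL] * 5))
        assert w[0] == pytest.approx(0.5)

    def test_requires_two_arrays(self):
        with pytest.raises(ValueError):
            wildtype_proportion(self._batch(["A"]))


class TestResolveNoCalls:
    def _setup(self, small_design, noisy_fwd_at, ratio=8.0):
        """Clean sample everywhere; at `noisy_fwd_at` the fwd strand is flat
        (G-stack-like failure) while rev keeps a clear reference signature."""
        n = small_design.n_positions
        sample = make_ratio_sample(small_design, np.full(n, ratio))
        for i in noisy_fwd_at:
            sample.values[i, 0, :] = [100.0, 99.0, 98.0, 97.0]
        calls = wildtype_calls(small_design)
        for i in noisy_fwd_at:
            calls.loc[i, "call"] = N_CALL
        model = ThresholdModel(t_fwd=4.0, t_rev=4.0, alpha=1.0, w=np.ones(n))
        return sample, calls, model

    def test_single_strand_rescue_to_wildtype(self, small_design):
        sample, calls, model = self._setup(small_design, [5])
        out, log = resolve_no_calls(sample, calls, model, small_design)
        assert out.loc[5, "call"] == out.loc[5, "ref"]
        assert out.loc[5, "source"] == "sprofiler"
        row = log.iloc[0]
        assert row["strand_used"] == "rev"
        assert row["ratio"] == pytest.approx(8.0)

    def test_no_ref_peak_remains_nocall_in_wildtype_only(self, small_design):
        sample, calls, model = self._setup(small_design, [5])
        # rewrite both strands so the peak is a fixed alternate base
        ref = small_design.ref_idx[5]
        alt = (ref + 1) % 4
        for s in range(2):
            sample.values[5, s, :] = 1.0
            sample.values[5, s, alt] = 500.0
        out, _ = resolve_no_calls(sample, calls, model, small_design)
        assert out.loc[5, "call"] == N_CALL

    def test_variant_assign_mode_flags_for_confirmation(self, small_design):
        sample, calls, model = self._setup(small_design, [5])
        ref = small_design.ref_idx[5]
        alt = (ref + 1) % 4
        for s in range(2):
            sample.values[5, s, :] = 1.0
            sample.values[5, s, alt] = 500.0
        out, _ = resolve_no_calls(
            sample, calls, model, small_design, mode="with_variant_assign"
        )
        assert out.loc[5, "call"] == BASES[alt]
        assert "requires_confirmation" in out.loc[5, "flags"]

    def test_contradicting_strands_stay_nocall_in_variant_mode(self, small_design):
        sample, calls, model = self._setup(small_design, [5])
        ref = small_design.ref_idx[5]
        alt1, alt2 = [(ref + k) % 4 for k in (1, 2)]
        sample.values[5, 0, :] = 1.0
        sample.values[5, 0, alt1] = 500.0
        sample.values[5, 1, :] = 1.0
        sample.values[5, 1, alt2] = 500.0
        out, _ = resolve_no_calls(
            sample, calls, model, small_design, mode="with_variant_assign"
        )
        assert out.loc[5, "call"] == N_CALL

    def test_non_interference_with_existing_calls(self, default_batch):
        """No variant call and no out-of-stretch wild-type call is modified."""
        _, result = default_batch
        for before, after in zip(result.primary_calls, result.resolved_calls):
            called = (before["call"] != N_CALL).to_numpy()
            untouched = ~after.loc[called, "flags"].str.contains("stretch_reexam")
            assert (
                before.loc[called, "call"][untouched.to_numpy()]
                == after.loc[called, "call"][untouched.to_numpy()]
            ).all()
            # wildtype_only mode never creates variant calls
            new = (before["call"] == N_CALL).to_numpy() & (after["call"] != N_CALL).to_numpy()
            assert (after.loc[new, "call"] == after.loc[new, "ref"]).all()
            assert (after.loc[new, "source"] == "sprofiler").all()

    def test_monotone_in_alpha_and_q(self, default_batch):
        cfg, result = default_batch
        design = result.design
        sample = result.samples[0]
        calls = result.primary_calls[0]
        w = result.models[0].w

        def n_resolved(q, alpha):
            t_fwd, t_rev = fit_thresholds(sample, calls, design, q=q, params=cfg.caller)
            model = ThresholdModel(t_fwd=t_fwd, t_rev=t_rev, q=q, alpha=alpha, w=w)
            out, _ = resolve_no_calls(sample, calls, model, design, params=cfg.caller)
            return int(((calls["call"] == N_CALL) & (out["call"] != N_CALL)).sum())

        base = n_resolved(0.05, 1.0)
        assert n_resolved(0.05, 2.0) <= base      # more conservative scaling
        assert n_resolved(0.01, 1.0) >= base      # lower quantile, looser threshold
        assert n_resolved(0.10, 1.0) <= base

    def test_limit_behavior_w_one_tiny_q(self, default_batch):
        """With w=1 and q->0 every no-call whose peak equals ref on a strand
        with ratio above the wild-type minimum is resolved."""
        cfg, result = default_batch
        design, sample, calls = result.design, result.samples[0], result.primary_calls[0]
        q = 1e-6
        t_fwd, t_rev = fit_thresholds(sample, calls, design, q=q, params=cfg.caller)
        model = ThresholdModel(t_fwd=t_fwd, t_rev=t_rev, q=q, alpha=1.0,
                               w=np.ones(design.n_positions))
        out, _ = resolve_no_calls(sample, calls, model, design, params=cfg.caller)
        from resarray.caller import strand_evidence

        peak, r1, _ = strand_evidence(sample, cfg.caller)
        eligible = (
            (calls["call"] == N_CALL).to_numpy()
            & (
                ((peak[:, 0] == design.ref_idx) & (r1[:, 0] >= t_fwd))
                | ((peak[:, 1] == design.ref_idx) & (r1[:, 1] >= t_rev))
            )
        )
        assert ((out["call"] != N_CALL).to_numpy()[eligible]).all()


class TestStretchReexamination:
    def _stretch_setup(self, small_design):
        n = small_design.n_positions
        sample = make_ratio_sample(small_design, np.full(n, 8.0))
        calls = wildtype_calls(small_design)
        model = ThresholdModel(t_fwd=4.0, t_rev=4.0, alpha=1.0, w=np.ones(n))
        return sample, calls, model

    def test_weak_wildtype_inside_stretch_demoted(self, small_design):
        sample, calls, model = self._stretch_setup(small_design)
        run = list(range(10, 24))         # 13 N + one interior wild-type at 16
        for i in run:
            if i != 16:
                calls.loc[i, "call"] = N_CALL
        sample.values[16, 0, :] = [100.0, 99.0, 98.0, 97.0]   # fails fwd test
        out = reexamine_wildtype_in_stretches(sample, calls, model, small_design)
        assert out.loc[16, "call"] == N_CALL
        assert "stretch_reexam" in out.loc[16, "flags"]

    def test_strong_wildtype_inside_stretch_survives(self, small_design):
        sample, calls, model = self._stretch_setup(small_design)
        for i in range(10, 24):
            if i != 16:
                calls.loc[i, "call"] = N_CALL
        out = reexamine_wildtype_in_stretches(sample, calls, model, small_design)
        assert out.loc[16, "call"] == out.loc[16, "ref"]

    def test_wildtype_outside_stretch_never_touched(self, small_design):
        sample, calls, model = self._stretch_setup(small_design)
        for i in range(10, 24):
            if i != 16:
                calls.loc[i, "call"] = N_CALL
        sample.values[40, 0, :] = [100.0, 99.0, 98.0, 97.0]   # weak but isolated
        out = reexamine_wildtype_in_stretches(sample, calls, model, small_design)
        assert out.loc[40, "call"] == out.loc[40, "ref"]

    def test_all_wildtype_input_unchanged(self, small_design):
        sample, calls, model = self._stretch_setup(small_design)
        out = reexamine_wildtype_in_stretches(sample, calls, model, small_design)
        pd.testing.assert_frame_equal(out, calls)

    def test_short_runs_below_min_run_ignored(self, small_design):
        sample, calls, model = self._stretch_setup(small_design)
        for i in (10, 11, 12, 14):        # 4 no-calls around a weak wild-type
            calls.loc[i, "call"] = N_CALL
        sample.values[13, 0, :] = [100.0, 99.0, 98.0, 97.0]
        out = reexamine_wildtype_in_stretches(sample, calls, model, small_design, min_run=5)
        assert out.loc[13, "call"] == out.loc[13, "ref"]
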