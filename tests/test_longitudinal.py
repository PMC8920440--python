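"""Delta changes, Mann-Whitney/paired tests, the methylation clock, mixed models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rejuvenomics as rj
from rejuvenomics.longitudinal import mann_whitney_deltas, paired_delta_test


def long_table(rows):
    return pd.DataFrame(rows, columns=["subject", "group", "timepoint", "value"])


class TestDeltaChange:
    def test_post_minus_pre(self):
        table = long_table([("m1", "g", "pre", 50.0), ("m1", "g", "post", 46.0)])
        deltas, incomplete = rj.delta_change(table)
        assert deltas.loc["m1", "delta"] == pytest.approx(-4.0)
        assert incomplete == []

    def test_equal_timepoints_zero_delta(self):
        table = long_table([("m1", "g", "pre", 33.0), ("m1", "g", "post", 33.0)])
        deltas, _ = rj.delta_change(table)
        assert deltas.loc["m1", "delta"] == 0.0

    def test_row_order_invariance_and_brute_force(self, rng):
        subjects = [f"m{i}" for i in range(40)]
        pre = rng.uniform(10, 90, 40)
        post = rng.uniform(10, 90, 40)
        rows = [(s, "g", "pre", a) for s, a in zip(subjects, pre)]
        rows += [(s, "g", "post", b) for s, b in zip(subjects, post)]
        table = long_table(rows)
        for _ in range(20):
            shuffled = table.sample(frac=1, random_state=rng.integers(1 << 31))
            deltas, _ = rj.delta_change(shuffled)
            expected = {s: b - a for s, a, b in zip(subjects, pre, post)}
            for s in subjects:
                assert deltas.loc[s, "delta"] == pytest.approx(expected[s])

    def test_swapping_timepoints_negates_delta(self):
        table = long_table([("m1", "g", "pre", 10.0), ("m1", "g", "post", 30.0)])
        fwd, _ = rj.delta_change(table)
        rev, _ = rj.delta_change(table, pre="post", post="pre")
        assert fwd.loc["m1", "delta"] == -rev.loc["m1", "delta"]

    def test_incomplete_subjects_listed_and_excluded(self):
        table = long_table(
            [("m1", "g", "pre", 1.0), ("m1", "g", "post", 2.0), ("m2", "g", "pre", 9.0)]
        )
        deltas, incomplete = rj.delta_change(table)
        assert incomplete == ["m2"]
        assert list(deltas.index) == ["m1"]

    def test_duplicate_rows_raise(self):
        table = long_table([("m1", "g", "pre", 1.0), ("m1", "g", "pre", 2.0)])
        with pytest.raises(ValueError, match="duplicated"):
            rj.delta_change(table)

    def test_no_complete_pairs_errors(self):
        table = long_table([("m1", "g", "pre", 1.0), ("m2", "g", "post", 2.0)])
        with pytest.raises(ValueError, match="complete"):
            rj.delta_change(table)


class TestMannWhitney:
    def test_extreme_4v3_configuration_exact(self):
        res = mann_whitney_deltas([4.0] * 4, [-4.0] * 3)
        assert res.p_value == pytest.approx(2 / 35)

    def test_matches_full_enumeration_small_samples(self, rng):
        """Exact p equals a direct enumeration over all group assignments
        (doubled smaller tail), including tied data."""
        from itertools import combinations

        for _ in range(15):
            n1, n2 = rng.integers(2, 6), rng.integers(2, 6)
            vals = np.round(rng.normal(size=n1 + n2), 1)  # rounding makes ties likely
            a, b = vals[:n1], vals[n1:]
            res = mann_whitney_deltas(a, b)
            ranks = stats.rankdata(vals)
            u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
            us = [
                ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
                for idx in combinations(range(n1 + n2), n1)
            ]
            us = np.array(us)
            ge = (us >= u_obs - 1e-12).mean()
            le = (us <= u_obs + 1e-12).mean()
            assert res.p_value == pytest.approx(min(1.0, 2 * min(ge, le)))

    def test_all_tied_values_p_one(self):
        res = mann_whitney_deltas([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0
        assert "all_tied" in res.flags

    def test_null_uniformity(self, rng):
        ps = []
        for _ in range(400):
            ps.append(mann_whitney_deltas(rng.normal(size=9), rng.normal(size=9)).p_value)
        # discrete p-values are super-uniform; check no excess of small ones
        assert (np.array(ps) < 0.05).mean() <= 0.08


class TestPairedDeltaTest:
    def test_all_zero_deltas_degenerate(self):
        res = paired_delta_test([0.0, 0.0, 0.0, 0.0])
        assert res.p_value == 1.0
        assert "degenerate_all_equal" in res.flags

    def test_normal_deltas_use_paired_t(self, rng):
        d = rng.normal(2.0, 1.0, size=12)
        res = paired_delta_test(d)
        assert res.method == "paired_t"
        ref = stats.ttest_1samp(d, 0.0)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_non_normal_deltas_fall_back_to_signed_rank(self, rng):
        d = np.concatenate([rng.normal(0, 0.05, 18), [40.0, -35.0]])  # gross outliers
        res = paired_delta_test(d)
        assert res.method == "wilcoxon_signed_rank"
        assert any("shapiro" in f for f in res.flags)

    def test_gaussian_null_p_uniform(self, rng):
        ps = [paired_delta_test(rng.normal(0, 1, 10)).p_value for _ in range(500)]
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.001


class TestClockFit:
    def test_perfect_line_endpoints(self):
        fit = rj.clock_fit([20.0, 37.5, 55.0], [10.0, 55.0, 100.0])
        assert fit.slope == pytest.approx(35 / 90)
        assert fit.r == pytest.approx(1.0)

    def test_matches_closed_form_normal_equations(self, rng):
        ages = rng.uniform(10, 100, 25)
        vals = rng.uniform(0, 100, 25)
        fit = rj.clock_fit(vals, ages)
        xc = ages - ages.mean()
        slope = (xc * (vals - vals.mean())).sum() / (xc**2).sum()
        intercept = vals.mean() - slope * ages.mean()
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_cpg_panel_averaged_before_fit(self, rng):
        ages = np.array([10.0, 40.0, 70.0, 100.0])
        panel = np.column_stack([ages * 0.3 + 15, ages * 0.3 + 25, ages * 0.3 + 20])
        fit = rj.clock_fit(panel, ages)
        assert fit.slope == pytest.approx(0.3)
        assert fit.intercept == pytest.approx(20.0)

    def test_flat_response_flagged(self):
        fit = rj.clock_fit([30.0, 30.0, 30.0], [10.0, 50.0, 90.0])
        assert fit.slope == 0.0
        assert "flat_response" in fit.flags

    def test_constant_ages_error(self):
        with pytest.raises(ValueError, match="constant ages"):
            rj.clock_fit([1.0, 2.0, 3.0], [50.0, 50.0, 50.0])

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(8)
        ages = np.linspace(10, 100, 40)
        vals = 15 + 0.389 * ages + rng.normal(0, 2.0, 40)
        fit = rj.clock_fit(vals, ages)
        assert abs(fit.slope - 0.389) < 3 * fit.stderr


class TestMixedModel:
    @staticmethod
    def paired_rows(rng, n, effect, between_sd, within_sd, metab="m"):
        rows = []
        for i in range(n):
            b = 50 + rng.normal(0, between_sd)
            rows.append(dict(metabolite=metab, specimen=f"sp{i}", timepoint="pre",
                             value=b + rng.normal(0, within_sd)))
            rows.append(dict(metabolite=metab, specimen=f"sp{i}", timepoint="post",
                             value=b + effect + rng.normal(0, within_sd)))
        return rows

    def test_zero_between_variance_agrees_with_paired_t(self):
        rng = np.random.default_rng(0)
        rows = self.paired_rows(rng, 20, effect=0.8, between_sd=0.0, within_sd=1.0)
        table = pd.DataFrame(rows)
        res = rj.metabolite_mixed_model(table, log_scale=False)[0]
        wide = table.pivot(index="specimen", columns="timepoint", values="value")
        t_ref = stats.ttest_1samp(wide["post"] - wide["pre"], 0.0).statistic
        assert abs(res.wald_statistic - t_ref) / abs(t_ref) < 0.10

    def test_large_between_variance_uses_random_intercept(self):
        rng = np.random.default_rng(1)
        rows = self.paired_rows(rng, 15, effect=1.0, between_sd=8.0, within_sd=0.5)
        res = rj.metabolite_mixed_model(pd.DataFrame(rows), log_scale=False)[0]
        assert res.method == "mixed"
        assert res.p_value < 0.01

    def test_single_timepoint_falls_back_flagged(self):
        rows = [
            dict(metabolite="m", specimen=f"sp{i}", timepoint=tp, value=10.0 + i + (tp == "post"))
            for i, tp in enumerate(["pre"] * 5 + ["post"] * 5)
        ]
        res = rj.metabolite_mixed_model(pd.DataFrame(rows), log_scale=False)[0]
        assert res.method == "fixed_fallback"
        assert "single_timepoint_per_specimen" in res.flags

    def test_null_effect_p_roughly_uniform(self):
        rng = np.random.default_rng(2)
        ps = []
        for k in range(60):
            rows = self.paired_rows(rng, 10, effect=0.0, between_sd=3.0, within_sd=1.0,
                                    metab=f"m{k}")
            ps.append(rj.metabolite_mixed_model(pd.DataFrame(rows), log_scale=False)[0].p_value)
        assert (np.array(ps) < 0.05).mean() <= 0.15
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_batch_fixed_effect_accepted(self):
        rng = np.random.default_rng(3)
        rows = self.paired_rows(rng, 8, effect=1.0, between_sd=2.0, within_sd=0.5)
        df = pd.DataFrame(rows)
        df["batch"] = ["e1"] * 8 + ["e2"] * 8
        res = rj.metabolite_mixed_model(df, log_scale=False, batch_col="batch")[0]
        assert np.isfinite(res.p_value)

    def test_stouffer_per_batch_combination(self):
        """Two batches with a consistent effect combine to stronger evidence
        than either batch alone."""
        rng = np.random.default_rng(4)
        rows = self.paired_rows(rng, 10, effect=0.8, between_sd=2.0, within_sd=0.7)
        df = pd.DataFrame(rows)
        df["batch"] = (["e1"] * 10 + ["e2"] * 10)  # split pre/post pairs per specimen
        df["batch"] = df["specimen"].str[2:].astype(int).lt(5).map({True: "e1", False: "e2"})
        res = rj.metabolite_mixed_model(
            df, log_scale=False, batch_col="batch", batch_mode="stouffer"
        )[0]
        assert res.method == "stouffer_per_batch"
        per_batch = [
            rj.metabolite_mixed_model(b, log_scale=False)[0].wald_statistic
            for _, b in df.groupby("batch")
        ]
        assert abs(res.wald_statistic) >= max(abs(z) for z in per_batch) - 1e-9
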