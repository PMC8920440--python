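"""Region definitions, CpG aggregation and the differential-methylation test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rejuvenomics as rj
from rejuvenomics.methylome import CpGMethylationTable


def make_table(chrom, pos, meth, unmeth, samples=None):
    meth = np.asarray(meth)
    samples = samples or [f"s{i}" for i in range(meth.shape[1])]
    return CpGMethylationTable(
        chrom=np.asarray(chrom), pos=np.asarray(pos), samples=samples,
        meth=meth, unmeth=np.asarray(unmeth),
    )


class TestDefinePromoters:
    def test_plus_strand_window(self):
        tss = pd.DataFrame({"chrom": ["chr1"], "pos": [10000], "strand": ["+"], "gene": ["A"]})
        out = rj.define_promoters(tss)
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (8000, 10500)

    def test_minus_strand_window_is_reflected(self):
        tss = pd.DataFrame({"chrom": ["chr1"], "pos": [10000], "strand": ["-"], "gene": ["A"]})
        out = rj.define_promoters(tss)
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (9501, 12001)

    def test_truncation_at_contig_start(self):
        tss = pd.DataFrame({"chrom": ["chr1"], "pos": [1500], "strand": ["+"], "gene": ["A"]})
        with pytest.warns(UserWarning, match="truncated"):
            out = rj.define_promoters(tss)
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (0, 2000)
        assert bool(out.loc[0, "truncated"])


class TestCallEnhancers:
    def setup_method(self):
        self.promoters = rj.define_promoters(
            pd.DataFrame({"chrom": ["chr1"], "pos": [10000], "strand": ["+"], "gene": ["A"]})
        )
        self.genes = pd.DataFrame({"chrom": ["chr1"], "pos": [10000], "gene": ["A"]})

    def test_promoter_overlap_excluded(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [8100], "end": [8300]})
        out = rj.call_enhancers(peaks, self.promoters, self.genes)
        assert len(out) == 0

    def test_distance_threshold_for_linking(self):
        peaks = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [900_000 + 10000, 1_200_000 + 10000],
             "end": [900_200 + 10000, 1_200_200 + 10000]}
        )
        out = rj.call_enhancers(peaks, self.promoters, self.genes)
        assert len(out) == 2
        assert out.iloc[0]["linked_gene"] == "A"
        assert out.iloc[1]["linked_gene"] is None

    def test_tie_broken_to_smaller_coordinate_and_matches_brute_force(self):
        genes = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [1000, 5000], "gene": ["L", "R"]})
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [2900], "end": [3101]})
        out = rj.call_enhancers(peaks, self.promoters.iloc[0:0], genes)
        # brute force: gap to each TSS
        s, e = 2900, 3101
        gaps = {g: max(s - p, p - (e - 1), 0) for g, p in zip(genes["gene"], genes["pos"])}
        assert gaps["L"] == gaps["R"]
        assert out.iloc[0]["linked_gene"] == "L"
        assert bool(out.iloc[0]["link_tie"])

    def test_empty_peaks_give_empty_set(self):
        peaks = pd.DataFrame({"chrom": [], "start": [], "end": []})
        out = rj.call_enhancers(peaks, self.promoters, self.genes)
        assert len(out) == 0


class TestAggregateRegions:
    regions = pd.DataFrame(
        {"region_id": ["r1"], "chrom": ["chr1"], "start": [0], "end": [100]}
    )

    def test_min_reads_filter_requires_all_samples(self):
        # CpG 1: coverage (5,5,5) kept; CpG 2: (5,4,5) dropped
        table = make_table(
            ["chr1", "chr1"], [10, 20],
            meth=[[5, 5, 5], [5, 4, 5]], unmeth=[[0, 0, 0], [0, 0, 0]],
        )
        out = rj.aggregate_regions(table, self.regions, min_reads=5)
        assert out.n_cpgs["r1"] == 1
        assert np.allclose(out.percent.loc["r1"], 100.0)

    def test_region_value_is_unweighted_cpg_mean(self):
        # one sample: CpG percentages 0 and 100 -> region value 50
        table = make_table(
            ["chr1", "chr1"], [10, 20], meth=[[0], [10]], unmeth=[[10], [0]], samples=["s0"]
        )
        out = rj.aggregate_regions(table, self.regions, min_reads=5)
        assert out.percent.loc["r1", "s0"] == pytest.approx(50.0)

    def test_matches_brute_force_on_random_table(self, rng):
        n_sites, n_samples = 120, 4
        pos = np.sort(rng.choice(5000, size=n_sites, replace=False))
        meth = rng.integers(0, 12, size=(n_sites, n_samples))
        unmeth = rng.integers(0, 12, size=(n_sites, n_samples))
        table = make_table(["chr1"] * n_sites, pos, meth, unmeth)
        regions = pd.DataFrame(
            {
                "region_id": [f"r{k}" for k in range(10)],
                "chrom": ["chr1"] * 10,
                "start": np.arange(10) * 500,
                "end": np.arange(1, 11) * 500,
            }
        )
        out = rj.aggregate_regions(table, regions, min_reads=5)
        cov = meth + unmeth
        for _, reg in regions.iterrows():
            expected = []
            for j in range(n_samples):
                vals = [
                    100.0 * meth[i, j] / cov[i, j]
                    for i in range(n_sites)
                    if reg["start"] <= pos[i] < reg["end"] and (cov[i] >= 5).all()
                ]
                expected.append(np.mean(vals) if vals else None)
            if expected[0] is None:
                assert reg["region_id"] in out.dropped_regions
            else:
                assert np.allclose(out.percent.loc[reg["region_id"]], expected)

    def test_permutation_invariance_in_sample_and_region_order(self, rng):
        n_sites = 60
        pos = np.sort(rng.choice(2000, size=n_sites, replace=False))
        meth = rng.integers(0, 15, size=(n_sites, 3))
        unmeth = rng.integers(0, 15, size=(n_sites, 3))
        table = make_table(["chr1"] * n_sites, pos, meth, unmeth)
        regions = pd.DataFrame(
            {"region_id": ["a", "b"], "chrom": ["chr1"] * 2, "start": [0, 1000], "end": [1000, 2000]}
        )
        out1 = rj.aggregate_regions(table, regions)
        perm = [2, 0, 1]
        table2 = make_table(
            ["chr1"] * n_sites, pos, meth[:, perm], unmeth[:, perm],
            samples=[f"s{i}" for i in perm],
        )
        out2 = rj.aggregate_regions(table2, regions.iloc[::-1])
        common = out1.percent.columns
        pd.testing.assert_frame_equal(
            out1.percent, out2.percent.loc[out1.percent.index, common], check_like=True
        )


def region_meth_from_counts(meth, total, samples):
    """Build a RegionMethylation directly from per-sample aggregated counts."""
    meth = pd.DataFrame(meth, columns=samples)
    total = pd.DataFrame(total, columns=samples)
    percent = 100.0 * meth / total
    return rj.RegionMethylation(
        percent=percent, meth=meth, total=total, n_cpgs=pd.Series(1, index=meth.index)
    )


class TestDMTest:
    groups = pd.Series(
        ["young"] * 3 + ["old"] * 3, index=["s0", "s1", "s2", "s3", "s4", "s5"]
    )

    def test_maximal_separation_significant_hypo(self):
        rm = region_meth_from_counts(
            [[20, 20, 20, 0, 0, 0]], [[20, 20, 20, 20, 20, 20]], list(self.groups.index)
        )
        out = rj.dm_test(rm, self.groups)
        row = out.iloc[0]
        assert row["delta_pp"] == pytest.approx(-100.0)
        assert row["p_raw"] < 0.05
        assert row["direction"] == "hypo"
        assert bool(row["significant"])

    def test_identical_groups_not_significant(self):
        rm = region_meth_from_counts(
            [[10, 10, 10, 10, 10, 10]], [[20, 20, 20, 20, 20, 20]], list(self.groups.index)
        )
        out = rj.dm_test(rm, self.groups)
        assert out.iloc[0]["delta_pp"] == pytest.approx(0.0)
        assert not out.iloc[0]["significant"]

    def test_all_zero_percent_degenerate(self):
        rm = region_meth_from_counts(
            [[0, 0, 0, 0, 0, 0]], [[20, 20, 20, 20, 20, 20]], list(self.groups.index)
        )
        out = rj.dm_test(rm, self.groups)
        assert out.iloc[0]["p_raw"] == 1.0
        assert bool(out.iloc[0]["degenerate"])

    def test_label_swap_flips_delta_not_p(self, rng):
        meth = rng.integers(0, 30, size=(20, 6))
        total = meth + rng.integers(1, 30, size=(20, 6))
        rm = region_meth_from_counts(meth, total, list(self.groups.index))
        fwd = rj.dm_test(rm, self.groups, group_a="young", group_b="old")
        rev = rj.dm_test(rm, self.groups, group_a="old", group_b="young")
        assert np.allclose(fwd["delta_pp"], -rev["delta_pp"])
        assert np.allclose(fwd["p_raw"], rev["p_raw"])

    def test_matches_statsmodels_binomial_glm(self, rng):
        """Closed-form LRT equals an independently fitted binomial GLM."""
        import statsmodels.api as sm

        meth = rng.integers(1, 25, size=(5, 6))
        total = meth + rng.integers(1, 25, size=(5, 6))
        rm = region_meth_from_counts(meth, total, list(self.groups.index))
        out = rj.dm_test(rm, self.groups)
        is_b = (self.groups == "old").to_numpy().astype(float)
        for i in range(5):
            endog = np.column_stack([meth[i], total[i] - meth[i]])
            full = sm.GLM(endog, sm.add_constant(is_b), family=sm.families.Binomial()).fit()
            null = sm.GLM(endog, np.ones((6, 1)), family=sm.families.Binomial()).fit()
            lr = 2 * (full.llf - null.llf)
            p_ref = stats.chi2.sf(lr, 1)
            assert out["p_raw"].iloc[i] == pytest.approx(p_ref, rel=1e-6)

    def test_quasi_variant_tames_overdispersion_false_positives(self, rng):
        """Beta-binomial (overdispersed) null data: the plain binomial LRT
        over-rejects, the quasi-binomial variant rejects much less often."""
        n_regions = 400
        p_true = rng.beta(8, 8, size=(n_regions, 6))  # per-sample wobble, no group effect
        total = np.full((n_regions, 6), 200)
        meth = rng.binomial(total, p_true)
        rm = region_meth_from_counts(meth, total, list(self.groups.index))
        plain = rj.dm_test(rm, self.groups)
        quasi = rj.dm_test(rm, self.groups, quasi=True)
        plain_rate = (plain["p_raw"] < 0.05).mean()
        quasi_rate = (quasi["p_raw"] < 0.05).mean()
        assert plain_rate > 0.2  # grossly anti-conservative without dispersion handling
        assert quasi_rate < plain_rate / 2
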