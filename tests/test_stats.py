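import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from trichomech import stats, synthio


def make_groups(rng, means, sds, ns):
    """Balanced/unbalanced 2×2 layout as a long DataFrame."""
    rows = []
    for (sp, loc), m, s, n in zip(
            [("a", "x"), ("a", "y"), ("b", "x"), ("b", "y")], means, sds, ns):
        rows.append(pd.DataFrame({"species": sp, "location": loc,
                                  "value": rng.normal(m, s, n)}))
    return pd.concat(rows, ignore_index=True)


class TestIQROutliers:
    def test_constant_data_no_outliers(self):
        assert not stats.iqr_outliers([3.0] * 6).any()

    def test_single_extreme_flagged(self):
        """{1..5, 100}: under linear-interpolation quantiles Q1 = 2.25,
        Q3 = 4.75, IQR = 2.5, fences [−1.5, 8.5] — only 100 falls outside."""
        vals = np.array([1, 2, 3, 4, 5, 100.0])
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        assert (q1, q3) == (2.25, 4.75)  # fixes the convention the rule uses
        mask = stats.iqr_outliers(vals)
        assert mask.tolist() == [False] * 5 + [True]

    def test_too_few_values_warns_and_passes_all(self):
        with pytest.warns(UserWarning):
            mask = stats.iqr_outliers([1.0, 2.0, 300.0])
        assert not mask.any()

    def test_order_and_affine_invariance(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(10, 1, 40), [50.0]])
        mask = stats.iqr_outliers(vals)
        perm = rng.permutation(len(vals))
        assert np.array_equal(stats.iqr_outliers(vals[perm]), mask[perm])
        assert np.array_equal(stats.iqr_outliers(3.0 * vals + 7.0), mask)


class TestGroupSummary:
    def test_constant_group_zero_sd(self):
        df = pd.DataFrame({"species": "a", "location": "x",
                           "value": [2.0, 2.0, 2.0, 2.0]})
        out = stats.group_summary(stats.GroupedMeasurements(df))
        assert out.loc[0, "sd"] == 0.0
        assert out.loc[0, "n"] == 4

    def test_counts_match_generator(self):
        df = synthio.gen_group_dataset(seed=2)
        gm = stats.GroupedMeasurements(
            df[["species", "location", "value"]]).flag_outliers()
        out = stats.group_summary(gm).set_index(["species", "location"])
        assert out.loc[("cultivar", "leaf"), "n"] == 16
        assert out.loc[("cultivar", "stem"), "n"] == 24
        assert out.loc[("wild", "leaf"), "n"] == 29
        assert out.loc[("wild", "stem"), "n"] == 10

    def test_pooled_mean_near_observed_grand_mean(self):
        """Across seeds, the pooled post-screening rupture force averages
        ≈6 μN, the observed grand mean."""
        means = []
        for seed in range(60):
            df = synthio.gen_group_dataset(seed=seed)
            gm = stats.GroupedMeasurements(
                df[["species", "location", "value"]]).flag_outliers()
            means.append(gm.clean()["value"].mean())
        assert np.mean(means) == pytest.approx(6.0, abs=1.0)


class TestTwoWayAnova:
    def test_balanced_layout_matches_hand_decomposition(self):
        """2×2 balanced layout with two observations per cell: SS terms from
        the classical mean decomposition."""
        df = pd.DataFrame({
            "species": ["a"] * 4 + ["b"] * 4,
            "location": (["x"] * 2 + ["y"] * 2) * 2,
            "value": [10.0, 12.0, 14.0, 16.0, 20.0, 22.0, 30.0, 32.0],
        })
        # cell means: ax=11, ay=15, bx=21, by=31; grand = 19.5
        # row means a=13, b=26; col means x=16, y=23
        n_per, grand = 2, 19.5
        ss_species = 4 * ((13 - grand) ** 2 + (26 - grand) ** 2)
        ss_location = 4 * ((16 - grand) ** 2 + (23 - grand) ** 2)
        ss_cells = n_per * sum((m - grand) ** 2 for m in (11, 15, 21, 31))
        ss_inter = ss_cells - ss_species - ss_location
        ss_resid = 8 * 1.0  # each value ±1 around its cell mean
        table = stats.two_way_anova(stats.GroupedMeasurements(df))
        assert table.loc["species", "sum_sq"] == pytest.approx(ss_species)
        assert table.loc["location", "sum_sq"] == pytest.approx(ss_location)
        assert table.loc["species:location", "sum_sq"] == pytest.approx(ss_inter)
        assert table.loc["residual", "sum_sq"] == pytest.approx(ss_resid)

    def test_null_pvalues_uniform(self):
        """Equal cell means: each factor's p-values over 500 replicates pass a
        KS test against U(0,1)."""
        rng = np.random.default_rng(31)
        ps = {"species": [], "location": [], "species:location": []}
        for _ in range(500):
            df = make_groups(rng, [5, 5, 5, 5], [2, 2, 2, 2], [16, 24, 29, 10])
            table = stats.two_way_anova(stats.GroupedMeasurements(df))
            for key in ps:
                ps[key].append(table.loc[key, "PR(>F)"])
        for key, vals in ps.items():
            assert sps.kstest(vals, "uniform").pvalue > 0.01, key

    def test_effects_detected_at_observed_sizes(self):
        """At the observed group means/SDs/ns the species×location structure
        is jointly significant (some factor p < 0.01) in ≥95% of 200 seeds."""
        hits = 0
        for seed in range(200):
            df = synthio.gen_group_dataset(seed=seed)
            gm = stats.GroupedMeasurements(
                df[["species", "location", "value"]]).flag_outliers()
            table = stats.two_way_anova(gm)
            pmin = table["PR(>F)"].iloc[:3].min()
            hits += pmin < 0.01
        assert hits >= 0.95 * 200

    def test_empty_cell_named_in_error(self):
        df = pd.DataFrame({
            "species": ["a"] * 8 + ["b"] * 4,
            "location": ["x"] * 4 + ["y"] * 4 + ["x"] * 4,
            "value": np.arange(12.0),
        })
        with pytest.raises(ValueError, match="location='y'"):
            stats.two_way_anova(stats.GroupedMeasurements(df))

    def test_total_ss_reconciles_on_balanced_design(self):
        rng = np.random.default_rng(8)
        df = make_groups(rng, [5, 7, 6, 9], [2, 2, 2, 2], [12, 12, 12, 12])
        table = stats.two_way_anova(stats.GroupedMeasurements(df))
        total = ((df["value"] - df["value"].mean()) ** 2).sum()
        assert table["sum_sq"].sum() == pytest.approx(total, rel=1e-9)


class TestTukey:
    def test_identical_groups_share_letter(self):
        rng = np.random.default_rng(3)
        base = rng.normal(5, 1, 20)
        df = pd.DataFrame({
            "species": ["a"] * 20 + ["b"] * 20,
            "location": "x",
            "value": np.concatenate([base, base]),
        })
        pairs, letters = stats.tukey_hsd(stats.GroupedMeasurements(df))
        assert pairs["p_adj"].iloc[0] > 0.9
        assert letters["a:x"] == letters["b:x"]

    def test_separated_group_gets_distinct_letter(self):
        rng = np.random.default_rng(4)
        df = make_groups(rng, [5, 20, 5, 5], [1, 1, 1, 1], [15, 15, 15, 15])
        _, letters = stats.tukey_hsd(stats.GroupedMeasurements(df))
        hot = letters["a:y"]
        assert all(set(hot).isdisjoint(set(v))
                   for k, v in letters.items() if k != "a:y")

    def test_singleton_group_excluded_with_warning(self):
        df = pd.DataFrame({
            "species": ["a"] * 10 + ["b"],
            "location": "x",
            "value": list(np.random.default_rng(0).normal(5, 1, 10)) + [6.0],
        })
        df2 = pd.concat([df, pd.DataFrame({
            "species": "c", "location": "x",
            "value": np.random.default_rng(1).normal(7, 1, 10)})],
            ignore_index=True)
        with pytest.warns(UserWarning, match="n=1"):
            pairs, letters = stats.tukey_hsd(stats.GroupedMeasurements(df2))
        assert "b:x" not in letters

    def test_letters_consistent_with_significance(self):
        """No two groups sharing a letter are significantly different."""
        for seed in range(10):
            df = synthio.gen_group_dataset(seed=seed)
            gm = stats.GroupedMeasurements(
                df[["species", "location", "value"]]).flag_outliers()
            pairs, letters = stats.tukey_hsd(gm)
            for _, r in pairs.iterrows():
                shared = set(letters[r["group1"]]) & set(letters[r["group2"]])
                if r["p_adj"] < stats.DEFAULT_ALPHA:
                    assert not shared

    def test_pairwise_symmetry(self):
        rng = np.random.default_rng(9)
        df = make_groups(rng, [5, 6, 7, 8], [2, 2, 2, 2], [10, 10, 10, 10])
        pairs, _ = stats.tukey_hsd(stats.GroupedMeasurements(df))
        seen = {}
        for _, r in pairs.iterrows():
            key = frozenset((r["group1"], r["group2"]))
            assert seen.setdefault(key, r["p_adj"]) == r["p_adj"]
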