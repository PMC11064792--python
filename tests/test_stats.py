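"""ART factorial ANOVA, ART-C contrasts, effect sizes, correlations, chi-square."""

import numpy as np
import pandas as pd
import pytest

from wrikit.stats import (
    art_anova_two_way,
    artc_posthoc,
    chi_square_independence,
    cohens_d,
    spearman_matrix,
)


def two_way_frame(rng, n_per_cell=15, group_shift=0.0, band_shift=(0.0, 0.0, 0.0)):
    rows = []
    for g, gs in (("ASD", group_shift), ("TD", 0.0)):
        for b, bs in zip(("3.5-4.5", "4.5-5.5", "5.5-6.5"), band_shift):
            y = rng.normal(gs + bs, 1.0, n_per_cell)
            rows += [{"group": g, "age_band": b, "y": v} for v in y]
    return pd.DataFrame(rows)


class TestArtAnova:
    def test_detects_pure_group_shift_only(self):
        rng = np.random.default_rng(21)
        df = two_way_frame(rng, group_shift=2.0)  # d = 2 on the group factor
        res = art_anova_two_way(df, "y")
        assert res["group"]["p"] < 0.001
        assert res["age_band"]["p"] > 0.05
        assert 0 <= res["group"]["partial_eta2"] <= 1

    def test_monotone_transform_invariance_in_oneway_collapse(self):
        """With one age level the alignment reduces to centring, so the ranks
        — and hence F — are unchanged by any strictly monotone transform.
        (In the full factorial design the alignment uses cell means, which a
        nonlinear transform shifts, so exact invariance holds only here.)"""
        rng = np.random.default_rng(6)
        df = two_way_frame(rng, group_shift=1.0)
        df = df[df.age_band == "4.5-5.5"]
        res_raw = art_anova_two_way(df, "y")
        res_exp = art_anova_two_way(df.assign(y=np.exp(df["y"])), "y")
        assert res_exp["group"]["F"] == pytest.approx(res_raw["group"]["F"], rel=1e-9)

    def test_single_age_level_matches_rank_transform_oneway(self):
        """Collapsed design: ART equals a plain one-way ANOVA on ranks."""
        from scipy.stats import f_oneway, rankdata

        rng = np.random.default_rng(7)
        df = two_way_frame(rng, group_shift=0.8)
        df = df[df.age_band == "3.5-4.5"]
        res = art_anova_two_way(df, "y")
        ranks = rankdata(df["y"])
        f_oracle, _ = f_oneway(ranks[df.group == "ASD"], ranks[df.group == "TD"])
        assert res["group"]["F"] == pytest.approx(f_oracle, rel=0.05)
        assert "age_band" not in res.effects

    def test_matches_statsmodels_factorial_anova_on_ranks(self):
        """The internal rank ANOVA agrees with an independent OLS route."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        from scipy.stats import rankdata

        rng = np.random.default_rng(8)
        df = two_way_frame(rng, group_shift=0.7, band_shift=(0, 0.3, 0.9))
        # unbalanced: drop some rows
        df = df.drop(df.index[::7]).reset_index(drop=True)
        res = art_anova_two_way(df, "y")

        # oracle: same alignment+ranking, ANOVA by statsmodels Type III
        from wrikit.stats import _cell_effects

        y = df["y"].to_numpy()
        resid, a_t, b_t, ab_t, *_ = _cell_effects(y, df["group"].to_numpy(), df["age_band"].to_numpy())
        for eff, aligned in (("group", resid + a_t), ("age_band", resid + b_t), ("interaction", resid + ab_t)):
            d2 = df.assign(r=rankdata(aligned))
            model = ols("r ~ C(group, Sum) * C(age_band, Sum)", data=d2).fit()
            tab = sm.stats.anova_lm(model, typ=3)
            key = {
                "group": "C(group, Sum)",
                "age_band": "C(age_band, Sum)",
                "interaction": "C(group, Sum):C(age_band, Sum)",
            }[eff]
            assert res[eff]["F"] == pytest.approx(tab.loc[key, "F"], rel=1e-6)

    def test_empty_cell_rejected(self):
        rng = np.random.default_rng(9)
        df = two_way_frame(rng)
        df = df[~((df.group == "ASD") & (df.age_band == "4.5-5.5"))]
        with pytest.raises(ValueError, match="empty design cell"):
            art_anova_two_way(df, "y")


class TestArtcPosthoc:
    def test_separated_groups_significant(self):
        rng = np.random.default_rng(10)
        df = two_way_frame(rng, group_shift=-50.0)  # non-overlapping ranges
        res = artc_posthoc(df, "y", "group")
        assert len(res) == 1
        assert res[0].contrast == "ASD - TD"
        assert res[0].p_adjusted < 0.001
        assert res[0].cohens_d < 0

    def test_three_levels_give_three_contrasts(self):
        rng = np.random.default_rng(11)
        df = two_way_frame(rng, band_shift=(0, 1, 2))
        res = artc_posthoc(df, "y", "age_band")
        assert len(res) == 3
        assert {r.contrast for r in res} == {
            "3.5-4.5 - 4.5-5.5", "3.5-4.5 - 5.5-6.5", "4.5-5.5 - 5.5-6.5",
        }

    def test_familywise_error_controlled_under_null(self):
        """With Bonferroni over 3 null contrasts, FWER stays near or below 5%."""
        rng = np.random.default_rng(12)
        n_rep = 400
        fw = 0
        for _ in range(n_rep):
            df = two_way_frame(rng, n_per_cell=10)
            res = artc_posthoc(df, "y", "age_band")
            fw += any(r.p_adjusted < 0.05 for r in res)
        rate = fw / n_rep
        assert rate < 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n_rep)


class TestCohensD:
    def test_unit_difference_unit_sd(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1, 1, 100_000)
        b = rng.normal(0, 1, 100_000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.02)

    def test_identical_samples_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert cohens_d(x, x) == 0.0

    def test_hand_computed_example(self):
        assert cohens_d([1, 2, 3], [4, 5, 6]) == pytest.approx(-3.0)

    def test_degenerate_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d([2.0, 2.0], [2.0, 2.0])


class TestSpearman:
    def test_monotone_pairs(self):
        f = pd.DataFrame({"m": [1, 2, 3, 4, 5]})
        s = pd.DataFrame({"up": [2, 4, 8, 16, 32], "down": [5, 4, 3, 2, 1]})
        rho, p = spearman_matrix(f, s)
        assert rho.loc["m", "up"] == pytest.approx(1.0)
        assert rho.loc["m", "down"] == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        f = pd.DataFrame({"x": [1, 2, 3, 4, 5]})
        s = pd.DataFrame({"y": [1, 3, 2, 5, 4]})
        rho, _ = spearman_matrix(f, s)
        assert rho.loc["x", "y"] == pytest.approx(0.8)

    def test_too_few_pairs_reported_missing(self):
        f = pd.DataFrame({"x": [1, 2, 3]})
        s = pd.DataFrame({"y": [1, 2, 3]})
        rho, p = spearman_matrix(f, s)
        assert np.isnan(rho.loc["x", "y"])

    def test_self_correlation_diagonal(self):
        f = pd.DataFrame({"x": [3, 1, 4, 1.5, 9]})
        rho, _ = spearman_matrix(f, f.copy())
        assert rho.loc["x", "x"] == pytest.approx(1.0)


class TestChiSquare:
    def test_study_demographics_table(self):
        chi2, p, df = chi_square_independence([[15, 19], [15, 20], [19, 20]])
        assert round(chi2, 2) == 0.29
        assert df == 2
        assert p == pytest.approx(0.87, abs=0.005)

    def test_proportional_table_zero(self):
        chi2, _, _ = chi_square_independence([[10, 20], [30, 60]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        chi2, _, df = chi_square_independence([[10, 20], [20, 10]])
        assert chi2 == pytest.approx(20 / 3, rel=1e-9)
        assert df == 1

    def test_permutation_invariance(self):
        a = np.array([[15, 19], [15, 20], [19, 20]])
        chi2_a, _, _ = chi_square_independence(a)
        chi2_b, _, _ = chi_square_independence(a[::-1, ::-1])
        assert chi2_a == pytest.approx(chi2_b)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_independence([[0, 0], [5, 5]])
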