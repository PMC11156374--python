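import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from oracles import bruteforce_fdr_bh, bruteforce_mixed_anova
from speechmarkers.stats import (
    chi2_2x2,
    correlate,
    correlation_grid,
    dunnett_t,
    fdr_bh,
    mixed_anova_2x2,
    one_tailed_t,
    outlier_screen,
    tukey_hsd,
    wide_to_long,
)


def make_long(y1, y2, levels=("a", "b"), groups=("patient", "HC")):
    rows = []
    for g, arr in zip(groups, (y1, y2)):
        for i, row in enumerate(np.atleast_2d(arr)):
            for s, v in zip(levels, row):
                rows.append(
                    {"participant_id": f"{g}{i}", "group": g, "level": s, "value": float(v)}
                )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_constant_within_difference_kills_interaction(self, rng):
        base1 = rng.normal(size=(8, 1))
        base2 = rng.normal(size=(8, 1))
        c = 0.37
        long = make_long(np.hstack([base1, base1 + c]), np.hstack([base2, base2 + c]))
        aov = mixed_anova_2x2(long)
        assert aov["interaction"].statistic == pytest.approx(0.0, abs=1e-18)

    def test_error_dfs_at_published_sample_size(self, rng):
        long = make_long(rng.normal(size=(21, 2)), rng.normal(size=(21, 2)))
        aov = mixed_anova_2x2(long)
        for eff in ("group", "within", "interaction"):
            assert aov[eff].df == (1, 40)

    def test_three_by_three_toy_table_matches_bruteforce(self):
        y1 = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 3.0]])
        y2 = np.array([[2.0, 1.0], [4.0, 2.0], [3.0, 2.0]])
        aov = mixed_anova_2x2(make_long(y1, y2))
        ref = bruteforce_mixed_anova(y1, y2)
        for eff in ("group", "within", "interaction"):
            assert aov[eff].statistic == pytest.approx(ref[eff]["F"], abs=1e-10)
            assert aov[eff].effect_size == pytest.approx(ref[eff]["np2"], abs=1e-10)

    def test_matches_pingouin_on_unbalanced_designs(self, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(5):
            n1, n2 = rng.integers(3, 12, size=2)
            long = make_long(rng.normal(size=(n1, 2)), rng.normal(size=(n2, 2)))
            aov = mixed_anova_2x2(long)
            ref = pg.mixed_anova(
                data=long, dv="value", within="level", subject="participant_id", between="group"
            ).set_index("Source")
            for eff, src in (("group", "group"), ("within", "level"), ("interaction", "Interaction")):
                assert aov[eff].statistic == pytest.approx(ref.loc[src, "F"], rel=1e-9)
                assert aov[eff].effect_size == pytest.approx(ref.loc[src, "np2"], rel=1e-9)

    def test_ss_additivity_on_random_tables(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 15))
            y1, y2 = rng.normal(size=(n, 2)), rng.normal(size=(n, 2))
            ref = bruteforce_mixed_anova(y1, y2)
            total = ((np.vstack([y1, y2]) - np.vstack([y1, y2]).mean()) ** 2).sum()
            assert ref["ss_total_check"] == pytest.approx(total, abs=1e-8)

    def test_missing_level_names_participant(self):
        long = make_long(np.ones((3, 2)), np.ones((3, 2)))
        long = long.drop(long[(long.participant_id == "patient1") & (long.level == "b")].index)
        with pytest.raises(ValueError, match="patient1"):
            mixed_anova_2x2(long)

    def test_degenerate_error_term_guard(self):
        # complementary levels: every subject mean identical
        y1 = np.array([[0.7, 0.3], [0.6, 0.4], [0.8, 0.2]])
        y2 = np.array([[0.4, 0.6], [0.5, 0.5], [0.3, 0.7]])
        with pytest.warns(UserWarning, match="degenerate"):
            aov = mixed_anova_2x2(make_long(y1, y2))
        assert aov["group"].statistic == 0.0 and aov["group"].p_raw == 1.0
        assert aov["interaction"].p_raw < 1.0


class TestTukey:
    def _long(self, rng, shift=0.0):
        return make_long(rng.normal(size=(6, 2)) + shift, rng.normal(size=(6, 2)))

    def test_identical_cell_means_give_p_one(self):
        y = np.tile([[1.0, 1.0]], (4, 1))
        jitter = np.array([[0.01, -0.01], [-0.01, 0.01], [0.02, -0.02], [-0.02, 0.02]])
        res = tukey_hsd(make_long(y + jitter, y + jitter), mse=1.0, df_error=6)
        assert all(r.p_raw > 0.999 for r in res)

    def test_q_statistic_against_published_critical_value(self):
        # studentized range upper-5% point for k=4, df=40 is 3.79
        assert sps.studentized_range.sf(3.79, 4, 40) == pytest.approx(0.05, abs=2e-3)

    def test_cohens_d_definition(self, rng):
        long = self._long(rng, shift=1.0)
        res = tukey_hsd(long, mse=1.0, df_error=10)
        cells = {}
        for _, row in long.iterrows():
            cells.setdefault(f"{row.group}:{row.level}", []).append(row.value)
        for r in res:
            a, b = r.name.split(" vs ")
            d = np.mean(cells[a]) - np.mean(cells[b])
            assert r.effect_size == pytest.approx(d, rel=1e-9)  # MSE = 1

    def test_nonpositive_mse_rejected(self, rng):
        with pytest.raises(ValueError):
            tukey_hsd(self._long(rng), mse=0.0, df_error=10)


class TestOneTailedT:
    def test_identical_samples(self):
        r = one_tailed_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "greater")
        assert r.statistic == pytest.approx(0.0) and r.p_raw == pytest.approx(0.5)

    def test_hand_computed_case(self):
        r = one_tailed_t([1, 2, 3], [2, 3, 4], "less")
        assert r.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert r.effect_size == pytest.approx(-1.0)
        assert r.df == (4, 0)

    def test_direction_reversal_maps_p(self):
        x, y = [1.0, 2.0, 5.0], [2.0, 3.0, 4.0]
        p_g = one_tailed_t(x, y, "greater").p_raw
        p_l = one_tailed_t(x, y, "less").p_raw
        assert p_g + p_l == pytest.approx(1.0)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError):
            one_tailed_t([1.0, 1.0], [1.0, 1.0])


class TestFdrBH:
    def test_single_p_unchanged(self):
        assert fdr_bh([0.03]) == pytest.approx([0.03])

    def test_hand_case(self):
        assert fdr_bh([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_all_ones(self):
        assert fdr_bh([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=6))
    def test_matches_bruteforce_enumeration(self, ps):
        assert fdr_bh(ps) == pytest.approx(bruteforce_fdr_bh(ps), abs=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=8))
    def test_monotone_and_dominating(self, ps):
        adj = fdr_bh(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestOutlierScreen:
    def test_all_equal_warns_and_flags_nothing(self):
        with pytest.warns(UserWarning):
            flags = outlier_screen([2.0, 2.0, 2.0])
        assert not flags.any()

    def test_planted_outlier_is_the_only_flag(self, rng):
        base = rng.normal(size=100)
        planted = base.mean() + 3.5 * base.std(ddof=1)
        values = np.append(base, planted)
        flags = outlier_screen(values)
        assert flags[-1] and flags.sum() == 1

    def test_exactly_at_threshold_not_flagged(self):
        # for [1,1,1,1,x] the extreme sits at exactly 4/sqrt(5) sample SDs
        values = [1.0, 1.0, 1.0, 1.0, 9.0]
        boundary = 4 / np.sqrt(5)
        assert not outlier_screen(values, threshold=boundary).any()
        assert outlier_screen(values, threshold=boundary - 1e-9).sum() == 1

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            outlier_screen([1.0, 2.0])


class TestDunnett:
    def test_zero_difference_zero_statistic(self):
        res = dunnett_t((5.0, 1.0, 10), {"t": (5.0, 1.0, 10)})
        assert res[0].statistic == 0.0 and res[0].p_value == pytest.approx(1.0, abs=0.01)

    def test_reduces_to_pooled_two_sample_t(self, rng):
        x, y = rng.normal(size=12), rng.normal(0.8, 1, size=15)
        (res,) = dunnett_t(
            (x.mean(), x.std(ddof=1), len(x)),
            {"t": (y.mean(), y.std(ddof=1), len(y))},
            n_mc=400_000,
            seed=5,
        )
        t_ref = sps.ttest_ind(y, x, equal_var=True)
        assert res.statistic == pytest.approx(abs(t_ref.statistic), rel=1e-9)
        assert res.p_value == pytest.approx(t_ref.pvalue, abs=0.01)

    def test_matches_scipy_dunnett_on_reconstructed_samples(self, rng):
        def sample_with(mean, sd, n):
            z = rng.normal(size=n)
            z = (z - z.mean()) / z.std(ddof=1)
            return mean + sd * z

        groups = {"a": (3.0, 1.2, 12), "b": (4.1, 0.9, 15)}
        control = (3.4, 1.0, 14)
        raw = {k: sample_with(*v) for k, v in groups.items()}
        raw_c = sample_with(*control)
        ours = dunnett_t(control, groups, n_mc=400_000, seed=9)
        ref = sps.dunnett(*raw.values(), control=raw_c)
        for r, stat_ref, p_ref in zip(ours, ref.statistic, ref.pvalue):
            assert r.statistic == pytest.approx(abs(stat_ref), rel=1e-6)
            assert r.p_value == pytest.approx(p_ref, abs=0.015)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            dunnett_t((0.0, 1.0, 1), {"t": (1.0, 1.0, 5)})


class TestChi2:
    def test_yates_flag_changes_statistic(self):
        # printed sex table: AD 10F:11M vs HC 13F:8M
        table = [[10, 11], [13, 8]]
        assert chi2_2x2(table, yates=True).statistic == pytest.approx(0.384, abs=5e-4)
        assert chi2_2x2(table, yates=False).statistic == pytest.approx(0.865, abs=5e-4)

    def test_identical_rows_zero(self):
        assert chi2_2x2([[7, 3], [7, 3]], yates=False).statistic == 0.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_2x2([[0, 0], [5, 5]])


class TestCorrelate:
    def test_perfect_self_correlation(self):
        x = [1.0, 2.0, 3.0, 5.0]
        r = correlate(x, x)
        assert r.statistic == pytest.approx(1.0)

    def test_constant_input_missing(self):
        with pytest.warns(UserWarning):
            assert correlate([1, 2, 3], [5, 5, 5]) is None

    def test_spearman_matches_rank_formula(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 5, 3]  # rank displacements d^2 sum to 8
        r = correlate(x, y, method="spearman")
        assert r.statistic == pytest.approx(1 - 6 * 8 / (5 * 24), abs=1e-12)

    def test_pairwise_deletion(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.1, 2.2, 3.0, 4.1, 4.9]
        r = correlate(x, y, method="pearson")
        assert r.df == (2, 0)  # 4 complete pairs

    def test_grid_applies_one_fdr_family(self, rng):
        df = pd.DataFrame(
            {
                "f1": rng.normal(size=20),
                "f2": rng.normal(size=20),
                "MoCA": rng.normal(size=20),
                "IFS": rng.normal(size=20),
            }
        )
        grid = correlation_grid(df, ["f1", "f2"], ["MoCA", "IFS"])
        assert len(grid) == 4
        assert np.all(grid.p_fdr >= grid.p_raw - 1e-12)


def test_wide_to_long_roundtrip(rng):
    df = pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(6)],
            "group": ["AD"] * 3 + ["HC"] * 3,
            "noun_ratio": rng.random(6),
            "verb_ratio": rng.random(6),
        }
    )
    long = wide_to_long(df, ("noun_ratio", "verb_ratio"))
    assert len(long) == 12
    assert set(long.level) == {"noun_ratio", "verb_ratio"}
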