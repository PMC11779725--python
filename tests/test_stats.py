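"""Correlation, ANOVA letter displays, PCA and heterosis rates."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as scistats

from stomatakit.io import TRAIT_COLUMNS, TraitTable
from stomatakit.reference_data import CULTIVAR_TRAIT_MEANS
from stomatakit.stats import anova_cld, heterosis_rates, pca_traits, pearson_matrix


def synthetic_trait_table(n=200, seed=0):
    rng = np.random.default_rng(seed)
    sl = rng.normal(95, 5, n)
    sw = rng.normal(55, 2, n)
    f = np.clip(rng.normal(0.5, 0.03, n), 0.05, 0.95)
    sa = np.pi * sl / 2 * sw / 2
    sp = np.pi * (3 * (sl + sw) / 2 - np.sqrt((3 * sl / 2 + sw / 2) * (sl / 2 + 3 * sw / 2)))
    df = pd.DataFrame({
        "SD": rng.normal(80, 8, n), "SW": sw, "SL": sl, "SA": sa, "SP": sp,
        "GCPA": f * sa, "SCA": (1 - f) * sa, "SR": 4 * np.pi * sa / sp ** 2,
        "SE": np.sqrt(1 - (sw / sl) ** 2), "PGCPA": f, "PSCA": 1 - f,
    })
    return TraitTable(df)


class TestPearson:
    def test_psca_pgcpa_complementarity(self):
        cm = pearson_matrix(synthetic_trait_table())
        assert cm.r.loc["PSCA", "PGCPA"] == pytest.approx(-1.0, abs=1e-9)
        assert cm.p.loc["PSCA", "PGCPA"] == 0.0

    def test_unit_diagonal_and_symmetry(self):
        cm = pearson_matrix(synthetic_trait_table(50, 1))
        assert np.allclose(np.diag(cm.r), 1.0)
        assert np.allclose(cm.r, cm.r.T, equal_nan=True)

    def test_perfect_linear_cases(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 4, 6], "c": [3.0, 2, 1]})
        cm = pearson_matrix(df, columns=["a", "b", "c"])
        assert cm.r.loc["a", "b"] == pytest.approx(1.0)
        assert cm.r.loc["a", "c"] == pytest.approx(-1.0)

    def test_zero_variance_reported_missing_with_reason(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
        cm = pearson_matrix(df, columns=["a", "b"])
        assert np.isnan(cm.r.loc["a", "b"])
        assert cm.undefined[("a", "b")] == "zero variance"

    def test_matches_covariance_oracle(self):
        table = synthetic_trait_table(80, 2)
        cm = pearson_matrix(table)
        data = table.traits
        for a, b in itertools.combinations(TRAIT_COLUMNS, 2):
            x, y = data[a].to_numpy(), data[b].to_numpy()
            r = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
            assert cm.r.loc[a, b] == pytest.approx(np.clip(r, -1, 1), abs=1e-12)

    def test_pvalues_match_t_distribution(self):
        table = synthetic_trait_table(60, 3)
        cm = pearson_matrix(table)
        n = 60
        r = cm.r.loc["SD", "SW"]
        t = r * np.sqrt((n - 2) / (1 - r * r))
        assert cm.p.loc["SD", "SW"] == pytest.approx(2 * scistats.t.sf(abs(t), n - 2))


class TestAnovaCld:
    def test_identically_drawn_groups_share_letters(self):
        rng = np.random.default_rng(10)
        values = np.concatenate([rng.normal(5, 1, 50), rng.normal(5, 1, 50)])
        groups = np.array(["g1"] * 50 + ["g2"] * 50)
        res = anova_cld(values, groups)
        assert res.letters["g1"] == res.letters["g2"] == "a"

    def test_separated_group_gets_own_letter(self):
        rng = np.random.default_rng(11)
        values = np.concatenate([rng.normal(0, 0.1, 20), rng.normal(0, 0.1, 20), rng.normal(10, 0.1, 20)])
        groups = np.array(["A"] * 20 + ["B"] * 20 + ["C"] * 20)
        res = anova_cld(values, groups)
        # welch-t/bonferroni oracle agrees on the partition {A,B} vs {C}
        assert res.letters["A"] == res.letters["B"]
        assert set(res.letters["C"]) != set(res.letters["A"])
        pAB = scistats.ttest_ind(values[groups == "A"], values[groups == "B"], equal_var=False).pvalue
        pAC = scistats.ttest_ind(values[groups == "A"], values[groups == "C"], equal_var=False).pvalue
        assert min(pAB * 3, 1) >= 0.05 and pAC * 3 < 0.05

    def test_single_group_letter_a(self):
        res = anova_cld(np.array([1.0, 2.0, 3.0]), np.array(["only"] * 3))
        assert res.letters == {"only": "a"}

    def test_groups_ordered_by_descending_mean_first_letter_a(self):
        rng = np.random.default_rng(12)
        values = np.concatenate([rng.normal(m, 0.1, 10) for m in (2.0, 8.0, 5.0)])
        groups = np.array(["lo"] * 10 + ["hi"] * 10 + ["mid"] * 10)
        res = anova_cld(values, groups)
        assert res.groups == ["hi", "mid", "lo"]
        assert "a" in res.letters["hi"]

    def test_cld_consistent_with_tukey_on_random_data(self):
        rng = np.random.default_rng(13)
        for trial in range(8):
            k = int(rng.integers(2, 6))
            means = rng.uniform(0, 4, k)
            values = np.concatenate([rng.normal(m, 1.0, 15) for m in means])
            groups = np.array([f"g{i}" for i in range(k) for _ in range(15)])
            res = anova_cld(values, groups)
            for _, row in res.tukey.iterrows():
                shared = set(res.letters[str(row.group1)]) & set(res.letters[str(row.group2)])
                if bool(row.reject):
                    assert not shared
                else:
                    assert shared

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            anova_cld(np.array([1.0, 2.0, 3.0]), np.array(["a", "a", "b"]))


class TestPca:
    def test_two_perfectly_correlated_traits(self):
        rng = np.random.default_rng(20)
        x = rng.normal(size=100)
        df = pd.DataFrame({"t1": x, "t2": 3 * x + 1})
        res = pca_traits(df, columns=["t1", "t2"])
        assert res.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-9)
        assert res.contributions == pytest.approx([100.0, 0.0], abs=1e-7)

    def test_independent_traits_flat_spectrum(self):
        rng = np.random.default_rng(21)
        df = pd.DataFrame(rng.normal(size=(10000, 5)), columns=list("abcde"))
        res = pca_traits(df, columns=list("abcde"))
        assert np.all(np.abs(res.eigenvalues - 1.0) < 0.1)

    def test_contributions_sum_to_100(self):
        res = pca_traits(synthetic_trait_table(120, 22).df, columns=TRAIT_COLUMNS)
        assert res.contributions.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_reconstructs_correlation_matrix(self):
        table = synthetic_trait_table(150, 23)
        cols = ["SD", "SW", "SL", "SA", "SP"]
        res = pca_traits(table.df, columns=cols)
        C = np.corrcoef(table.df[cols].to_numpy(), rowvar=False)
        R = res.loadings @ np.diag(res.eigenvalues) @ res.loadings.T
        assert np.allclose(R, C, atol=1e-9)

    def test_sign_convention_deterministic(self):
        df = synthetic_trait_table(40, 24).df
        a = pca_traits(df, columns=TRAIT_COLUMNS)
        b = pca_traits(df, columns=TRAIT_COLUMNS)
        assert np.array_equal(a.loadings, b.loadings)
        for k in range(a.loadings.shape[1]):
            j = np.argmax(np.abs(a.loadings[:, k]))
            assert a.loadings[j, k] > 0

    def test_zero_variance_trait_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [4.0, 3, 2, 1], "c": [7.0, 7, 7, 7]})
        with pytest.warns(UserWarning, match="c"):
            res = pca_traits(df, columns=["a", "b", "c"])
        assert res.traits == ["a", "b"]

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            pca_traits(pd.DataFrame({"a": [1.0, 2], "b": [2.0, 1]}), columns=["a", "b"])


class TestHeterosis:
    def test_midparent_equality_gives_zero(self):
        res = heterosis_rates(5.0, 4.0, 6.0)
        assert res.mid_parent_rate == 0.0

    def test_density_from_published_cultivar_means(self):
        m = {c: CULTIVAR_TRAIT_MEANS[c]["SD"] for c in ("728", "2416", "MC01")}
        res = heterosis_rates(m["728"], m["2416"], m["MC01"], "SD")
        assert res.mid_parent_rate == pytest.approx(-0.0962, abs=5e-4)
        assert res.over_high_parent_rate == pytest.approx(-0.1406, abs=5e-4)
        assert res.over_low_parent_rate == pytest.approx(-0.0469, abs=5e-4)

    def test_size_traits_positive_rates(self):
        m = CULTIVAR_TRAIT_MEANS
        res = heterosis_rates(m["728"]["SL"], m["2416"]["SL"], m["MC01"]["SL"], "SL")
        assert res.mid_parent_rate > 0 and res.over_high_parent_rate > 0 and res.over_low_parent_rate > 0

    def test_scale_invariance_exact(self):
        a = heterosis_rates(7.0, 5.0, 6.0)
        b = heterosis_rates(7.0 * 8, 5.0 * 8, 6.0 * 8)
        assert b.mid_parent_rate == a.mid_parent_rate
        assert b.over_high_parent_rate == a.over_high_parent_rate
        assert b.over_low_parent_rate == a.over_low_parent_rate

    def test_nonpositive_parent_rejected(self):
        with pytest.raises(ValueError):
            heterosis_rates(5.0, 0.0, 6.0)
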