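import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracle_utils import exact_one_way_p, holm_by_hand
from qfasakit.comp_stats import (
    DistanceMatrix,
    annual_mean_trend,
    chi_square_distance,
    holm_adjust,
    ice_covariate_permanova,
    pairwise_class_tests,
    per_prey_permanova,
    permanova,
)
from qfasakit.signatures import IceIndexTable, SignatureValidationError


class TestDistanceMatrix:
    def test_asymmetry_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(np.array([[1.0, 0.0], [0.0, 0.0]]))


class TestChiSquareDistance:
    def test_identical_rows_zero(self):
        P = np.tile([0.2, 0.3, 0.5], (3, 1))
        assert chi_square_distance(P).values.max() == 0.0

    def test_hand_computed_two_by_two(self):
        D = chi_square_distance(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert D.values[0, 1] == pytest.approx(2.0, abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.dirichlet(np.ones(3), size=5)
        d = chi_square_distance(P).values
        for i, j, k in itertools.permutations(range(5), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_zero_column_named(self):
        with pytest.raises(ValueError, match="columns at positions \\[1\\]"):
            chi_square_distance(np.array([[0.5, 0.0], [0.7, 0.0]]))

    def test_scale_invariance_of_rows(self):
        # chi-square distance depends on row profiles only
        P = np.array([[1.0, 2.0, 3.0], [4.0, 1.0, 1.0]])
        D1 = chi_square_distance(P)
        D2 = chi_square_distance(P / P.sum(axis=1, keepdims=True))
        np.testing.assert_allclose(D1.values, D2.values, atol=1e-12)


class TestPermanova:
    def test_degenerate_zero_distance(self):
        D = DistanceMatrix(np.zeros((6, 6)))
        factors = pd.DataFrame({"g": ["a", "a", "a", "b", "b", "b"]})
        res = permanova(D, factors, ["g"], n_perm=99, seed=0)
        assert res.table.loc["g", "SS"] == pytest.approx(0.0, abs=1e-12)
        assert res.F("g") == 0.0
        assert res.p("g") == 1.0

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        P = rng.dirichlet(np.ones(3), size=6)
        D = chi_square_distance(P)
        labels = ["a", "a", "a", "b", "b", "b"]
        res = permanova(D, pd.DataFrame({"g": labels}), ["g"], exact=True)
        F_oracle, p_oracle = exact_one_way_p(D.values, labels)
        assert res.F("g") == pytest.approx(F_oracle, rel=1e-10)
        assert res.p("g") == pytest.approx(p_oracle, abs=1e-12)

    def test_exact_matches_oracle_unbalanced(self):
        rng = np.random.default_rng(9)
        P = rng.dirichlet(np.ones(4), size=7)
        D = chi_square_distance(P)
        labels = ["a", "a", "b", "b", "b", "c", "c"]
        res = permanova(D, pd.DataFrame({"g": labels}), ["g"], exact=True)
        F_oracle, p_oracle = exact_one_way_p(D.values, labels)
        assert res.F("g") == pytest.approx(F_oracle, rel=1e-10)
        assert res.p("g") == pytest.approx(p_oracle, abs=1e-12)

    def test_df_bookkeeping_13_years(self):
        rng = np.random.default_rng(0)
        n_per = 3
        years = [str(y) for y in range(2004, 2017) for _ in range(n_per)]
        P = rng.dirichlet(np.ones(5), size=len(years))
        res = permanova(
            chi_square_distance(P), pd.DataFrame({"year": years}), ["year"],
            n_perm=99, seed=0,
        )
        assert res.table.loc["year", "df"] == 12
        assert res.table.loc["Residual", "df"] == len(years) - 1 - 12

    def test_sequential_terms_and_interaction_df(self):
        rng = np.random.default_rng(1)
        years = [str(y) for y in (2013, 2014, 2015, 2016) for _ in range(8)]
        classes = (["AF", "AM", "SF", "SM"] * 8)[: len(years)]
        P = rng.dirichlet(np.ones(5), size=len(years))
        factors = pd.DataFrame({"year": years, "class": classes})
        res = permanova(
            chi_square_distance(P), factors, ["year", "class", "year:class"],
            n_perm=99, seed=0,
        )
        assert res.table.loc["year", "df"] == 3
        assert res.table.loc["class", "df"] == 3
        assert res.table.loc["year:class", "df"] == 9
        dfs = res.table["df"].drop("Total").sum()
        assert dfs == len(years) - 1
        # sequential SS decompose the total
        ss = res.table["SS"]
        assert ss.drop("Total").sum() == pytest.approx(ss["Total"], rel=1e-9)

    def test_single_level_factor_rejected(self):
        D = DistanceMatrix(np.zeros((4, 4)))
        with pytest.raises(SignatureValidationError, match="single level"):
            permanova(D, pd.DataFrame({"g": ["a"] * 4}), ["g"], n_perm=99)

    def test_confounded_term_rejected(self):
        rng = np.random.default_rng(2)
        P = rng.dirichlet(np.ones(3), size=6)
        g = ["a", "a", "a", "b", "b", "b"]
        factors = pd.DataFrame({"g": g, "h": g})  # h duplicates g
        with pytest.raises(SignatureValidationError, match="confounded"):
            permanova(chi_square_distance(P), factors, ["g", "h"], n_perm=99)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(4)
        P = rng.dirichlet(np.ones(4), size=12)
        factors = pd.DataFrame({"g": ["a", "b", "c"] * 4})
        D = chi_square_distance(P)
        p1 = permanova(D, factors, ["g"], n_perm=199, seed=42).p("g")
        p2 = permanova(D, factors, ["g"], n_perm=199, seed=42).p("g")
        assert p1 == p2

    def test_p_floor_add_one_convention(self):
        # strong separation: observed F should beat every permutation
        P = np.vstack([np.tile([0.9, 0.1], (6, 1)), np.tile([0.1, 0.9], (6, 1))])
        P += np.random.default_rng(0).normal(scale=1e-3, size=P.shape)
        P = np.abs(P)
        factors = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 6})
        res = permanova(chi_square_distance(P), factors, ["g"], n_perm=199, seed=0)
        assert res.p("g") == pytest.approx(1.0 / 200.0)


class TestHolm:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.2]), [0.2])

    def test_hand_computed(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06], atol=1e-12
        )

    def test_five_prey_example(self):
        adj = holm_adjust([0.01, 0.2, 0.3, 0.4, 0.5])
        assert adj[0] == pytest.approx(0.05, abs=1e-12)

    def test_all_ones(self):
        np.testing.assert_array_equal(holm_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    @settings(max_examples=100, deadline=None)
    def test_matches_independent_implementations(self, p):
        adj = holm_adjust(p)
        np.testing.assert_allclose(adj, holm_by_hand(p), atol=1e-12)
        from statsmodels.stats.multitest import multipletests

        _, adj_sm, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(adj, adj_sm, atol=1e-9)
        # never below raw; smallest p gets Bonferroni
        assert np.all(adj >= np.asarray(p) - 1e-15)
        i = int(np.argmin(p))
        assert adj[i] == pytest.approx(min(1.0, len(p) * p[i]), abs=1e-12)


def _null_diet_table(rng, n=24, k=5):
    P = rng.dirichlet(np.ones(k), size=n)
    return pd.DataFrame(P, columns=[f"sp{i}" for i in range(k)]).assign(
        **{"class": (["AF", "AM", "SF", "SM"] * n)[:n],
           "year": (["2013", "2014", "2015"] * n)[:n]}
    )


class TestPerPrey:
    def test_constant_prey_degenerate(self):
        rng = np.random.default_rng(0)
        df = _null_diet_table(rng)
        df["sp0"] = 0.2
        prey = [f"sp{i}" for i in range(5)]
        out = per_prey_permanova(
            df, df[["class"]], ["class"], prey, n_perm=99, seed=0
        )
        row = out[(out["prey"] == "sp0") & (out["term"] == "class")].iloc[0]
        assert row["pseudo_F"] == 0.0 and row["p_holm"] == 1.0

    def test_structured_prey_has_smallest_adjusted_p(self):
        rng = np.random.default_rng(1)
        df = _null_diet_table(rng, n=40)
        shift = (df["class"].isin(["AF", "SF"])).to_numpy() * 0.35 + 0.1
        df["sp0"] = shift + rng.normal(scale=0.01, size=40).clip(-0.05, 0.05)
        prey = [f"sp{i}" for i in range(5)]
        out = per_prey_permanova(df, df[["class"]], ["class"], prey, n_perm=199, seed=0)
        sub = out[out["term"] == "class"].set_index("prey")
        assert sub["p_holm"].idxmin() == "sp0"
        assert sub.loc["sp0", "p_holm"] < 0.05


class TestPairwise:
    def test_identical_rows_all_p_one(self):
        df = pd.DataFrame({"sp0": [0.3] * 12, "class": ["AF", "AM", "SF", "SM"] * 3})
        out = pairwise_class_tests(df, "sp0", n_perm=99, seed=0)
        assert (out["p_holm"] == 1.0).all()

    def test_displaced_class_pairs_smallest(self):
        rng = np.random.default_rng(2)
        classes = ["AF"] * 10 + ["AM"] * 10 + ["SF"] * 10 + ["SM"] * 10
        vals = rng.uniform(0.2, 0.3, size=40)
        vals[10:20] += 0.4  # AM displaced
        df = pd.DataFrame({"sp0": vals, "class": classes})
        out = pairwise_class_tests(df, "sp0", n_perm=199, seed=0)
        out["is_am"] = (out["class_a"] == "AM") | (out["class_b"] == "AM")
        am_max = out.loc[out["is_am"], "p_holm"].max()
        rest_min = out.loc[~out["is_am"], "p_holm"].min()
        assert am_max < rest_min

    def test_small_class_excluded_with_warning(self):
        df = pd.DataFrame(
            {"sp0": np.linspace(0.1, 0.9, 9),
             "class": ["AF"] * 4 + ["AM"] * 4 + ["SM"]}
        )
        with pytest.warns(UserWarning, match="SM"):
            out = pairwise_class_tests(df, "sp0", n_perm=99, seed=0)
        assert set(out["class_a"]) | set(out["class_b"]) == {"AF", "AM"}


class TestTrend:
    def test_strictly_increasing(self):
        df = pd.DataFrame({
            "sp0": [0.1, 0.1, 0.2, 0.2, 0.3, 0.3],
            "year": [2004, 2004, 2005, 2005, 2006, 2006],
        })
        res = annual_mean_trend(df, ["sp0"])["sp0"]
        assert res.r_s == pytest.approx(1.0)

    def test_hand_ranked(self):
        df = pd.DataFrame({"sp0": [0.3, 0.1, 0.2], "year": [2004, 2005, 2006]})
        res = annual_mean_trend(df, ["sp0"])["sp0"]
        assert res.r_s == pytest.approx(-0.5, abs=1e-12)
        assert res.n == 3

    def test_exact_p_small_n(self):
        # n=3 rank orders give r in {±1, ±0.5}; all six satisfy |r| >= 0.5
        df = pd.DataFrame({"sp0": [0.3, 0.1, 0.2], "year": [2004, 2005, 2006]})
        res = annual_mean_trend(df, ["sp0"])["sp0"]
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_exact_p_perfect_monotone_n5(self):
        # only 2 of 120 orders reach |r| = 1
        df = pd.DataFrame({"sp0": [0.1, 0.2, 0.3, 0.4, 0.5],
                           "year": [2004, 2005, 2006, 2007, 2008]})
        res = annual_mean_trend(df, ["sp0"])["sp0"]
        assert res.r_s == pytest.approx(1.0)
        assert res.p == pytest.approx(2 / 120, abs=1e-12)

    def test_large_n_uses_approximation(self):
        rng = np.random.default_rng(0)
        years = np.repeat(np.arange(2004, 2016), 2)
        df = pd.DataFrame({"sp0": rng.uniform(size=years.size), "year": years})
        res = annual_mean_trend(df, ["sp0"])["sp0"]
        assert 0.0 <= res.p <= 1.0 and res.n == 12

    def test_too_few_years_rejected(self):
        df = pd.DataFrame({"sp0": [0.1, 0.2], "year": [2004, 2005]})
        with pytest.raises(SignatureValidationError, match=">= 3"):
            annual_mean_trend(df, ["sp0"])


def _ice(years, ifd50=None):
    years = list(years)
    return IceIndexTable(pd.DataFrame({
        "year": years,
        "ifd50": ifd50 if ifd50 is not None else np.linspace(50, 90, len(years)),
        "ifd15": np.linspace(30, 60, len(years)),
        "melt_season": np.linspace(90, 130, len(years)),
    }))


class TestIceCovariate:
    def _table(self, rng, n=36, year_signal=0.0):
        # classes drawn independently of year so terms are not aliased
        years = np.array(([2004, 2008, 2012, 2016] * n)[:n])
        classes = rng.choice(["AF", "AM", "SF", "SM"], size=n)
        P = rng.dirichlet(np.ones(4), size=n)
        if year_signal:
            bump = year_signal * (years - 2004) / 12.0
            P[:, 0] += bump
            P = P / P.sum(axis=1, keepdims=True)
        df = pd.DataFrame(P, columns=[f"sp{i}" for i in range(4)])
        df["year"] = years
        df["class"] = classes
        return df

    def test_covariate_df_is_one(self):
        rng = np.random.default_rng(0)
        df = self._table(rng)
        res = ice_covariate_permanova(
            df, _ice(sorted(df["year"].unique())), "ifd50",
            prey=[f"sp{i}" for i in range(4)], n_perm=99, seed=0,
        )
        assert res.table.loc["ifd50", "df"] == 1

    def test_constant_covariate_zero_ss(self):
        rng = np.random.default_rng(1)
        df = self._table(rng)
        ice = _ice(sorted(df["year"].unique()), ifd50=[70.0] * 4)
        with pytest.warns(UserWarning, match="constant"):
            res = ice_covariate_permanova(
                df, ice, "ifd50", prey=[f"sp{i}" for i in range(4)],
                include_interaction=False, n_perm=99, seed=0,
            )
        assert res.table.loc["ifd50", "SS"] == pytest.approx(0.0, abs=1e-9)

    def test_covariate_tracking_year_effect_significant(self):
        rng = np.random.default_rng(2)
        df = self._table(rng, n=48, year_signal=0.8)
        res = ice_covariate_permanova(
            df, _ice(sorted(df["year"].unique())), "ifd50",
            prey=[f"sp{i}" for i in range(4)], include_interaction=False,
            n_perm=199, seed=0,
        )
        assert res.p("ifd50") < 0.05

    def test_missing_year_listed(self):
        rng = np.random.default_rng(3)
        df = self._table(rng)
        with pytest.raises(SignatureValidationError, match="2016"):
            ice_covariate_permanova(
                df, _ice([2004, 2008, 2012]), "ifd50",
                prey=[f"sp{i}" for i in range(4)], n_perm=99, seed=0,
            )
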