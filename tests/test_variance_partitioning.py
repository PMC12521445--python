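import itertools

import numpy as np
import pandas as pd
import pytest

from rootmeta import variance_partitioning as vp


@pytest.fixture(scope="module")
def matrix(harmonized) -> vp.PredictorMatrix:
    return vp.build_matrix(harmonized, "both", "all")


class TestBuildMatrix:
    def test_boundary_duration_in_early_group(self, harmonized):
        m = vp.build_matrix(harmonized, "geoclimate", "le12")
        assert (m.X["duration_months"] <= 12.0).all()
        assert (m.X["duration_months"] == 12.0).any()

    def test_temporal_split_partitions_all(self, harmonized):
        m_all = vp.build_matrix(harmonized, "quality", "all")
        m_le = vp.build_matrix(harmonized, "quality", "le12")
        m_gt = vp.build_matrix(harmonized, "quality", "gt12")
        assert m_le.n_rows + m_gt.n_rows == m_all.n_rows
        assert set(m_le.X.index) | set(m_gt.X.index) == set(m_all.X.index)

    def test_incomplete_rows_dropped(self, harmonized):
        df = harmonized.copy()
        control = df["treatment_mean"].isna()
        first = df.index[control][0]
        df.loc[first, "aur"] = np.nan
        m = vp.build_matrix(df, "quality", "all")
        assert df.loc[first, "obs_id"] not in m.X.index

    def test_control_rows_only(self, matrix, harmonized):
        paired_ids = set(harmonized.loc[harmonized["treatment_mean"].notna(), "obs_id"])
        assert not (set(matrix.X.index) & paired_ids)

    def test_duration_retained_as_predictor(self, matrix):
        assert "duration_months" in matrix.X.columns


class TestRandomForest:
    def test_deterministic_under_seed(self, matrix):
        a = vp.rf_variance_explained(matrix, n_trees=60, seed=5)
        b = vp.rf_variance_explained(matrix, n_trees=60, seed=5)
        assert a == b

    def test_row_order_invariance(self, harmonized):
        shuffled = harmonized.sample(frac=1.0, random_state=9).reset_index(drop=True)
        m1 = vp.build_matrix(harmonized, "quality", "all")
        m2 = vp.build_matrix(shuffled, "quality", "all")
        assert vp.rf_variance_explained(m1, n_trees=40, seed=3) == vp.rf_variance_explained(
            m2, n_trees=40, seed=3
        )

    def test_pure_noise_low_r2(self, rng):
        n = 500
        X = pd.DataFrame(rng.normal(0, 1, (n, 4)), columns=list("abcd"))
        X.index = [f"o{i}" for i in range(n)]
        m = vp.PredictorMatrix(X=X, y=pd.Series(rng.normal(0, 1, n), index=X.index),
                               column_set="test", time_filter="all")
        assert vp.rf_variance_explained(m, n_trees=150, seed=0) <= 0.1

    def test_strong_signal_high_r2(self, rng):
        n = 500
        X = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=list("abc"))
        X.index = [f"o{i}" for i in range(n)]
        y = np.sin(X["a"]) * 3 + rng.normal(0, 0.1, n)
        m = vp.PredictorMatrix(X=X, y=pd.Series(y, index=X.index),
                               column_set="test", time_filter="all")
        assert vp.rf_variance_explained(m, n_trees=150, seed=0) >= 0.8

    def test_too_few_rows_rejected(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (10, 3)), columns=list("abc"))
        m = vp.PredictorMatrix(X=X, y=pd.Series(rng.normal(0, 1, 10)),
                               column_set="test", time_filter="all")
        with pytest.raises(ValueError):
            vp.rf_variance_explained(m, n_trees=10, seed=0)


@pytest.fixture(scope="module")
def signal_matrix():
    rng = np.random.default_rng(77)
    n = 300
    X = pd.DataFrame(rng.normal(0, 1, (n, 4)), columns=["driver", "b", "c", "d"])
    X.index = [f"o{i}" for i in range(n)]
    y = 2.0 * X["driver"] + rng.normal(0, 0.3, n)
    return vp.PredictorMatrix(X=X, y=pd.Series(y, index=X.index),
                              column_set="test", time_filter="all")


class TestPermutationImportance:
    def test_dominant_predictor_found(self, signal_matrix):
        imps = vp.rf_permutation_importance(signal_matrix, n_trees=80, n_perm=30, seed=1)
        by_name = {i.predictor: i for i in imps}
        assert by_name["driver"].importance == max(i.importance for i in imps)
        assert by_name["driver"].p_value == min(i.p_value for i in imps)
        assert by_name["driver"].significant

    def test_p_never_zero(self, signal_matrix):
        imps = vp.rf_permutation_importance(signal_matrix, n_trees=40, n_perm=24, seed=2)
        assert all(i.p_value >= 1 / 25 for i in imps)

    def test_null_predictor_p_not_extreme(self, signal_matrix):
        imps = vp.rf_permutation_importance(signal_matrix, n_trees=40, n_perm=30, seed=3)
        null_ps = [i.p_value for i in imps if i.predictor != "driver"]
        assert max(null_ps) > 0.1  # at least one clearly nonsignificant


class TestGroupMeanContribution:
    def _imps(self, values):
        return [vp.ImportanceResult(p, v, None, None) for p, v in values.items()]

    def test_identity_grouping(self):
        imps = self._imps({"a": 3.0, "b": 5.0})
        out = vp.group_mean_contribution(imps, {"a": ["a"], "b": ["b"]})
        assert out == {"a": 3.0, "b": 5.0}

    def test_equal_importances(self):
        imps = self._imps({"a": 2.0, "b": 2.0, "c": 2.0})
        out = vp.group_mean_contribution(imps, {"g": ["a", "b", "c"]})
        assert out["g"] == pytest.approx(2.0)

    def test_unknown_predictor_rejected(self):
        with pytest.raises(KeyError):
            vp.group_mean_contribution(self._imps({"a": 1.0}), {"g": ["zz"]})

    def test_rescaling_to_r2(self):
        imps = self._imps({"a": 1.0, "b": 3.0})
        out = vp.group_mean_contribution(imps, {"g": ["a", "b"]}, scale_to_r2=0.8)
        # total importance 4 -> rescaled to 80; mean = 40
        assert out["g"] == pytest.approx(40.0)


class TestPC1Composite:
    def test_perfectly_correlated_columns(self, rng):
        a = rng.normal(0, 1, 50)
        X = pd.DataFrame({"x": a, "y": 2 * a + 1})
        scores = vp.pc1_composite(X)
        # PC1 of two perfectly correlated standardized columns carries all variance
        assert np.var(scores) == pytest.approx(2.0 * 50 / 50, rel=1e-6)
        assert abs(np.corrcoef(scores, a)[0, 1]) == pytest.approx(1.0)

    def test_anchor_fixes_sign(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (40, 3)), columns=["n_conc", "b", "c"])
        X["b"] = X["n_conc"] * 0.8 + rng.normal(0, 0.3, 40)
        s1 = vp.pc1_composite(X, anchor="n_conc")
        s2 = vp.pc1_composite(-X, anchor="n_conc")
        np.testing.assert_allclose(s1, -s2, atol=1e-10)
        assert np.corrcoef(s1, X["n_conc"])[0, 1] > 0

    def test_scores_centred(self, rng):
        X = pd.DataFrame(rng.normal(5, 2, (30, 4)))
        X.columns = ["a", "b", "c", "d"]
        assert np.mean(vp.pc1_composite(X)) == pytest.approx(0.0, abs=1e-10)

    def test_zero_variance_column_rejected(self):
        X = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="zero-variance"):
            vp.pc1_composite(X)


def brute_force_partition(y, composites):
    """Average R^2 increments over explicit orderings of group entry."""
    names = list(composites)
    r2 = {}
    for r in range(len(names) + 1):
        for subset in itertools.combinations(names, r):
            X = (
                np.column_stack([composites[n] for n in subset])
                if subset
                else np.empty((len(y), 0))
            )
            design = np.column_stack([np.ones(len(y)), X])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            resid = y - design @ coef
            r2[frozenset(subset)] = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
    out = {}
    orders = list(itertools.permutations(names))
    for name in names:
        incs = []
        for order in orders:
            pos = order.index(name)
            before = frozenset(order[:pos])
            incs.append(r2[before | {name}] - r2[before])
        out[name] = float(np.mean(incs))
    return out, r2[frozenset(names)]


class TestHierarchicalPartition:
    def test_two_group_closed_form(self, rng):
        """IC_A = 0.5*[R2(A) + (R2(AB) - R2(B))] on a constructed case."""
        n = 400
        a = rng.normal(0, 1, n)
        b = 0.6 * a + rng.normal(0, 0.8, n)
        y = a + 0.5 * b + rng.normal(0, 1, n)
        res = vp.hierarchical_partition(y, {"A": a, "B": b})
        ics = {r.group: r.independent_contribution for r in res}
        oracle, full = brute_force_partition(y, {"A": a, "B": b})
        assert ics["A"] == pytest.approx(oracle["A"], abs=1e-10)
        assert ics["B"] == pytest.approx(oracle["B"], abs=1e-10)
        assert sum(ics.values()) == pytest.approx(full, abs=1e-10)

    @pytest.mark.parametrize("g", [2, 3, 4])
    def test_matches_brute_force_orderings(self, g, rng):
        n = 200
        comps = {f"g{i}": rng.normal(0, 1, n) for i in range(g)}
        y = sum((i + 1) * comps[f"g{i}"] for i in range(g)) + rng.normal(0, 2, n)
        res = vp.hierarchical_partition(y, comps)
        oracle, full = brute_force_partition(y, comps)
        for r in res:
            assert r.independent_contribution == pytest.approx(oracle[r.group], abs=1e-10)
            assert r.total_model_r2 == pytest.approx(full, abs=1e-10)

    def test_orthogonal_groups_get_marginal_r2(self, rng):
        n = 10_000
        a = rng.normal(0, 1, n)
        b = rng.normal(0, 1, n)
        a, b = a - a.mean(), b - b.mean()
        b -= a * (a @ b) / (a @ a)  # exactly orthogonal
        y = a + b + rng.normal(0, 1, n)
        res = {r.group: r for r in vp.hierarchical_partition(y, {"A": a, "B": b})}
        _, r2_cache_full = brute_force_partition(y, {"A": a, "B": b})
        # marginal R2 of each group alone
        for name, x in (("A", a), ("B", b)):
            design = np.column_stack([np.ones(n), x])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            marginal = 1 - ((y - design @ coef) ** 2).sum() / ((y - y.mean()) ** 2).sum()
            assert res[name].independent_contribution == pytest.approx(marginal, abs=1e-10)

    def test_contributions_telescope(self, matrix):
        comps = {
            "quality": vp.pc1_composite(matrix.X[list(vp.QUALITY_COLUMNS)], anchor="n_conc"),
            "geoclimate": vp.pc1_composite(matrix.X[list(vp.GEOCLIMATE_COLUMNS)], anchor="mat"),
        }
        res = vp.hierarchical_partition(matrix.y.to_numpy(), comps)
        assert sum(r.independent_contribution for r in res) == pytest.approx(
            res[0].total_model_r2, abs=1e-10
        )


class TestTraitCorrelation:
    def test_exact_negative(self):
        df = pd.DataFrame(
            {
                "treatment_mean": [np.nan] * 5,
                "control_mean": [50.0, 40.0, 30.0, 20.0, 10.0],
                "aur": [10.0, 20.0, 30.0, 40.0, 50.0],
            }
        )
        r, p, n = vp.trait_correlation(df, "aur")
        assert r == pytest.approx(-1.0)
        assert n == 5

    def test_generator_truth_signs(self, harmonized):
        """The generator builds in negative AUR and positive N effects."""
        r_aur, p_aur, _ = vp.trait_correlation(harmonized, "aur")
        r_n, p_n, _ = vp.trait_correlation(harmonized, "n_conc")
        r_aurn, p_aurn, _ = vp.trait_correlation(harmonized, "aur_n")
        assert r_aur < 0 and p_aur < 0.05
        assert r_aurn < 0 and p_aurn < 0.05
        assert r_n > 0 and p_n < 0.05

    def test_independent_pairs_small_r(self, rng):
        df = pd.DataFrame(
            {
                "treatment_mean": np.nan,
                "control_mean": rng.uniform(5, 95, 500),
                "aur": rng.normal(25, 7, 500),
            }
        )
        r, p, _ = vp.trait_correlation(df, "aur")
        assert abs(r) < 0.15

    def test_constant_trait_rejected(self):
        df = pd.DataFrame(
            {"treatment_mean": [np.nan] * 4, "control_mean": [1.0, 2.0, 3.0, 4.0],
             "aur": [25.0] * 4}
        )
        with pytest.raises(ValueError, match="constant"):
            vp.trait_correlation(df, "aur")
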