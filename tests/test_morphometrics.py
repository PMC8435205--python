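"""Morphometric pipeline: allometry, imputation, size correction, Gower,
NMDS, feature scores, Mantel and Welch."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oracles
from conftest import toy_matrix
from moonjelly.morphometrics import (
    AllometryEntry,
    AllometryModel,
    feature_scores,
    filter_features,
    fit_allometry,
    geographic_distances,
    gower_distance,
    impute_missing,
    mantel_test,
    minmax_scale,
    nmds,
    size_correct,
    welch_t,
)
from moonjelly.simulate import FeatureSim, LocalitySim, TraitSimSpec, simulate_traits


def model_with(feature, slope, pvalue=1e-6, intercept=0.0, n=10):
    return AllometryModel({feature: AllometryEntry(feature, slope, intercept, pvalue, n)})


class TestFitAllometry:
    def test_exact_power_law_recovers_slope(self):
        f1 = [5.0, 10.0, 15.0, 20.0]
        tm = toy_matrix({"fx": [0.5 * x ** 1.3 for x in f1]}, f1, ["L"] * 4)
        entry = fit_allometry(tm, "fx")
        assert entry.slope == pytest.approx(1.3, abs=1e-12)
        assert entry.intercept == pytest.approx(np.log(0.5), abs=1e-10)
        assert entry.pvalue < 1e-10

    def test_constant_feature_zero_slope_p_one(self):
        tm = toy_matrix({"fx": [3.0, 3.0, 3.0, 3.0]}, [5, 10, 15, 20], ["L"] * 4)
        entry = fit_allometry(tm, "fx")
        assert entry.slope == 0.0
        assert entry.pvalue == 1.0

    def test_nonpositive_value_names_specimen_and_feature(self):
        tm = toy_matrix({"fx": [1.0, -2.0, 3.0]}, [5, 10, 15], ["L"] * 3)
        with pytest.raises(ValueError, match="fx.*s2|s2.*fx"):
            fit_allometry(tm, "fx")

    def test_too_few_points_flagged_unfittable(self):
        tm = toy_matrix({"fx": [1.0, 2.0, np.nan]}, [5, 10, 15], ["L"] * 3)
        entry = fit_allometry(tm, "fx")
        assert not entry.fittable

    def test_noisy_recovery_within_tolerance(self):
        spec = TraitSimSpec(
            localities=[LocalitySim("L", 0.0, 0.0, np.log(12.0), 0.3)],
            features=[FeatureSim("fx", a=1.0, b_true=0.9, sigma=0.05)],
            n_per_locality=100,
            missing_rate=0.0,
            seed=42,
        )
        tm, _ = simulate_traits(spec)
        entry = fit_allometry(tm, "fx")
        assert entry.slope == pytest.approx(0.9, abs=0.05)
        assert entry.pvalue < 1e-10


class TestImputeMissing:
    def test_size_equality_returns_group_mean(self):
        tm = toy_matrix(
            {"fx": [3.0, 3.0, np.nan]}, [10.0, 10.0, 10.0], ["L"] * 3,
            coords=[[0, 0]] * 3,
        )
        for b in (0.0, 0.7, 2.0):
            out = impute_missing(tm, model_with("fx", b))
            assert out.values.loc["s3", "fx"] == pytest.approx(3.0)
            assert bool(out.imputed.loc["s3", "fx"])

    def test_proportional_case(self):
        tm = toy_matrix(
            {"fx": [3.0, 3.0, np.nan]}, [10.0, 10.0, 20.0], ["L"] * 3,
            coords=[[0, 0]] * 3,
        )
        out = impute_missing(tm, model_with("fx", 1.0))
        assert out.values.loc["s3", "fx"] == pytest.approx(6.0)

    def test_observed_cells_unchanged(self, small_traits):
        tm, truth = small_traits
        model = fit_allometry(tm)
        out = impute_missing(tm, model)
        observed = ~tm.mask
        for c in tm.numeric_features():
            pd.testing.assert_series_equal(
                out.values[c][observed[c]], tm.values[c][observed[c]]
            )
        assert not out.values[tm.numeric_features()].isna().any().any()

    def test_nearest_locality_fallback(self):
        # group "FAR" has no observation for fx; nearest group by centroid is "MID"
        tm = toy_matrix(
            {"fx": [2.0, 2.0, 4.0, 4.0, np.nan]},
            [10.0, 10.0, 10.0, 10.0, 10.0],
            ["NEAR", "NEAR", "MID", "MID", "FAR"],
            coords=[[0, 0], [0, 0], [10, 10], [10, 10], [12, 12]],
        )
        out = impute_missing(tm, model_with("fx", 1.0))
        assert out.values.loc["s5", "fx"] == pytest.approx(4.0)

    def test_missing_coordinates_without_fallback_raise(self):
        tm = toy_matrix(
            {"fx": [2.0, 2.0, np.nan]}, [10.0, 10.0, 10.0],
            ["A", "A", "B"],
            coords=[[0, 0], [0, 0], [np.nan, np.nan]],
        )
        with pytest.raises(ValueError, match="fallback"):
            impute_missing(tm, model_with("fx", 1.0))
        out = impute_missing(tm, model_with("fx", 1.0), fallback={"B": ["A"]})
        assert out.values.loc["s3", "fx"] == pytest.approx(2.0)

    def test_noiseless_linear_allometry_recovered_exactly(self):
        # b = 1: the raw group mean transforms exactly, so held-out values
        # are recovered to machine precision
        spec = TraitSimSpec(
            localities=[
                LocalitySim("A", 0.0, 0.0, np.log(10.0), 0.3),
                LocalitySim("B", 20.0, 20.0, np.log(15.0), 0.3),
            ],
            features=[FeatureSim("fx", a=2.0, b_true=1.0, sigma=0.0)],
            n_per_locality=20,
            missing_rate=0.2,
            seed=3,
        )
        tm, truth = simulate_traits(spec)
        held_out = truth.missing_mask["fx"]
        assert held_out.any()
        out = impute_missing(tm, model_with("fx", 1.0))
        np.testing.assert_allclose(
            out.values.loc[held_out, "fx"],
            truth.true_values.loc[held_out, "fx"],
            rtol=1e-12,
        )

    def test_noisy_recovery_error_below_noise_scale(self):
        sigma = 0.05
        spec = TraitSimSpec(
            localities=[
                LocalitySim("A", 0.0, 0.0, np.log(10.0), 0.2),
                LocalitySim("B", 20.0, 20.0, np.log(15.0), 0.2),
            ],
            features=[FeatureSim("fx", a=1.0, b_true=0.9, sigma=sigma)],
            n_per_locality=100,
            missing_rate=0.2,
            seed=9,
        )
        tm, truth = simulate_traits(spec)
        model = fit_allometry(tm)
        out = impute_missing(tm, model)
        held = truth.missing_mask["fx"]
        rel = np.abs(
            out.values.loc[held, "fx"] / truth.true_values.loc[held, "fx"] - 1.0
        )
        # mean absolute relative error of a log-normal with sd sigma is ~sigma
        assert rel.mean() < 2 * sigma


class TestSizeCorrect:
    def test_identity_when_specimen_is_group_mean_size(self):
        tm = toy_matrix({"fx": [4.0, 6.0]}, [10.0, 10.0], ["L", "L"])
        out = size_correct(tm, model_with("fx", 1.7))
        np.testing.assert_allclose(out.values["fx"], tm.values["fx"])

    def test_zero_slope_is_identity(self):
        tm = toy_matrix({"fx": [4.0, 6.0]}, [5.0, 20.0], ["L", "L"])
        out = size_correct(tm, model_with("fx", 0.0))
        np.testing.assert_allclose(out.values["fx"], tm.values["fx"])

    def test_removes_allometric_slope_within_locality(self):
        spec = TraitSimSpec(
            localities=[LocalitySim("L", 0.0, 0.0, np.log(12.0), 0.3)],
            features=[FeatureSim("fx", a=0.8, b_true=1.2, sigma=0.02)],
            n_per_locality=150,
            missing_rate=0.0,
            seed=21,
        )
        tm, _ = simulate_traits(spec)
        model = fit_allometry(tm)
        out = size_correct(tm, model)
        refit = stats.linregress(np.log(tm.size), np.log(out.values["fx"]))
        assert abs(refit.slope) < 0.02  # residual slope at the noise scale

    def test_requires_complete_matrix(self):
        tm = toy_matrix({"fx": [4.0, np.nan]}, [10.0, 12.0], ["L", "L"])
        with pytest.raises(ValueError, match="missing"):
            size_correct(tm, model_with("fx", 1.0))


class TestFilterAndScale:
    def test_filter_rules_fire_as_logged(self):
        tm = toy_matrix(
            {
                "f3": [1.0, 2.0, 3.0, 4.0],     # kept
                "f19": [8.0, 8.0, 9.0, 8.0],    # configured exclusion
                "f20": [8.0, 8.0, 7.0, 8.0],    # configured exclusion
                "fconst": [2.0, 2.0, 2.0, 2.0],  # near-invariant
                "fnoise": [1.0, 2.0, 1.5, 1.2],  # non-significant slope
                "fcat": [0.0, 1.0, 2.0, 0.0],    # categorical
            },
            [5.0, 10.0, 15.0, 20.0],
            ["L"] * 4,
        )
        tm.features["fcat"] = type(tm.features["fcat"])("fcat", "categorical")
        model = AllometryModel({
            "f3": AllometryEntry("f3", 1.0, 0.0, 1e-8, 4),
            "f19": AllometryEntry("f19", 0.0, 0.0, 0.9, 4),
            "f20": AllometryEntry("f20", 0.0, 0.0, 0.9, 4),
            "fconst": AllometryEntry("fconst", 0.0, 0.7, 1.0, 4),
            "fnoise": AllometryEntry("fnoise", 0.1, 0.0, 0.6, 4),
        })
        out, log = filter_features(tm, model)
        assert out.feature_codes == ["f3"]
        rules = dict(zip(log["feature"], log["rule"]))
        assert rules == {
            "f19": "configured_exclusion",
            "f20": "configured_exclusion",
            "fconst": "near_invariant",
            "fnoise": "nonsignificant_allometry",
            "fcat": "categorical",
        }

    def test_planted_size_independent_features_removed(self):
        spec = TraitSimSpec(
            localities=[LocalitySim("L", 0.0, 0.0, np.log(12.0), 0.3)],
            features=(
                [FeatureSim(f"a{i}", a=1.0, b_true=1.0 + 0.1 * i, sigma=0.05) for i in range(5)]
                + [FeatureSim(f"n{i}", a=1.0, sigma=0.3, size_independent=True) for i in range(3)]
            ),
            n_per_locality=200,
            missing_rate=0.0,
            seed=17,
        )
        tm, _ = simulate_traits(spec)
        out, log = filter_features(tm, fit_allometry(tm), excluded=())
        assert sorted(out.feature_codes) == [f"a{i}" for i in range(5)]
        assert sorted(log["feature"]) == [f"n{i}" for i in range(3)]

    def test_all_removed_raises(self):
        tm = toy_matrix({"fx": [1.0, 1.0, 1.0]}, [5.0, 10.0, 15.0], ["L"] * 3)
        model = AllometryModel({"fx": AllometryEntry("fx", 0.0, 0.0, 1.0, 3)})
        with pytest.raises(ValueError, match="all features"):
            filter_features(tm, model)

    def test_minmax_scale(self):
        tm = toy_matrix({"fx": [2.0, 4.0, 6.0]}, [5.0, 10.0, 15.0], ["L"] * 3)
        out = minmax_scale(tm)
        np.testing.assert_allclose(out.values["fx"], [0.0, 0.5, 1.0])
        again = minmax_scale(out)  # idempotent once bounds are attained
        np.testing.assert_allclose(again.values["fx"], out.values["fx"])

    def test_minmax_postcondition_on_random_matrix(self):
        rng = np.random.default_rng(0)
        tm = toy_matrix(
            {f"f{j}": rng.uniform(1, 9, 12) for j in range(5)},
            rng.uniform(5, 20, 12), ["L"] * 12,
        )
        out = minmax_scale(tm)
        np.testing.assert_allclose(out.values.min(), 0.0, atol=1e-15)
        np.testing.assert_allclose(out.values.max(), 1.0, atol=1e-15)

    def test_minmax_rejects_constant(self):
        tm = toy_matrix({"fx": [2.0, 2.0]}, [5.0, 10.0], ["L"] * 2)
        with pytest.raises(ValueError, match="constant"):
            minmax_scale(tm)


class TestGower:
    def test_identical_rows_zero_extremes_one(self):
        vals = pd.DataFrame([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
        d = gower_distance(vals)
        assert d.iloc[0, 1] == 0.0
        assert d.iloc[0, 2] == 1.0

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(size=(6, 4))
        d = gower_distance(pd.DataFrame(x)).to_numpy()
        np.testing.assert_allclose(d, oracles.gower_loop(x), atol=1e-12)

    def test_missing_aware_and_symmetric(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(size=(8, 5))
        x[rng.uniform(size=x.shape) < 0.25] = np.nan
        d = gower_distance(pd.DataFrame(x)).to_numpy()
        np.testing.assert_allclose(d, oracles.gower_loop(x), atol=1e-12)
        assert (d >= 0).all() and (d <= 1).all()
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0)

    def test_disjoint_pair_raises(self):
        x = pd.DataFrame([[1.0, np.nan], [np.nan, 1.0]])
        with pytest.raises(ValueError, match="no observed feature"):
            gower_distance(x)


class TestNmds:
    def test_embeddable_configuration_recovered(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(12, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = nmds(pd.DataFrame(d), k=2, restarts=4, seed=0)
        assert res.stress < 1e-3
        emb = res.scores.to_numpy()
        de = np.sqrt(((emb[:, None] - emb[None]) ** 2).sum(-1))
        iu = np.triu_indices(12, 1)
        rho = stats.spearmanr(d[iu], de[iu]).statistic
        assert rho == pytest.approx(1.0, abs=1e-9)

    def test_tiny_inputs_zero_stress(self):
        assert nmds(np.zeros((1, 1))).stress == 0.0
        assert nmds(np.array([[0.0, 2.0], [2.0, 0.0]])).stress == 0.0

    def test_never_worse_than_pcoa_start(self, small_traits):
        tm, _ = small_traits
        from moonjelly.morphometrics import fit_allometry as fa
        model = fa(tm)
        full = impute_missing(tm, model)
        keep = [c for c in full.numeric_features() if c != "f40"]
        scaled = minmax_scale(full.with_values(full.values[keep]))
        res = nmds(gower_distance(scaled), seed=2, restarts=4)
        assert res.stress <= res.pcoa_start_stress + 1e-12
        # majorization never increases stress along the winning trajectory
        diffs = np.diff(res.stress_history)
        assert (diffs <= 1e-9).all()

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            nmds(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(10, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        a = nmds(d, seed=3, restarts=3)
        b = nmds(d, seed=3, restarts=3)
        np.testing.assert_array_equal(a.scores.to_numpy(), b.scores.to_numpy())


class TestFeatureScores:
    def _ord(self, n, k=2, seed=0):
        rng = np.random.default_rng(seed)
        d = np.abs(rng.normal(size=(n, n)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        return nmds(d, k=k, restarts=2, seed=seed)

    def test_point_mass_and_uniform_weights(self):
        res = self._ord(5)
        w = pd.DataFrame(0.0, index=res.scores.index, columns=["hot", "flat"])
        w.loc[res.scores.index[2], "hot"] = 1.0
        w["flat"] = 1.0
        fs = feature_scores(res, w)
        np.testing.assert_allclose(
            fs.loc["hot", res.scores.columns].to_numpy(float),
            res.scores.iloc[2].to_numpy(),
        )
        np.testing.assert_allclose(
            fs.loc["flat", res.scores.columns].to_numpy(float),
            res.scores.mean().to_numpy(),
        )

    def test_matches_explicit_weighted_average(self):
        res = self._ord(7, seed=1)
        rng = np.random.default_rng(2)
        w = pd.DataFrame(rng.uniform(size=(7, 3)), index=res.scores.index,
                         columns=["a", "b", "c"])
        fs = feature_scores(res, w)
        for col in w.columns:
            expect = sum(
                w.loc[s, col] * res.scores.loc[s].to_numpy() for s in w.index
            ) / w[col].sum()
            np.testing.assert_allclose(
                fs.loc[col, res.scores.columns].to_numpy(float), expect
            )

    def test_zero_weight_feature_flagged(self):
        res = self._ord(4)
        w = pd.DataFrame(0.0, index=res.scores.index, columns=["dead"])
        fs = feature_scores(res, w)
        assert not fs.loc["dead", "defined"]
        assert fs.loc["dead", res.scores.columns].isna().all()

    def test_mismatched_specimens_raise(self):
        res = self._ord(4)
        w = pd.DataFrame(1.0, index=["x", "y", "z", "w"], columns=["a"])
        with pytest.raises(ValueError, match="match"):
            feature_scores(res, w)


class TestMantel:
    @staticmethod
    def _rand_dist(n, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 2))
        return np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))

    def test_self_correlation(self):
        d = self._rand_dist(10, 0)
        res = mantel_test(d, d, permutations=99, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.pvalue == pytest.approx(1 / 100)

    def test_matches_double_loop_oracle(self):
        dx = self._rand_dist(6, 1)
        dy = self._rand_dist(6, 2)
        res = mantel_test(dx, dy, permutations=9, seed=0)
        assert res.r == pytest.approx(oracles.mantel_r_loop(dx, dy), abs=1e-12)

    def test_agrees_with_skbio(self):
        skbio_mantel = pytest.importorskip("skbio.stats.distance").mantel
        dx = self._rand_dist(12, 3)
        dy = self._rand_dist(12, 4)
        r_skbio = skbio_mantel(dx, dy, method="pearson", permutations=0)[0]
        res = mantel_test(dx, dy, permutations=9, seed=0)
        assert res.r == pytest.approx(float(r_skbio), abs=1e-10)

    def test_p_bounds_and_small_n_error(self):
        d = self._rand_dist(5, 5)
        res = mantel_test(d, self._rand_dist(5, 6), permutations=99, seed=0)
        assert 1 / 100 <= res.pvalue <= 1.0
        with pytest.raises(ValueError, match="at least 4"):
            mantel_test(self._rand_dist(3, 0), self._rand_dist(3, 1))


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_equal_variance_equal_n_matches_pooled(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.0, 3.0, 4.0, 5.0]
        t, df, p = welch_t(a, b)
        pooled = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(float(pooled.statistic), abs=1e-12)
        assert p == pytest.approx(float(pooled.pvalue), abs=1e-12)

    def test_matches_closed_form(self):
        a = [12.1, 14.3, 11.8, 13.0, 12.7]
        b = [15.9, 16.2, 14.8]
        t, df, p = welch_t(a, b)
        to, dfo, po = oracles.welch_formula(a, b)
        assert t == pytest.approx(to, abs=1e-10)
        assert df == pytest.approx(dfo, abs=1e-10)
        assert p == pytest.approx(po, abs=1e-10)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            welch_t([1.0], [1.0, 2.0])


def test_geographic_distance_methods():
    coords = pd.DataFrame(
        {"lat": [0.0, 0.0, 3.0], "lon": [0.0, 4.0, 0.0]}, index=["a", "b", "c"]
    )
    d = geographic_distances(coords)
    assert d.loc["a", "b"] == pytest.approx(4.0)
    assert d.loc["a", "c"] == pytest.approx(3.0)
    gc = geographic_distances(coords, method="greatcircle")
    # one degree of longitude at the equator ~111.19 km
    assert gc.loc["a", "b"] == pytest.approx(4 * 111.19, rel=1e-3)
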