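import numpy as np
import pandas as pd
import pytest

from regrowage.age_predictors import (
    RFConfig,
    extract_predictors,
    filter_correlated,
    importance,
    partial_dependence,
    stratified_sample,
    tune_and_train,
)
from regrowage.stack_io import AgeMap, GeoRef

GEOREF = GeoRef((30.0, 0.0, 0.0, 0.0, -30.0, 0.0), "synthetic")
SMALL_RF = RFConfig(search=False, final_ntree=100, final_mtry=2, seed=0)


def striped_age_map(n_per_age=40, ages=range(3, 11)):
    """Age map with exactly n_per_age pixels of each requested age."""
    vals = np.concatenate([[a] * n_per_age for a in ages])
    side = int(np.ceil(np.sqrt(vals.size)))
    arr = np.zeros(side * side, dtype=np.int16)
    arr[: vals.size] = vals
    return AgeMap(2023, arr.reshape(side, side), GEOREF, 0.09)


def make_table(n=600, seed=0, signal="linear"):
    rng = np.random.default_rng(seed)
    x1 = rng.random(n)
    x2 = rng.random(n)
    x3 = rng.random(n)
    if signal == "linear":
        age = 3 + 31 * x1
    elif signal == "noise":
        age = rng.uniform(3, 34, n)
    return pd.DataFrame({"age": age, "x1": x1, "x2": x2, "x3": x3})


class TestSampler:
    def test_small_stratum_is_exhausted(self):
        amap = striped_age_map(5, ages=[3])
        out = stratified_sample(amap, n_per_age=10_000, seed=0)
        assert len(out) == 5

    def test_full_strata_yield_exact_counts(self):
        amap = striped_age_map(40, ages=range(3, 11))
        out = stratified_sample(amap, n_per_age=25, seed=0)
        assert out.groupby("age").size().eq(25).all()

    def test_determinism(self):
        amap = striped_age_map(40)
        a = stratified_sample(amap, 10, seed=3)
        b = stratified_sample(amap, 10, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_sampling_without_replacement(self):
        amap = striped_age_map(40)
        out = stratified_sample(amap, 40, seed=1)
        assert not out.duplicated(["row", "col"]).any()


class TestExtraction:
    def test_nearest_cell_lookup_and_constant_column(self):
        amap = striped_age_map(10, ages=[3, 4])
        pts = stratified_sample(amap, 5, seed=0)
        grid_vals = np.arange(amap.ages.size, dtype=float).reshape(amap.ages.shape)
        out = extract_predictors(pts, {"idx": grid_vals, "const": np.full(amap.ages.shape, 7.0)})
        assert (out["const"] == 7.0).all()
        for rec in out.itertuples():
            assert rec.idx == grid_vals[rec.row, rec.col]

    def test_nodata_rows_dropped(self):
        amap = striped_age_map(10, ages=[3])
        pts = stratified_sample(amap, 10, seed=0)
        holes = np.ones(amap.ages.shape)
        rr = pts.row.to_numpy()[:3]
        cc = pts.col.to_numpy()[:3]
        holes[rr, cc] = -9999.0
        out = extract_predictors(pts, {"p": holes}, nodata={"p": -9999.0})
        assert len(out) == len(pts) - 3

    def test_name_collision_rejected(self):
        amap = striped_age_map(5, ages=[3])
        pts = stratified_sample(amap, 5, seed=0)
        with pytest.raises(ValueError, match="collision"):
            extract_predictors(pts, {"age": np.ones(amap.ages.shape)})


class TestCorrelationFilter:
    def test_duplicate_column_drops_exactly_one(self, rng):
        x = rng.random(200)
        t = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.random(200)})
        _, kept, removed = filter_correlated(t, ["a", "b", "c"])
        assert len(removed) == 1
        assert set(kept) & {"a", "b"} and "c" in kept

    def test_uncorrelated_set_is_identity(self, rng):
        t = pd.DataFrame(rng.random((300, 4)), columns=list("abcd"))
        _, kept, removed = filter_correlated(t, list("abcd"))
        assert kept == list("abcd") and not removed

    def test_matches_independent_greedy_trace(self, rng):
        # three collinear variables; verify against a from-scratch run of
        # the stated rule (drop the worst-pair member with larger mean |r|)
        n = 500
        z = rng.standard_normal(n)
        t = pd.DataFrame({
            "a": z,
            "b": z + 0.05 * rng.standard_normal(n),
            "c": z + 0.3 * rng.standard_normal(n),
            "d": rng.standard_normal(n),
        })
        cols = list("abcd")
        expect = cols.copy()
        while True:
            corr = t[expect].corr().abs()
            best, pair = 0.0, None
            for i, u in enumerate(expect):
                for v in expect[i + 1:]:
                    if corr.loc[u, v] > best:
                        best, pair = corr.loc[u, v], (u, v)
            if best <= 0.9:
                break
            u, v = pair
            mu = corr.loc[u, [w for w in expect if w != u]].mean()
            mv = corr.loc[v, [w for w in expect if w != v]].mean()
            expect.remove(u if mu >= mv else v)
        _, kept, _ = filter_correlated(t, cols)
        assert kept == expect


class TestTuneAndTrain:
    def test_noiseless_linear_signal_recovered(self):
        t = make_table(signal="linear")
        model, report, _ = tune_and_train(t, ["x1", "x2", "x3"], SMALL_RF)
        assert report.r2 >= 0.95

    def test_pure_noise_has_no_skill(self):
        t = make_table(signal="noise")
        _, report, _ = tune_and_train(t, ["x1", "x2", "x3"], SMALL_RF)
        assert report.r2 <= 0.1

    def test_split_is_disjoint_and_exhaustive(self):
        t = make_table()
        _, report, (tr, te) = tune_and_train(t, ["x1", "x2"], SMALL_RF)
        assert len(set(tr) & set(te)) == 0
        assert len(tr) + len(te) == len(t)
        assert report.n_train == len(tr) == round(0.75 * len(t))

    def test_grid_search_is_deterministic(self):
        t = make_table(n=300)
        cfg = RFConfig(ntree_grid=(50, 100), mtry_grid=(1, 2), cv_folds=3, seed=5)
        m1, r1, s1 = tune_and_train(t, ["x1", "x2", "x3"], cfg)
        m2, r2, s2 = tune_and_train(t, ["x1", "x2", "x3"], cfg)
        assert (r1.ntree, r1.mtry) == (r2.ntree, r2.mtry)
        assert np.array_equal(s1[0], s2[0])
        assert r1.r2 == r2.r2
        assert r1.cv_results is not None and len(r1.cv_results) == 4

    def test_excessive_mtry_rejected(self):
        t = make_table()
        cfg = RFConfig(search=False, final_ntree=10, final_mtry=7)
        with pytest.raises(ValueError, match="mtry"):
            tune_and_train(t, ["x1", "x2"], cfg)


class TestImportance:
    def test_causal_predictor_ranks_first_both_measures(self):
        t = make_table(signal="linear")
        model, _, _ = tune_and_train(t, ["x1", "x2", "x3"], SMALL_RF)
        imp = importance(model, t, ["x1", "x2", "x3"], seed=0)
        assert imp.predictor.iloc[0] == "x1"
        assert imp.sort_values("permutation_importance", ascending=False
                               ).predictor.iloc[0] == "x1"

    def test_noise_predictors_score_near_zero(self):
        t = make_table(signal="linear")
        model, _, _ = tune_and_train(t, ["x1", "x2", "x3"], SMALL_RF)
        imp = importance(model, t, ["x1", "x2", "x3"], seed=0).set_index("predictor")
        causal = imp.loc["x1", "corrected_impurity"]
        for null in ("x2", "x3"):
            assert abs(imp.loc[null, "corrected_impurity"]) < 0.1 * causal
        assert np.isfinite(imp.to_numpy(float)).all()


class TestPartialDependence:
    def test_flat_for_ignored_predictor(self):
        t = make_table(signal="linear")
        model, _, _ = tune_and_train(t, ["x1", "x2", "x3"], SMALL_RF)
        curve = partial_dependence(model, t, "x2", ["x1", "x2", "x3"])
        span = curve.mean_prediction.max() - curve.mean_prediction.min()
        assert span < 0.1 * t.age.std()

    def test_monotone_for_monotone_signal(self):
        t = make_table(signal="linear")
        model, _, _ = tune_and_train(t, ["x1", "x2", "x3"], SMALL_RF)
        curve = partial_dependence(model, t, "x1", ["x1", "x2", "x3"])
        from scipy.stats import spearmanr
        assert spearmanr(curve.value, curve.mean_prediction).statistic > 0.95

    def test_grid_endpoints_match_observed_range(self):
        t = make_table(n=100)
        model, _, _ = tune_and_train(t, ["x1", "x2"], SMALL_RF)
        curve = partial_dependence(model, t, "x1", ["x1", "x2"], grid_points=11)
        assert curve.value.iloc[0] == pytest.approx(t.x1.min())
        assert curve.value.iloc[-1] == pytest.approx(t.x1.max())

    def test_unknown_predictor_rejected(self):
        t = make_table(n=100)
        model, _, _ = tune_and_train(t, ["x1", "x2"], SMALL_RF)
        with pytest.raises(KeyError):
            partial_dependence(model, t, "nope", ["x1", "x2"])
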