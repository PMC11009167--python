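"""Design matrix, elastic net, nested CV, performance and associations."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats as sps

from celltreeage.agemodel import (
    CellTreeAge,
    FittedModel,
    age_acceleration,
    build_design,
    elastic_net,
    enet_objective,
    marker_associations,
    performance_metrics,
)
from celltreeage.features import FEATURE_NAMES


@pytest.fixture(scope="module")
def planted_model(synthetic_feature_cohort):
    features, metadata = synthetic_feature_cohort
    return CellTreeAge.from_features(features, metadata)


class TestBuildDesign:
    def test_63_predictors_and_row_count(self, synthetic_feature_cohort):
        features, metadata = synthetic_feature_cohort
        d = build_design(features, metadata)
        assert len(d.predictor_names) == 63
        assert d.n_tot == 18 * 5
        assert d.n_samples == 18

    def test_all_female_interactions_vanish(self, synthetic_feature_cohort):
        features, metadata = synthetic_feature_cohort
        meta = metadata.assign(sex="F")
        model = CellTreeAge.from_features(features, meta)
        rows = np.arange(model.design.n_tot)
        X = model._design_matrix(rows, *model._make_transform(rows))
        assert np.all(X[:, 31:] == 0.0)  # sex column and every interaction

    def test_missing_metadata_named(self, synthetic_feature_cohort):
        features, metadata = synthetic_feature_cohort
        with pytest.raises(ValueError, match="P00"):
            build_design(features, metadata[metadata.sample_id != "P00"])

    def test_non_finite_features_rejected(self, synthetic_feature_cohort):
        features, metadata = synthetic_feature_cohort
        bad = features.copy()
        bad.loc[3, FEATURE_NAMES[2]] = np.nan
        with pytest.raises(ValueError, match=FEATURE_NAMES[2]):
            build_design(bad, metadata)

    def test_inconsistent_ages_rejected(self, synthetic_feature_cohort):
        features, metadata = synthetic_feature_cohort
        from celltreeage.agemodel import CohortDesign

        d = build_design(features, metadata)
        y = d.y.copy()
        y[0] += 1.0
        with pytest.raises(ValueError):
            CohortDesign(sample_ids=d.sample_ids, replicate_ids=d.replicate_ids,
                         stats=d.stats, sex=d.sex, y=y)


class TestElasticNet:
    def test_full_shrinkage_limit(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(50, 10, 20)
        fit = elastic_net(X, y, lam=1e3, alpha=0.8)
        assert np.allclose(fit.beta, 0.0)
        assert fit.mu == pytest.approx(y.mean())

    def test_no_penalty_recovers_ols(self, rng):
        x = rng.normal(size=30)
        y = 3.0 * x + 7.0
        fit = elastic_net(x[:, None], y, lam=0.0, alpha=1.0, standardize=False)
        assert fit.beta[0] == pytest.approx(3.0, abs=1e-6)
        assert fit.mu == pytest.approx(7.0, abs=1e-6)

    @pytest.mark.parametrize("lam,alpha", [(0.5, 1.0), (1.0, 0.6), (2.0, 0.0)])
    def test_objective_matches_convex_solver(self, lam, alpha, rng):
        """Independent oracle: minimize the objective directly with BFGS on
        a smoothed |.| (tight smoothing), compare objective values."""
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        fit = elastic_net(X, y, lam, alpha, standardize=False)
        ours = enet_objective(X, y, fit.mu, fit.beta, lam, alpha)

        eps = 1e-9

        def obj(params):
            mu, b = params[0], params[1:]
            r = y - mu - X @ b
            return (r @ r) / (2 * len(y)) + lam * ((1 - alpha) * (b @ b) / 2
                                                   + alpha * np.sqrt(b * b + eps).sum())

        best = None
        for trial in range(4):
            x0 = np.concatenate([[y.mean()], rng.normal(0, 0.5, 3)])
            res = optimize.minimize(obj, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-12,
                                             "maxiter": 20000})
            best = res.fun if best is None else min(best, res.fun)
        assert ours <= best + 1e-4
        assert abs(ours - best) < 1e-4

    def test_kkt_conditions(self, rng):
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        lam, alpha = 0.3, 0.7
        fit = elastic_net(X, y, lam, alpha, standardize=False)
        r = y - fit.mu - X @ fit.beta
        grad = -X.T @ r / len(y) + lam * (1 - alpha) * fit.beta
        for j, b in enumerate(fit.beta):
            if b != 0:
                assert grad[j] + lam * alpha * np.sign(b) == pytest.approx(0, abs=1e-5)
            else:
                assert abs(grad[j]) <= lam * alpha + 1e-5

    def test_zero_variance_column_standardized_safely(self, rng):
        X = np.column_stack([np.ones(15), rng.normal(size=15)])
        y = rng.normal(size=15)
        fit = elastic_net(X, y, 0.1, 0.9, standardize=True)
        assert np.isfinite(fit.beta).all()


class TestNestedCV:
    def test_fold_structure_counts(self, planted_model):
        res = planted_model.fit(lambda_grid=(1.0,), alpha_grid=(0.9,))
        assert len(res.fold_hyperparams) == 18          # outer folds
        assert len(res.coefficients) == 18              # one estimate set per fold
        assert all(len(v) == 17 for v in res.folds.values())  # inner fold count
        assert res.predictions["predicted_age"].notna().all()
        assert len(res.predictions) == 90

    def test_group_hygiene(self, planted_model):
        res = planted_model.fit(lambda_grid=(1.0,), alpha_grid=(1.0,))
        for held, train in res.folds.items():
            assert held not in train

    def test_degenerate_grid_equals_plain_loocv(self, planted_model):
        """With a single (lambda, alpha) pair, nested CV is plain
        leave-one-sample-out at that pair."""
        lam, alpha = 0.3, 0.8
        res = planted_model.fit(lambda_grid=(lam,), alpha_grid=(alpha,))
        d = planted_model.design
        for held in d.unique_samples:
            tr = d.rows_of([s for s in d.unique_samples if s != held])
            te = d.rows_of([held])
            fit, center, scale = planted_model._fit_fold(tr, lam, alpha)
            manual = planted_model._predict_rows(fit, center, scale, te)
            got = res.predictions.loc[res.predictions.sample_id == held,
                                      "predicted_age"].to_numpy()
            assert np.allclose(manual, got)

    def test_empty_grid_rejected(self, planted_model):
        with pytest.raises(ValueError):
            planted_model.fit(lambda_grid=(), alpha_grid=())

    def test_planted_signal_recovered(self, planted_model):
        res = planted_model.fit()
        assert res.performance.r > 0.8
        dummy = planted_model.fit_dummy()
        assert res.performance.mae < dummy.performance.mae


class TestPerformance:
    def test_perfect_predictions(self):
        p = performance_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (p.mae, p.mdae, p.rmse) == (0.0, 0.0, 0.0)
        assert p.r == pytest.approx(1.0)

    def test_hand_computed_example(self):
        p = performance_metrics([1.0, 5.0], [2.0, 4.0])
        assert p.mae == 1.0 and p.rmse == 1.0 and p.mdae == 1.0
        assert p.r == pytest.approx(1.0)

    def test_mae_never_exceeds_rmse(self, rng):
        for _ in range(20):
            y = rng.normal(size=30)
            yh = rng.normal(size=30)
            p = performance_metrics(y, yh)
            assert p.mae <= p.rmse + 1e-12

    def test_constant_predictions_flagged(self):
        p = performance_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert p.r == 0.0 and not p.r_defined


class TestAgeAcceleration:
    def test_on_trend_line_gives_zero(self):
        y = np.array([20.0, 40.0, 60.0])
        yh = 0.5 * y + 12
        diff, acc = age_acceleration(y, yh)
        assert np.allclose(acc, 0.0, atol=1e-12)

    def test_mean_acceleration_is_zero(self, rng):
        y = rng.uniform(20, 80, 40)
        yh = y + rng.normal(0, 5, 40)
        _, acc = age_acceleration(y, yh)
        assert acc.mean() == pytest.approx(0.0, abs=1e-9)

    def test_identity_predictions(self):
        y = np.array([30.0, 50.0, 70.0])
        diff, acc = age_acceleration(y, y)
        assert np.allclose(diff, 0.0)

    def test_single_age_rejected(self):
        with pytest.raises(ValueError):
            age_acceleration([40.0, 40.0], [41.0, 39.0])


class TestDummyBaseline:
    def test_hand_computed_loo_means(self):
        rows = []
        for i, age in enumerate([20.0, 40.0, 60.0]):
            vals = {f: 0.0 for f in FEATURE_NAMES}
            rows.append({"sample_id": f"s{i}", "replicate_id": 0, **vals})
        features = pd.DataFrame(rows)
        meta = pd.DataFrame({"sample_id": ["s0", "s1", "s2"],
                             "age": [20.0, 40.0, 60.0], "sex": ["F", "M", "F"]})
        res = CellTreeAge.from_features(features, meta).fit_dummy()
        got = dict(zip(res.predictions.sample_id, res.predictions.predicted_age))
        assert got == {"s0": 50.0, "s1": 40.0, "s2": 30.0}
        assert res.performance.mae == pytest.approx(20.0)

    def test_shrinkage_limit_equivalence(self, planted_model):
        """nested CV on a huge-lambda grid reproduces the dummy baseline."""
        res = planted_model.fit(lambda_grid=(1e9,), alpha_grid=(1.0,))
        dummy = planted_model.fit_dummy()
        assert np.array_equal(res.predictions["predicted_age"].to_numpy(),
                              dummy.predictions["predicted_age"].to_numpy())


class TestPreselection:
    def test_k_all_is_identity(self, planted_model):
        grids = dict(lambda_grid=(0.3, 3.0), alpha_grid=(0.8, 1.0))
        pre = planted_model.fit_preselected([63], **grids)
        base = planted_model.fit(**grids)
        assert np.allclose(pre.per_k[63].predictions["predicted_age"],
                           base.predictions["predicted_age"])

    def test_ranking_is_permutation(self, planted_model):
        pre = planted_model.fit_preselected([5], lambda_grid=(1.0,), alpha_grid=(1.0,))
        assert sorted(pre.ranking) == sorted(planted_model.design.predictor_names)

    def test_small_k_runs_and_reports(self, planted_model):
        pre = planted_model.fit_preselected([1, 5], lambda_grid=(1.0,), alpha_grid=(1.0,))
        assert set(pre.per_k) == {1, 5}
        assert pre.best_k in (1, 5)


class TestExternal:
    def test_train_as_test_bounded_by_cv_error(self, planted_model):
        ext = planted_model.fit_external(planted_model)
        cv = planted_model.fit()
        assert ext.performance.mae <= cv.performance.mae

    def test_generalizes_to_fresh_cohort(self, synthetic_feature_cohort):
        features, metadata = synthetic_feature_cohort
        rng = np.random.default_rng(7)
        # a second cohort from the same generative recipe
        rows = []
        ages = rng.uniform(21, 82, 10)
        for i in range(10):
            for r in range(3):
                vals = {}
                for j, f in enumerate(FEATURE_NAMES):
                    vals[f] = (0.05 * ages[i] * (j + 1) + rng.normal(0, 0.8)
                               if j < 5 else rng.normal(0, 1))
                rows.append({"sample_id": f"Q{i}", "replicate_id": r, **vals})
        meta2 = pd.DataFrame({"sample_id": [f"Q{i}" for i in range(10)],
                              "age": ages, "sex": ["F"] * 10})
        train = CellTreeAge.from_features(features, metadata)
        test = CellTreeAge.from_features(pd.DataFrame(rows), meta2)
        res = train.fit_external(test)
        assert res.performance.r > 0

    def test_empty_test_rejected(self, planted_model):
        from celltreeage.agemodel import CohortDesign

        empty = CohortDesign(sample_ids=[], replicate_ids=[],
                             stats=np.zeros((0, 31)), sex=np.zeros(0), y=np.zeros(0))
        with pytest.raises(ValueError):
            planted_model.fit_external(CellTreeAge(empty))

    def test_fitted_model_json_round_trip(self, planted_model, tmp_path):
        fm = planted_model.fit_final(lambda_grid=(1.0,), alpha_grid=(1.0,))
        fm.to_json(tmp_path / "m.json")
        fm2 = FittedModel.from_json(tmp_path / "m.json")
        p1 = fm.predict_design(planted_model.design)["predicted_age"]
        p2 = fm2.predict_design(planted_model.design)["predicted_age"]
        assert np.allclose(p1, p2)


class TestMarkerAssociations:
    @pytest.fixture
    def sample_table(self):
        rng = np.random.default_rng(3)
        ages = rng.uniform(20, 80, 12)
        return pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(12)],
            "age": ages,
            "cell_tree_age": ages + rng.normal(0, 6, 12),
            "sex": ["F", "M"] * 6,
        })

    def test_marker_equal_to_age(self, sample_table):
        markers = sample_table[["sample_id", "age"]].rename(columns={"age": "glucose"})
        out = marker_associations(sample_table, markers)
        row = out[(out.stratum == "All") & (out.marker == "glucose")].iloc[0]
        assert row["r_chron_age"] == pytest.approx(1.0)
        assert row["sig_chron_age"]

    def test_constant_marker_skipped(self, sample_table):
        markers = pd.DataFrame({"sample_id": sample_table.sample_id, "albumin": 4.2})
        out = marker_associations(sample_table, markers)
        assert (out["note"].str.contains("constant")).all()

    def test_textbook_r_and_p(self, sample_table):
        rng = np.random.default_rng(8)
        markers = pd.DataFrame({"sample_id": sample_table.sample_id,
                                "crp": rng.normal(size=12)})
        out = marker_associations(sample_table, markers)
        row = out[(out.stratum == "All") & (out.marker == "crp")].iloc[0]
        x = markers["crp"].to_numpy()
        y = sample_table["cell_tree_age"].to_numpy()
        r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        t = r * np.sqrt((12 - 2) / (1 - r * r))
        p = 2 * sps.t.sf(abs(t), 12 - 2)
        assert row["r_cell_tree_age"] == pytest.approx(r, abs=1e-12)
        assert row["p_cell_tree_age"] == pytest.approx(p, rel=1e-9)

    def test_small_stratum_skipped(self, sample_table):
        small = sample_table.head(4)  # 2 per sex
        markers = pd.DataFrame({"sample_id": small.sample_id,
                                "x": [1.0, 2.0, 3.0, 4.0]})
        out = marker_associations(small, markers)
        male = out[(out.stratum == "Male") & (out.marker == "x")].iloc[0]
        assert "fewer than 3" in male["note"]
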