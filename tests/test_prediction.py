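"""Predictors, case-control designs, accuracy metrics, and the QRS pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import agearch as a
from agearch.errors import DegenerateInputError, EmptySetError, ParameterError


class TestCalibratePredictor:
    def test_perfect_predictor_is_standardized_liability(self):
        L = np.random.default_rng(1).normal(2.0, 3.0, 1000)
        s = a.calibrate_predictor(L, 1.0, seed=2)
        assert np.corrcoef(s.values, L)[0, 1] == pytest.approx(1.0)
        assert s.values.mean() == pytest.approx(0.0, abs=1e-10)
        assert s.values.std(ddof=1) == pytest.approx(1.0)

    def test_noise_variance_closed_form(self):
        # t = 0.05 -> noise variance 19 * var(L)
        rng = np.random.default_rng(3)
        L = rng.normal(0, 1, 200_000)
        s = a.calibrate_predictor(L, 0.05, seed=4)
        # reconstruct the (unstandardized) noise variance from realized corr
        r2 = np.corrcoef(s.values, L)[0, 1] ** 2
        implied = L.var() * (1 - r2) / r2
        assert implied == pytest.approx(19 * L.var(), rel=0.05)

    def test_realized_r2_near_target(self):
        L = np.random.default_rng(5).normal(0, 1, 100_000)
        s = a.calibrate_predictor(L, 0.5, seed=6)
        assert np.corrcoef(s.values, L)[0, 1] ** 2 == pytest.approx(0.5, abs=0.01)

    def test_invalid_target(self):
        with pytest.raises(ParameterError):
            a.calibrate_predictor(np.zeros(10) + np.arange(10), 0.0, seed=0)


class TestRankNormal:
    def test_order_preserved_and_standardized(self):
        x = np.random.default_rng(7).exponential(size=5000)
        z = a.rank_normal(x)
        assert stats.spearmanr(x, z).statistic == pytest.approx(1.0)
        assert z.mean() == pytest.approx(0.0, abs=0.01)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=0.01)

    def test_blom_plug_in_n3(self):
        z = a.rank_normal(np.array([5.0, -2.0, 11.0]))
        c = 3.0 / 8.0
        expect = stats.norm.ppf((np.array([2.0, 1.0, 3.0]) - c) / (3 - 2 * c + 1))
        assert np.allclose(z, expect)
        assert z[1] < z[0] < z[2]

    def test_ties_share_average_rank(self):
        z = a.rank_normal(np.array([1.0, 1.0, 2.0]))
        assert z[0] == z[1] < z[2]

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            a.rank_normal(np.ones(5))


@pytest.fixture(scope="module")
def signal_data():
    rng = np.random.default_rng(8)
    n = 3000
    latent = rng.normal(0, 1, n)
    X = np.column_stack(
        [latent + rng.normal(0, 0.5, n)] + [rng.normal(0, 1, n) for _ in range(9)]
    )
    y = (latent > np.quantile(latent, 0.85)).astype(float)
    return X, y


class TestEstimatedLiability:
    def test_selects_informative_trait(self, signal_data):
        X, y = signal_data
        score, coef = a.fit_estimated_liability(X, y, n_folds=5, rule="1se", seed=1)
        assert coef[0] > 0
        assert (np.abs(coef[1:]) < np.abs(coef[0]) / 3).all()
        assert np.corrcoef(score.values, y)[0, 1] > 0.3

    def test_2se_penalty_at_least_1se(self, signal_data):
        from sklearn.linear_model import lasso_path
        from sklearn.model_selection import StratifiedKFold
        from agearch.prediction import _lasso_cv_curve

        X, y = signal_data
        Xs = (X - X.mean(0)) / X.std(0)
        alphas, _, _ = lasso_path(Xs, y, alphas=60)
        folds = list(StratifiedKFold(5, shuffle=True, random_state=1).split(Xs, y))
        cvm, cvse = _lasso_cv_curve(Xs, y, alphas, folds)
        i_min = int(np.argmin(cvm))
        a1 = alphas[cvm <= cvm[i_min] + cvse[i_min]].max()
        a2 = alphas[cvm <= cvm[i_min] + 2 * cvse[i_min]].max()
        assert a2 >= a1

    def test_too_few_cases(self, signal_data):
        X, _ = signal_data
        y = np.zeros(len(X))
        y[:3] = 1
        with pytest.raises(ParameterError):
            a.fit_estimated_liability(X, y, n_folds=10)


def _toy_cohort():
    """10 diagnosed at distinct ages 50..59 + 40 never-diagnosed, censored late."""
    ids = [f"c{i}" for i in range(10)] + [f"h{i}" for i in range(40)]
    individuals = pd.DataFrame(
        {
            "id": ids,
            "sex": [0, 1] * 25,
            "baseline_age": 45.0,
            "censor_age": [85.0] * 50,
        }
    )
    diagnoses = pd.DataFrame(
        {
            "id": [f"c{i}" for i in range(10)],
            "disease": "dz",
            "age_at_diagnosis": [50.0 + i for i in range(10)],
        }
    )
    return a.CohortTable(
        individuals=individuals,
        visits=pd.DataFrame(columns=["id", "visit", "age", "trait", "value"]),
        diagnoses=diagnoses,
    )


class TestCaseControlConstruction:
    def test_toy_incident_quintiles(self):
        table = _toy_cohort()
        sets = a.incident_case_sets(table, "dz", n_bins=5, seed=1)
        assert [len(s.case_ids) for s in sets] == [2] * 5
        assert all(len(s.control_ids) == len(s.case_ids) for s in sets)
        ind = table.individuals
        for s in sets:
            lo, hi = s.interval
            case_ids = set(ind["id"].iloc[s.case_ids])
            # brute force: exactly the individuals diagnosed in (lo, hi]
            expect = {
                f"c{i}" for i in range(10) if (50.0 + i > lo and 50.0 + i <= hi) or (50.0 + i == lo and s.bin == 1)
            }
            assert case_ids == expect
            # controls never diagnosed inside or before the interval
            ctrl_ids = set(ind["id"].iloc[s.control_ids])
            diag_map = dict(zip(table.diagnoses["id"], table.diagnoses["age_at_diagnosis"]))
            assert all(diag_map.get(c, np.inf) > hi for c in ctrl_ids)

    def test_earlier_diagnosis_excluded_from_later_interval(self):
        table = _toy_cohort()
        sets = a.incident_case_sets(table, "dz", n_bins=5, seed=2)
        last = sets[-1]
        ids = set(table.individuals["id"].iloc[last.ids()])
        assert "c0" not in ids  # diagnosed years before the oldest interval

    def test_prevalent_counts_cumulative(self):
        table = _toy_cohort()
        inc = a.incident_case_sets(table, "dz", n_bins=5, seed=3)
        # use each interval's end as baseline: prevalent = everyone diagnosed before it
        baselines = [s.interval[1] + 0.01 for s in inc]
        prev = a.prevalent_case_sets(table, "dz", baselines, seed=3)
        assert [len(s.case_ids) for s in prev] == [2, 4, 6, 8, 10]
        assert all(len(s.control_ids) == len(s.case_ids) for s in prev)

    def test_baseline_before_all_diagnoses_errors(self):
        with pytest.raises(EmptySetError):
            a.prevalent_case_sets(_toy_cohort(), "dz", [30.0], seed=0)

    def test_lost_to_followup_switch(self):
        table = _toy_cohort()
        # censor half the healthy individuals inside the oldest interval
        table.individuals.loc[
            table.individuals["id"].isin([f"h{i}" for i in range(20)]), "censor_age"
        ] = 58.6
        with_lost = a.incident_case_sets(table, "dz", 5, seed=4, include_lost_to_followup=True)
        without = a.incident_case_sets(table, "dz", 5, seed=4, include_lost_to_followup=False)
        assert with_lost[-1].K < without[-1].K  # larger control pool with the lost


class TestObservedR2:
    def test_self_prediction_and_orthogonality(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 500).astype(float)
        cov = rng.normal(size=(500, 2))
        from agearch.prediction import _residualize

        resid = _residualize(y, cov)
        assert a.observed_r2(resid, y, cov) == pytest.approx(1.0)
        assert a.observed_r2(rng.normal(size=500), y, cov) < 0.02

    def test_six_point_hand_example(self):
        score = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([0.0, 0.0, 1.0, 0.0, 1.0, 1.0])
        r = np.corrcoef(y - y.mean(), score)[0, 1]
        assert a.observed_r2(score, y) == pytest.approx(r * r)

    def test_constant_score_rejected(self):
        with pytest.raises(DegenerateInputError):
            a.observed_r2(np.ones(10), np.arange(10) % 2)


class TestAssociationMetrics:
    def test_perfect_separation_auc(self):
        y = np.repeat([0.0, 1.0], 50)
        s = np.concatenate([np.random.default_rng(1).normal(-3, 0.1, 50),
                            np.random.default_rng(2).normal(3, 0.1, 50)])
        est = a.association_metrics(s, y, None, "auc")
        assert est.value == pytest.approx(1.0)

    def test_independent_score_null_metrics(self):
        rng = np.random.default_rng(10)
        y = rng.integers(0, 2, 2000).astype(float)
        s = rng.normal(size=2000)
        auc = a.association_metrics(s, y, None, "auc")
        assert auc.value == pytest.approx(0.5, abs=0.03)
        lor = a.association_metrics(s, y, None, "log_or")
        assert abs(lor.value) < 3 * lor.se
        lin = a.association_metrics(s, y, None, "linear_effect")
        assert abs(lin.value) < 3 * lin.se

    def test_cox_loghr_simulation_oracle(self):
        """Exponential survival with hazard ratio e per unit score -> logHR ~ 1."""
        rng = np.random.default_rng(11)
        n = 3000
        s = rng.normal(size=n)
        t = rng.exponential(1.0 / np.exp(s * 1.0))
        cens = np.quantile(t, 0.8)
        durations = np.minimum(t, cens)
        events = (t <= cens).astype(int)
        est = a.association_metrics(s, events, None, "log_hr", durations=durations, events=events)
        # score was standardized internally; 1 unit of raw s ~ 1 sd
        assert est.value == pytest.approx(1.0, abs=3 * est.se + 0.05)

    def test_unknown_metric(self):
        with pytest.raises(ParameterError):
            a.association_metrics(np.arange(10.0), np.arange(10) % 2, None, "c_index")


class TestLiabilityScaleTransforms:
    def test_zero_maps_to_zero_and_monotone(self):
        assert a.liability_r2_transform(0.0, 0.1, 0.5) == 0.0
        grid = [a.liability_r2_transform(r, 0.1, 0.5) for r in (0.01, 0.05, 0.1)]
        assert grid == sorted(grid)

    def test_inverse_round_trip(self):
        r2l = 0.05
        r2o = a.inverse_liability_r2_transform(r2l, 0.1, 0.5)
        assert a.liability_r2_transform(r2o, 0.1, 0.5) == pytest.approx(r2l)

    def test_simulation_round_trip(self):
        """Ascertained case-control observed R2 transforms back to the liability R2."""
        rng = np.random.default_rng(12)
        n, K, target = 400_000, 0.1, 0.05
        L = rng.normal(0, 1, n)
        g = np.sqrt(target) * L + rng.normal(0, np.sqrt(1 - target), n)
        y = (L > np.quantile(L, 1 - K)).astype(float)
        cases = np.flatnonzero(y == 1)
        controls = rng.choice(np.flatnonzero(y == 0), size=len(cases), replace=False)
        idx = np.concatenate([cases, controls])
        r2_obs = np.corrcoef(g[idx], y[idx])[0, 1] ** 2
        r2_liab = a.liability_r2_transform(r2_obs, K, 0.5)
        assert r2_liab == pytest.approx(target, abs=0.01)

    def test_point_biserial_mapping(self):
        rng = np.random.default_rng(13)
        n, K = 200_000, 0.2
        L = rng.normal(0, 1, n)
        x = 0.6 * L + rng.normal(0, 0.8, n)
        y = (L > np.quantile(L, 1 - K)).astype(float)
        r = a.liability_scale_correlation(x, y)
        truth = 0.6 / np.sqrt(0.6**2 + 0.8**2)  # corr(x, L)
        assert r == pytest.approx(truth, abs=0.03)
        assert a.liability_scale_correlation(-x, y) == pytest.approx(-r)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=20_000)
        y = (rng.random(20_000) < 0.1).astype(float)
        assert abs(a.liability_scale_correlation(x, y)) < 0.02

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            a.liability_r2_transform(-0.1, 0.1, 0.5)
        with pytest.raises(ParameterError):
            a.liability_r2_transform(0.1, 0.0, 0.5)


class TestQRSPipeline:
    def test_noise_matching_and_trajectories(self, marker_cohort):
        geno, table, states = marker_cohort
        prs = a.calibrate_predictor(states["dz"].G, 0.2, seed=21)
        X = np.column_stack(
            [table.trait_at_visit(f"marker_{i}", 1).to_numpy() for i in range(4)]
        )
        est, _ = a.fit_estimated_liability(X, _status(table, "dz"), n_folds=5, seed=22)
        sexage = np.column_stack([table.individuals["sex"], table.individuals["baseline_age"]])
        res = a.qrs_pipeline(
            est.values, prs.values, table, "dz",
            qrs_covariates=sexage,
            prs_covariates=table.individuals[["sex"]].to_numpy(),
            n_mc=12, seed=23,
        )
        assert res.noise_var > 0  # raw QRS is stronger than this PRS
        assert res.r2liab_qrs_raw > res.r2liab_prs
        # after matching, liability-scale accuracy agrees with the PRS's
        assert res.r2liab_qrs_matched == pytest.approx(res.r2liab_prs, abs=0.02)
        assert len(res.qrs_series) == len(res.prs_series) == 5
        assert np.all(res.qrs_series.ses > 0)

    def test_weaker_qrs_needs_no_noise(self, marker_cohort):
        geno, table, states = marker_cohort
        prs = a.calibrate_predictor(states["dz"].G, 0.2, seed=24)
        weak_qrs = prs.values + np.random.default_rng(0).normal(0, 2.0, len(prs.values))
        with pytest.warns(UserWarning, match="no noise"):
            res = a.qrs_pipeline(
                weak_qrs, prs.values, table, "dz",
                qrs_covariates=None, prs_covariates=None, n_mc=3, seed=25,
            )
        assert res.noise_var == 0.0


def _status(table, disease):
    return (
        table.individuals["id"]
        .isin(table.diagnoses.loc[table.diagnoses["disease"] == disease, "id"])
        .to_numpy()
        .astype(float)
    )
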