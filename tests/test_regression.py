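"""Cluster-robust logistic regression: sandwich algebra, inference, battery."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from awagkit.regression import (
    BASE_COVARIATES,
    ClusterRobustLogit,
    ModelSpec,
    battery_to_frame,
    default_model_spec,
    fit_logit_cluster,
    run_table4_battery,
)
from awagkit.synthetic import (
    GeneratorConfig,
    generate_covariates,
    generate_responses,
    generate_survey,
    recovery_config,
    single_item_catalog,
)


def _sim_logit(n, beta, seed, n_clusters=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(beta)))
    eta = 0.3 + X @ np.asarray(beta)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    groups = rng.integers(0, n_clusters, size=n)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(len(beta))]), y, groups


class TestClusterRobustLogit:
    def test_intercept_only_recovers_odds(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        est = ClusterRobustLogit().fit(np.empty((100, 0)), y)
        assert math.exp(est.params_["const"]) == pytest.approx(30 / 70, rel=1e-6)

    def test_one_obs_per_cluster_equals_scaled_hc0(self):
        """With singleton clusters the CR1 meat is the HC0 meat, so the
        covariance is the HC0 sandwich times G/(G-1)."""
        X, y, _ = _sim_logit(60, [0.5, -0.4], seed=3)
        groups = np.arange(60)  # one observation per cluster
        est = ClusterRobustLogit().fit(X, y, groups=groups)
        sm_res = sm.Logit(y, sm.add_constant(X)).fit(disp=0, cov_type="HC0")
        scaled = sm_res.cov_params().to_numpy() * 60 / 59
        np.testing.assert_allclose(est.cov_.to_numpy(), scaled, rtol=1e-6)

    def test_sandwich_matches_bruteforce_oracle(self):
        """Explicit per-cluster score outer products on a 50-row fixture."""
        X, y, groups = _sim_logit(50, [0.8, -0.6], seed=11, n_clusters=5)
        est = ClusterRobustLogit().fit(X, y, groups=groups)

        Xc = sm.add_constant(X).to_numpy()
        beta = est.params_.to_numpy()
        p = 1 / (1 + np.exp(-Xc @ beta))
        info = np.zeros((3, 3))
        for i in range(50):
            info += p[i] * (1 - p[i]) * np.outer(Xc[i], Xc[i])
        bread = np.linalg.inv(info)
        meat = np.zeros((3, 3))
        for g in np.unique(groups):
            s = np.zeros(3)
            for i in np.where(groups == g)[0]:
                s += (y[i] - p[i]) * Xc[i]
            meat += np.outer(s, s)
        G = len(np.unique(groups))
        expected = bread @ meat @ bread * G / (G - 1)
        np.testing.assert_allclose(est.cov_.to_numpy(), expected, atol=1e-8)

    def test_parameter_recovery_known_model(self):
        """beta_age = -0.05 at n=5000: estimated OR near exp(-0.05)=0.951."""
        X, y, groups = _sim_logit(5000, [-0.05, 0.3], seed=21)
        est = ClusterRobustLogit().fit(X, y, groups=groups)
        assert math.exp(est.params_["x0"]) == pytest.approx(
            math.exp(-0.05), abs=0.02
        )

    def test_ci_brackets_or_and_positive(self):
        X, y, groups = _sim_logit(400, [0.4, -0.2], seed=5)
        est = ClusterRobustLogit().fit(X, y, groups=groups)
        for name in est.params_.index:
            row = est.odds_ratios_.loc[name]
            assert 0 < row["ci_low"] <= row["odds_ratio"] <= row["ci_high"]

    def test_row_order_and_cluster_relabeling_invariance(self):
        X, y, groups = _sim_logit(300, [0.5, -0.5], seed=9)
        est1 = ClusterRobustLogit().fit(X, y, groups=groups)
        perm = np.random.default_rng(0).permutation(300)
        relabel = np.array(["c%d" % g for g in groups])  # new labels, same partition
        est2 = ClusterRobustLogit().fit(
            X.iloc[perm].reset_index(drop=True), y[perm], groups=relabel[perm]
        )
        np.testing.assert_allclose(
            est1.params_.to_numpy(), est2.params_.to_numpy(), rtol=1e-7
        )
        np.testing.assert_allclose(
            est1.bse_.to_numpy(), est2.bse_.to_numpy(), rtol=1e-6
        )

    def test_fewer_than_two_clusters_falls_back_classical(self):
        X, y, _ = _sim_logit(200, [0.5], seed=1)
        with pytest.warns(UserWarning, match="classical"):
            est = ClusterRobustLogit().fit(X, y, groups=np.zeros(200))
        assert est.n_clusters_ == 1

    def test_constant_outcome_rejected(self):
        X = np.random.default_rng(0).normal(size=(50, 1))
        with pytest.raises(ValueError, match="constant"):
            ClusterRobustLogit().fit(X, np.ones(50))

    def test_separation_flagged(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        with pytest.warns(UserWarning, match="separation"):
            est = ClusterRobustLogit().fit(x[:, None], y)
        assert est.separation_ and not est.converged_

    def test_sklearn_interface(self):
        X, y, groups = _sim_logit(200, [1.0], seed=2)
        est = ClusterRobustLogit(alpha=0.10)
        assert est.get_params()["alpha"] == 0.10
        est.set_params(alpha=0.05).fit(X, y, groups=groups)
        proba = est.predict_proba(X)
        assert proba.shape == (200, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert set(est.predict(X)) <= {0, 1}


class TestModelSpec:
    def test_awareness_excludes_technology_scores(self):
        with pytest.raises(ValueError):
            ModelSpec("awareness", "treatment", BASE_COVARIATES + ("pu", "peou"))
        spec = default_model_spec("want", "treatment")
        assert "pu" in spec.covariates and "peou" in spec.covariates
        spec_a = default_model_spec("awareness", "treatment")
        assert "pu" not in spec_a.covariates


@pytest.fixture(scope="module")
def records():
    recs, _ = generate_survey(GeneratorConfig(n=900, seed=77))
    return recs


class TestBattery:
    def test_nine_models_all_converged(self, records):
        results = run_table4_battery(records)
        assert len(results) == 9
        assert all(r.converged for r in results)
        order = [(r.category, r.outcome) for r in results]
        assert order[0] == ("information_based", "awareness")
        assert order[-1] == ("treatment", "adoption")

    def test_want_models_include_perceived_usefulness(self, records):
        results = run_table4_battery(records)
        want_info = next(
            r for r in results
            if r.outcome == "want" and r.category == "information_based"
        )
        assert any(t["term"] == "pu" for t in want_info.terms)
        aware_info = next(
            r for r in results
            if r.outcome == "awareness" and r.category == "information_based"
        )
        assert not any(t["term"] in ("pu", "peou") for t in aware_info.terms)

    def test_export_frame_columns(self, records):
        df = battery_to_frame(run_table4_battery(records))
        assert list(df.columns) == [
            "outcome", "category", "term", "level",
            "odds_ratio", "ci_low", "ci_high", "p_value",
        ]
        assert (df.groupby(["outcome", "category"]).size() > 0).all()

    def test_negative_age_mechanism_recovers_negative_sign(self):
        cfg = recovery_config(n=4000, seed=5)
        cfg.beta_awareness["age"] = -0.05
        cat = single_item_catalog()
        recs = generate_responses(generate_covariates(cfg), cfg, cat)
        res = fit_logit_cluster(
            recs, default_model_spec("awareness", "information_based"), cat
        )
        age = next(t for t in res.terms if t["term"] == "age")
        assert age["odds_ratio"] < 1
        assert age["odds_ratio"] == pytest.approx(math.exp(-0.05), abs=0.02)
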