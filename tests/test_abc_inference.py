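import numpy as np
import pandas as pd
import pytest

from invabc.abc_inference import (
    ReferenceTable,
    build_reference_table,
    confidence_error_rates,
    local_linear_adjust,
    logistic_scenario_posterior,
    pca_model_check,
    posterior_summary,
    rejection_sample,
    scenario_choice,
)
from invabc.abc_summaries import SummaryStatVector
from invabc.calibration import TOY_PANEL, toy_split_scenario, toy_three_scenarios
from invabc.coalescent_engine import SimOptions


def manual_table(stats, scenario_ids=None, params=None, labels=None):
    stats = np.asarray(stats, float)
    n = stats.shape[0]
    sid = np.zeros(n, dtype=int) if scenario_ids is None else np.asarray(scenario_ids)
    labels = labels or [str(i) for i in range(sid.max() + 1)]
    params = np.zeros((n, 1)) if params is None else np.asarray(params)
    return ReferenceTable(
        scenario_ids=sid, scenario_labels=labels, param_names=["theta"],
        params=params.reshape(n, -1),
        stat_names=[f"s{j}" for j in range(stats.shape[1])],
        stats=stats, mask=np.ones_like(stats, dtype=bool),
    )


def observed(values, mask=None):
    values = np.asarray(values, float)
    return SummaryStatVector(
        [f"s{j}" for j in range(values.size)], values,
        np.ones(values.size, bool) if mask is None else np.asarray(mask),
    )


class TestRejection:
    def test_tolerance_one_retains_everything(self):
        rng = np.random.default_rng(0)
        rt = manual_table(rng.normal(size=(50, 3)))
        ret = rejection_sample(rt, observed([0, 0, 0]), tolerance=1.0)
        assert ret.indices.size == 50

    def test_exact_match_is_first(self):
        rng = np.random.default_rng(1)
        stats = rng.normal(size=(40, 3))
        rt = manual_table(stats)
        ret = rejection_sample(rt, observed(stats[17]), tolerance=0.2)
        assert ret.indices[0] == 17
        assert ret.distances[0] == pytest.approx(0.0, abs=1e-12)

    def test_retained_set_matches_brute_force_sort(self):
        rng = np.random.default_rng(2)
        stats = rng.normal(size=(60, 4))
        rt = manual_table(stats)
        obs = observed(rng.normal(size=4))
        ret = rejection_sample(rt, obs, tolerance=0.25)
        med = np.median(stats, axis=0)
        mad = np.median(np.abs(stats - med), axis=0)
        z = (stats - med) / mad
        zo = (obs.values - med) / mad
        d = np.sqrt(((z - zo) ** 2).sum(axis=1))
        expected = np.argsort(d, kind="stable")[:15]
        assert np.array_equal(ret.indices, expected)

    def test_masked_and_dead_stats_excluded(self):
        rng = np.random.default_rng(3)
        stats = np.column_stack([rng.normal(size=30), np.ones(30), rng.normal(size=30)])
        rt = manual_table(stats)
        obs = observed([0.0, 99.0, 0.0], mask=[True, True, False])
        ret = rejection_sample(rt, obs, tolerance=0.5)
        assert ret.used_stats.tolist() == [True, False, False]

    def test_invalid_tolerance(self):
        rt = manual_table(np.zeros((10, 2)) + np.arange(10)[:, None])
        with pytest.raises(ValueError):
            rejection_sample(rt, observed([0, 0]), tolerance=0.0)

    def test_posterior_invariant_to_affine_stat_rescaling(self):
        rng = np.random.default_rng(4)
        stats = rng.normal(size=(300, 3))
        sid = (stats[:, 0] + 0.5 * rng.normal(size=300) > 0).astype(int)
        rt1 = manual_table(stats, sid, labels=["a", "b"])
        scaled = stats * np.array([10.0, 0.1, 3.0]) + np.array([5.0, -2.0, 0.0])
        rt2 = manual_table(scaled, sid, labels=["a", "b"])
        obs1 = observed([0.2, 0.1, -0.3])
        obs2 = observed(np.array([0.2, 0.1, -0.3]) * np.array([10.0, 0.1, 3.0]) + np.array([5.0, -2.0, 0.0]))
        p1 = scenario_choice(rt1, obs1, tolerance=0.2)
        p2 = scenario_choice(rt2, obs2, tolerance=0.2)
        assert np.allclose(p1.table["posterior"], p2.table["posterior"], atol=1e-8)


class TestLogisticPosterior:
    def test_uninformative_stats_give_uniform_posterior(self):
        rng = np.random.default_rng(5)
        n = 900
        stats = rng.normal(size=(n, 3))
        sid = np.repeat([0, 1, 2], n // 3)
        rt = manual_table(stats, sid, labels=["x", "y", "z"])
        post = scenario_choice(rt, observed([0, 0, 0]), tolerance=0.5)
        assert np.allclose(post.table["posterior"], 1 / 3, atol=0.12)
        assert post.table["posterior"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_separating_stat_drives_posterior_to_one(self):
        rng = np.random.default_rng(6)
        n = 400
        stats = np.concatenate([rng.normal(-3, 1, n // 2), rng.normal(3, 1, n // 2)])
        sid = np.repeat([0, 1], n // 2)
        rt = manual_table(stats.reshape(-1, 1), sid, labels=["lo", "hi"])
        post = scenario_choice(rt, observed([3.0]), tolerance=1.0)
        assert post.chosen == "hi"
        assert post.probability("hi") > 0.9

    def test_binary_fit_matches_independent_irls(self):
        """Posterior at the observed point matches a hand-coded Newton/IRLS
        unpenalized logistic fit."""
        rng = np.random.default_rng(7)
        n = 500
        x = rng.normal(size=(n, 2))
        logit = 0.4 + x @ np.array([1.0, -0.7])
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        rt = manual_table(x, y, labels=["0", "1"])
        ret = rejection_sample(rt, observed([0.0, 0.0]), tolerance=1.0)
        post = logistic_scenario_posterior(ret, ["0", "1"])

        # IRLS on the same design the package uses (MAD-normalized, centred, unit sd)
        X = ret.stats_centered
        X = X / X.std(axis=0)
        A = np.column_stack([np.ones(n), X])
        beta = np.zeros(3)
        yy = y[ret.indices]
        for _ in range(50):
            p = 1 / (1 + np.exp(-A @ beta))
            w = p * (1 - p)
            H = A.T @ (A * w[:, None])
            beta += np.linalg.solve(H, A.T @ (yy - p))
        p1 = 1 / (1 + np.exp(-beta[0]))
        assert post.probability("1") == pytest.approx(p1, abs=0.02)

    def test_ci_bounds_are_probabilities(self):
        rng = np.random.default_rng(8)
        stats = rng.normal(size=(600, 2))
        sid = (stats[:, 0] > 0.3).astype(int)
        rt = manual_table(stats, sid, labels=["a", "b"])
        post = scenario_choice(rt, observed([0.0, 0.0]), tolerance=0.5)
        tab = post.table
        assert ((tab["ci_low"] >= 0) & (tab["ci_high"] <= 1)).all()
        assert (tab["ci_low"] <= tab["posterior"] + 1e-12).all()


class TestLocalLinear:
    def build_linear(self, n=2000, noise=0.0, seed=9):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(1, 10, n)
        stat = 2 * theta + noise * rng.normal(size=n)
        return manual_table(stat.reshape(-1, 1), params=theta), theta

    def test_deterministic_linear_map_collapses_to_truth(self):
        rt, _ = self.build_linear()
        obs = observed([10.0])  # theta_true = 5
        ret = rejection_sample(rt, obs, tolerance=0.2)
        adj = local_linear_adjust(rt, ret, param_names=["theta"], transform="none")
        assert np.std(adj["theta"]) < 0.05
        assert np.median(adj["theta"]) == pytest.approx(5.0, abs=0.05)

    def test_log_transform_keeps_positivity(self):
        rt, _ = self.build_linear(noise=2.0)
        ret = rejection_sample(rt, observed([4.0]), tolerance=0.3)
        adj = local_linear_adjust(rt, ret, param_names=["theta"], transform="log")
        assert (adj["theta"] > 0).all()

    def test_uninformative_stats_return_retained_sample(self):
        rng = np.random.default_rng(10)
        theta = rng.uniform(1, 10, 1500)
        stat = rng.normal(size=1500)  # carries no signal
        rt = manual_table(stat.reshape(-1, 1), params=theta)
        ret = rejection_sample(rt, observed([0.0]), tolerance=0.3)
        adj = local_linear_adjust(rt, ret, param_names=["theta"], transform="none")
        retained_theta = theta[ret.indices]
        assert np.mean(adj["theta"]) == pytest.approx(np.mean(retained_theta), abs=0.4)

    def test_too_few_rows_rejected(self):
        rt, _ = self.build_linear(n=100)
        ret = rejection_sample(rt, observed([10.0]), tolerance=0.2)
        with pytest.raises(ValueError, match=">= 50"):
            local_linear_adjust(rt, ret, param_names=["theta"])

    def test_posterior_summary_quantiles(self):
        adj = pd.DataFrame({"T": np.arange(1, 101, dtype=float)})
        summ = posterior_summary(adj)
        assert summ.loc[0, "median"] == pytest.approx(50.5)
        assert summ.loc[0, "q2.5"] < summ.loc[0, "q97.5"]


class TestBuildTable:
    def test_row_counts_and_reproducibility(self):
        scenarios = toy_three_scenarios(n_diploid=4)
        opts = SimOptions(simulate_sequence=False)
        rt1 = build_reference_table(scenarios, 6, TOY_PANEL, seed=3, options=opts)
        rt2 = build_reference_table(scenarios, 6, TOY_PANEL, seed=3, options=opts)
        assert rt1.n_rows == 18
        assert np.array_equal(rt1.stats, rt2.stats)
        assert np.array_equal(rt1.params, rt2.params)

    def test_rows_satisfy_scenario_conditions(self):
        scenarios = toy_three_scenarios(n_diploid=4)
        rt = build_reference_table(
            scenarios, 8, TOY_PANEL, seed=4, options=SimOptions(simulate_sequence=False)
        )
        t1 = rt.params[:, rt.param_names.index("t1")]
        t2 = rt.params[:, rt.param_names.index("t2")]
        assert np.all(t2 > t1)

    def test_posterior_invariant_to_row_order(self):
        scenarios = toy_three_scenarios(n_diploid=4)
        rt = build_reference_table(
            scenarios, 30, TOY_PANEL, seed=5, options=SimOptions(simulate_sequence=False)
        )
        obs = observed(rt.stats[7])
        obs.names = rt.stat_names
        perm = np.random.default_rng(0).permutation(rt.n_rows)
        rt2 = ReferenceTable(
            rt.scenario_ids[perm], rt.scenario_labels, rt.param_names,
            rt.params[perm], rt.stat_names, rt.stats[perm], rt.mask[perm],
        )
        p1 = scenario_choice(rt, obs, tolerance=0.5).table["posterior"].to_numpy()
        p2 = scenario_choice(rt2, obs, tolerance=0.5).table["posterior"].to_numpy()
        assert np.allclose(p1, p2, atol=1e-6)


class TestErrorRates:
    def test_identical_scenarios_choose_by_chance(self):
        base = toy_split_scenario(n_diploid=4)
        import copy

        s1, s2 = copy.deepcopy(base), copy.deepcopy(base)
        s1.id, s2.id = "c1", "c2"
        opts = SimOptions(simulate_sequence=False)
        rt = build_reference_table([s1, s2], 300, TOY_PANEL, seed=6, options=opts)
        err = confidence_error_rates(rt, [s1, s2], TOY_PANEL, n_pods=20, seed=6,
                                     tolerance=0.2, options=opts)
        # indistinguishable scenarios: type I near (S-1)/S = 0.5
        assert 0.2 <= err["type_I"].mean() <= 0.8

    def test_reproducible_error_table(self):
        scenarios = toy_three_scenarios(n_diploid=4)
        opts = SimOptions(simulate_sequence=False)
        rt = build_reference_table(scenarios, 100, TOY_PANEL, seed=7, options=opts)
        e1 = confidence_error_rates(rt, scenarios, TOY_PANEL, n_pods=5, seed=7,
                                    tolerance=0.3, options=opts)
        e2 = confidence_error_rates(rt, scenarios, TOY_PANEL, n_pods=5, seed=7,
                                    tolerance=0.3, options=opts)
        assert e1.equals(e2)


class TestModelCheck:
    def test_observed_at_stat_mean_projects_at_origin(self):
        rng = np.random.default_rng(11)
        stats = rng.normal(size=(500, 5))
        rt = manual_table(stats)
        obs = observed(np.median(stats, axis=0))
        rep = pca_model_check(rt, obs, n_components=3)
        assert np.allclose(rep["observed_projection"], 0, atol=0.2)
        assert sum(rep["variance_explained_pct"]) <= 100 + 1e-9

    def test_posterior_cloud_percentiles_reported(self):
        rng = np.random.default_rng(12)
        stats = rng.normal(size=(400, 4))
        rt = manual_table(stats)
        obs = observed(stats[3])
        rep = pca_model_check(rt, obs, posterior_stats=stats[:100], n_components=2)
        assert len(rep["posterior_percentile"]) == 2
        assert all(0 <= p <= 100 for p in rep["prior_percentile"])
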