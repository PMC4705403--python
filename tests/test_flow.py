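"""Spillover compensation, log-ratio normalization, EM gating, condition ANOVA."""

import numpy as np
import pandas as pd
import pytest

from hcrquant.flow import (PopulationSummary, SpilloverMatrix,
                           compensate_events, condition_summary_anova,
                           fit_induced_mixture, log_ratio_normalize,
                           summarize_population)
from hcrquant.simulate import FlowSimConfig, simulate_flow_events


class TestCompensation:
    def test_identity_spillover_is_noop(self):
        events = pd.DataFrame({"event": [0, 1], "RFP": [10.0, 20.0],
                               "GFP": [5.0, 2.0], "APC": [1.0, 1.0]})
        out = compensate_events(events, SpilloverMatrix.identity())
        pd.testing.assert_frame_equal(out, events)

    def test_roundtrip_recovers_true_signals(self, flow_events_mixed):
        cfg, events, _ = flow_events_mixed
        true_cfg = FlowSimConfig(n_events=cfg.n_events,
                                 induced_fraction=cfg.induced_fraction,
                                 spillover=np.eye(3), seed=cfg.seed)
        true_events, _ = simulate_flow_events(true_cfg)
        comp = compensate_events(events, SpilloverMatrix(cfg.spillover))
        got = comp[["RFP", "GFP", "APC"]].to_numpy()
        want = true_events[["RFP", "GFP", "APC"]].to_numpy()
        assert np.max(np.abs(got - want) / np.abs(want)) < 1e-9

    def test_singular_matrix_rejected(self):
        m = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError):
            SpilloverMatrix(m)

    def test_nonunit_diagonal_rejected(self):
        with pytest.raises(ValueError):
            SpilloverMatrix(np.diag([1.0, 0.9, 1.0]))


class TestLogRatio:
    def test_known_values(self):
        events = pd.DataFrame({"RFP": [3.0, 3.0 * np.e], "GFP": [3.0, 3.0],
                               "APC": [1.0, 1.0]})
        lr, log = log_ratio_normalize(events)
        np.testing.assert_allclose(lr, [0.0, 1.0], atol=1e-12)
        assert log["n_kept"] == 2

    def test_nonpositive_events_excluded_and_counted(self):
        events = pd.DataFrame({"RFP": [1.0, -0.5, 2.0], "GFP": [1.0, 1.0, 0.0],
                               "APC": [1.0, 1.0, 1.0]})
        lr, log = log_ratio_normalize(events)
        assert len(lr) == 1
        assert log["n_nonpositive_rfp"] == 1
        assert log["n_nonpositive_gfp"] == 1

    def test_no_surviving_events_rejected(self):
        events = pd.DataFrame({"RFP": [-1.0], "GFP": [1.0], "APC": [1.0]})
        with pytest.raises(ValueError):
            log_ratio_normalize(events)


class TestMixture:
    def test_two_component_recovery(self):
        rng = np.random.default_rng(31)
        x = np.concatenate([rng.normal(-2, 0.5, 3000), rng.normal(1, 0.5, 7000)])
        fit = fit_induced_mixture(x, seed=0)
        w = fit.weights[fit.induced_index]
        assert w == pytest.approx(0.7, abs=0.05)
        assert fit.means[fit.induced_index] == pytest.approx(1.0, abs=0.1)
        assert fit.means[1 - fit.induced_index] == pytest.approx(-2.0, abs=0.1)

    def test_loglikelihood_nondecreasing(self):
        rng = np.random.default_rng(32)
        x = np.concatenate([rng.normal(-1, 0.4, 500), rng.normal(1, 0.6, 500)])
        fit = fit_induced_mixture(x, seed=1)
        diffs = np.diff(fit.log_likelihood_trace)
        assert np.all(diffs >= -1e-8)

    def test_matches_reference_em_implementation(self):
        """Independent cross-check against scikit-learn's Gaussian mixture."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(33)
        x = np.concatenate([rng.normal(-2, 0.5, 2000), rng.normal(1, 0.5, 3000)])
        fit = fit_induced_mixture(x, seed=2)
        gm = GaussianMixture(2, n_init=5, random_state=0, tol=1e-8).fit(x[:, None])
        order_mine = np.argsort(fit.means)
        order_ref = np.argsort(gm.means_.ravel())
        np.testing.assert_allclose(fit.means[order_mine],
                                   gm.means_.ravel()[order_ref], atol=0.02)
        np.testing.assert_allclose(fit.weights[order_mine],
                                   gm.weights_[order_ref], atol=0.02)

    def test_identical_values_flagged_degenerate(self):
        fit = fit_induced_mixture(np.full(100, 1.3), seed=0)
        assert fit.degenerate
        assert fit.induced_labels.all() or (~fit.induced_labels).all()

    def test_all_induced_population_assigned_to_induced(self):
        cfg = FlowSimConfig(n_events=5000, induced_fraction=1.0, seed=34)
        events, _ = simulate_flow_events(cfg)
        lr, _ = log_ratio_normalize(events)
        fit = fit_induced_mixture(lr, seed=0)
        assert fit.induced_labels.mean() >= 0.99

    def test_induced_is_larger_mean_component(self):
        rng = np.random.default_rng(35)
        x = np.concatenate([rng.normal(-2, 0.5, 5000), rng.normal(1, 0.5, 1000)])
        fit = fit_induced_mixture(x, seed=3)
        assert fit.means[fit.induced_index] > fit.means[1 - fit.induced_index]
        # events called induced sit above the non-induced mean
        assert x[fit.induced_labels].mean() > 0.5

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            fit_induced_mixture(np.zeros(10))


class TestConditionSummary:
    def _pops(self, ratios_by_cond, n_pops=3, sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        pops = []
        for cond, ratio in ratios_by_cond.items():
            for i in range(n_pops):
                m = np.log(ratio) + (rng.normal(0, sd) if sd else 0.0)
                pops.append(PopulationSummary(cond, f"p{i}", m, float(np.exp(m)), 1000))
        return pops

    def test_identical_populations_give_zero_f(self):
        pops = self._pops({"control": 1.0, "damaged": 1.0})
        res = condition_summary_anova(pops)
        assert res.anova_f == 0.0

    def test_control_is_100_and_true_ratio_recovered(self):
        pops = self._pops({"control": 1.0, "damaged": 0.5}, sd=0.05, seed=4)
        res = condition_summary_anova(pops)
        table = res.table.set_index("condition")
        assert table.loc["control", "mean_pct_of_control"] == pytest.approx(100.0, abs=1e-9)
        assert table.loc["damaged", "mean_pct_of_control"] == pytest.approx(50.0, abs=5.0)

    def test_contrast_zero_sum_validated(self):
        pops = self._pops({"control": 1.0, "damaged": 0.5}, sd=0.05, seed=5)
        with pytest.raises(ValueError):
            condition_summary_anova(pops, contrasts={"bad": {"control": 1.0,
                                                             "damaged": 1.0}})

    def test_true_difference_detected_by_contrast(self):
        pops = self._pops({"control": 1.0, "damaged": 0.3}, n_pops=4, sd=0.05, seed=6)
        res = condition_summary_anova(
            pops, contrasts={"ctrl_vs_dmg": {"control": 1.0, "damaged": -1.0}})
        assert res.contrast_results[0]["p"] < 0.01

    def test_underpopulated_condition_excluded_with_warning(self):
        pops = self._pops({"control": 1.0, "damaged": 0.5}, sd=0.01, seed=7)
        pops.append(PopulationSummary("stray", "p0", 0.0, 1.0, 100))
        with pytest.warns(UserWarning, match="stray"):
            res = condition_summary_anova(pops)
        assert "stray" not in set(res.table["condition"])

    def test_summarize_population_uses_induced_events_only(self):
        lr = np.array([-2.0, -2.0, 1.0, 1.0, 1.0])
        labels = np.array([False, False, True, True, True])
        pop = summarize_population("c", "p0", lr, labels)
        assert pop.mean_logratio == pytest.approx(1.0)
        assert pop.n_events == 3
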