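import io

import numpy as np
import pytest

from parevol import synthetic_data as syn
from parevol.core_io import TimedTree, ValidationError, read_timed_tree
from parevol.temporal_signal import (
    ClockRegressionModel,
    ConjugateNormalModel,
    PowerPosteriorTrace,
    bets_compare,
    beta_ladder,
    fit_root_to_tip,
    path_sampling_logml,
    run_bets_toy,
    stepping_stone_logml,
)


def _divergence_tree(seed, rate=1e-3, noise=0.0):
    tt = syn.simulate_timed_tree(n_taxa=15, seed=seed, sampling_window=100, pop_size=40)
    return tt, syn.as_divergence_tree(tt, rate=rate, noise_sd=noise, seed=seed)


class TestRootToTip:
    def test_noise_free_clock_recovered_exactly(self):
        tt, dt = _divergence_tree(seed=3)
        fit = fit_root_to_tip(dt, rooting="best-r2")
        root_date = min(tt.node_dates().values())
        assert fit.substitution_rate == pytest.approx(1e-3, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.tmrca == pytest.approx(root_date, abs=1e-6)

    def test_residual_mean_squared_rooting_also_exact(self):
        tt, dt = _divergence_tree(seed=4)
        fit = fit_root_to_tip(dt, rooting="residual-mean-squared")
        assert fit.substitution_rate == pytest.approx(1e-3, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noisy_slope_in_ols_confidence_interval(self):
        """With Gaussian distance noise the OLS CI (computed from the fixed
        true root, the closed-form oracle) covers the true rate >= 90/100."""
        from scipy.stats import t as t_dist

        hits = 0
        for r in range(100):
            tt, dt = _divergence_tree(seed=200 + r, noise=0.004)
            fit = fit_root_to_tip(dt, rooting="fixed")
            tips = dt.tip_labels()
            dates = np.array([dt.tip_dates[x] for x in tips])
            n = dates.size
            resid = np.array([fit.residuals[x] for x in tips])
            s2 = (resid @ resid) / (n - 2)
            se = np.sqrt(s2 / ((dates - dates.mean()) ** 2).sum())
            half = t_dist.ppf(0.975, n - 2) * se
            hits += abs(fit.substitution_rate - 1e-3) <= half
        assert hits >= 90

    def test_isochronous_tips_raise(self):
        tt = syn.simulate_timed_tree(n_taxa=10, seed=1, isochronous=True)
        with pytest.raises(ValidationError, match="isochronous"):
            fit_root_to_tip(tt)

    def test_invariance_to_tip_order_and_uniform_scaling(self):
        tt, dt = _divergence_tree(seed=7, noise=0.002)
        fit1 = fit_root_to_tip(dt)
        # re-read from newick (different internal ordering), then scale x10
        dt2 = read_timed_tree(io.StringIO(dt.as_newick()))
        fit2 = fit_root_to_tip(dt2)
        # newick serialization rounds branch lengths -> small tolerance
        assert fit2.substitution_rate == pytest.approx(fit1.substitution_rate, rel=1e-5)
        for e in dt2.tree.preorder_edge_iter():
            if e.length is not None:
                e.length *= 10.0
        fit3 = fit_root_to_tip(dt2)
        assert fit3.substitution_rate == pytest.approx(10 * fit2.substitution_rate, rel=1e-9)
        assert fit3.r_squared == pytest.approx(fit2.r_squared, rel=1e-9)


def _constant_trace(n_rungs=5, n=20, value=-5.0):
    betas = beta_ladder(n_rungs)
    return PowerPosteriorTrace(betas, [np.full(n, value) for _ in betas])


class TestMarginalLikelihoodEstimators:
    def test_constant_likelihood_is_exact_for_both(self):
        tr = _constant_trace()
        assert path_sampling_logml(tr).log_ml == pytest.approx(-5.0, abs=1e-12)
        assert stepping_stone_logml(tr).log_ml == pytest.approx(-5.0, abs=1e-12)

    def test_single_rung_rejected(self):
        with pytest.raises(ValidationError):
            PowerPosteriorTrace([1.0], [np.zeros(5)])

    def test_ladder_must_cover_unit_interval(self):
        with pytest.raises(ValidationError):
            PowerPosteriorTrace([0.0, 0.5], [np.zeros(3), np.zeros(3)])

    def test_conjugate_normal_within_three_se(self):
        model = ConjugateNormalModel(sigma=1.0, mu0=0.0, tau=2.0)
        rng = np.random.default_rng(42)
        data = rng.normal(0.7, 1.0, size=25)
        betas = beta_ladder(50)
        tr = PowerPosteriorTrace(
            betas, [model.sample_power_posterior(data, b, 1000, rng) for b in betas])
        truth = model.analytic_log_ml(data)
        ps = path_sampling_logml(tr)
        ss = stepping_stone_logml(tr)
        assert abs(ps.log_ml - truth) <= 3 * max(ps.mc_se, 1e-3)
        assert abs(ss.log_ml - truth) <= 3 * max(ss.mc_se, 1e-3)
        assert abs(ps.log_ml - ss.log_ml) <= 3 * (ps.mc_se + ss.mc_se) + 1e-2

    def test_mc_se_shrinks_with_sample_size(self):
        model = ConjugateNormalModel(tau=2.0)
        rng = np.random.default_rng(5)
        data = rng.normal(1.0, 1.0, size=25)
        betas = beta_ladder(30)

        def se_at(n, seed):
            r = np.random.default_rng(seed)
            tr = PowerPosteriorTrace(
                betas, [model.sample_power_posterior(data, b, n, r) for b in betas])
            return path_sampling_logml(tr, seed=seed).mc_se

        small = np.mean([se_at(200, s) for s in range(5)])
        big = np.mean([se_at(800, s + 10) for s in range(5)])
        assert big < small  # ~1/2 expected for 4x samples
        assert big / small < 0.8

    def test_trace_tsv_round_trip(self, tmp_path):
        tr = _constant_trace(4, 6, -2.5)
        p = tmp_path / "trace.tsv"
        tr.to_tsv(p)
        back = PowerPosteriorTrace.from_tsv(p)
        assert back.betas == pytest.approx(tr.betas)
        for a, b in zip(back.samples, tr.samples):
            assert a == pytest.approx(b)


# log marginal likelihoods and Bayes factors as printed in the published
# model-comparison table (PS and SS estimators, strict and relaxed clocks)
TABLE1 = [
    (176_580.2855, 176_878.692, 298.4064438),    # RdRp, strict, PS
    (176_567.3726, 176_899.6801, 332.3074985),   # RdRp, strict, SS
    (175_969.1107, 176_250.5675, 281.4567672),   # RdRp, relaxed, PS
    (175_969.1107, 176_274.2038, 305.0930831),   # RdRp, relaxed, SS
    (405_357.6929, 405_449.0548, 91.36191103),   # capsid, strict, PS
    (405_397.271, 405_479.4964, 82.22538598),    # capsid, strict, SS
    (405_085.058, 405_842.493, 757.4349536),     # capsid, relaxed, PS
    (405_116.8626, 405_877.5076, 760.6449583),   # capsid, relaxed, SS
]


class TestBetsCompare:
    @pytest.mark.parametrize("het,iso,bf", TABLE1)
    def test_published_bayes_factors_reproduced(self, het, iso, bf):
        comp = bets_compare(het, iso, convention="table1")
        assert comp.bayes_factor == pytest.approx(bf, abs=1e-3)
        assert comp.favored_model == "heterochronous"

    def test_equal_logml_inconclusive(self):
        comp = bets_compare(-10.0, -10.0)
        assert comp.bayes_factor == 0.0
        assert comp.favored_model == "inconclusive"

    def test_logbf_convention_flips_sign(self):
        c1 = bets_compare(-5.0, -20.0, convention="log-bf")
        assert c1.bayes_factor == pytest.approx(15.0)
        assert c1.favored_model == "heterochronous"
        c2 = bets_compare(-20.0, -5.0, convention="log-bf")
        assert c2.favored_model == "isochronous"


class TestRunBetsToy:
    def _datasets(self, seed):
        tt = syn.simulate_timed_tree(n_taxa=20, seed=40 + seed,
                                     sampling_window=100, pop_size=40)
        dt = syn.as_divergence_tree(tt, rate=1e-3, noise_sd=0.005, seed=seed)
        d = dt.root_to_tip_distances()
        tips = dt.tip_labels()
        t = np.array([dt.tip_dates[x] for x in tips])
        dist = np.array([d[x] for x in tips])
        return (t, dist), (np.full_like(t, t.max()), dist)

    def test_clock_signal_favors_heterochronous(self):
        model = ClockRegressionModel()
        wins = 0
        for seed in range(4):
            het, iso = self._datasets(seed)
            comp, _ = run_bets_toy(model, het, iso, ladder_size=16,
                                   samples_per_rung=300, seed=seed)
            wins += comp.favored_model == "heterochronous"
        assert wins >= 3

    def test_mcmc_tracks_analytic_marginal_likelihood(self):
        model = ClockRegressionModel()
        het, iso = self._datasets(9)
        comp, env = run_bets_toy(model, het, iso, ladder_size=16,
                                 samples_per_rung=300, seed=9)
        truth = model.analytic_log_ml(het) - model.analytic_log_ml(iso)
        assert comp.bayes_factor == pytest.approx(truth, abs=3.0)

    def test_permuted_dates_destroy_signal(self):
        model = ClockRegressionModel()
        rng = np.random.default_rng(9)
        inconclusive = 0
        for seed in range(4):
            het, iso = self._datasets(seed + 20)
            perm = (rng.permutation(het[0]), het[1])
            comp, _ = run_bets_toy(model, perm, iso, ladder_size=16,
                                   samples_per_rung=300, seed=seed)
            inconclusive += abs(comp.bayes_factor) < 3
        assert inconclusive >= 3

    def test_two_rung_ladder_degrades_gracefully(self):
        model = ConjugateNormalModel(tau=2.0)
        rng = np.random.default_rng(0)
        data = rng.normal(0.5, 1.0, size=15)
        comp, env = run_bets_toy(model, data, data, ladder_size=2,
                                 samples_per_rung=500, seed=0)
        assert np.isfinite(comp.bayes_factor)
        est = env["estimates"]["het"]["PS"]
        assert np.isfinite(est.log_ml) and est.mc_se >= 0
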