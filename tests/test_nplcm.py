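"""Latent-class multi-list capture-recapture: sampler, summaries, checks."""

import numpy as np
import pytest

import kpsize as kp
from kpsize.nplcm import (
    NPLCMConfig,
    NPLCMPosterior,
    fit_nplcm,
    m0_profile_mle,
    posterior_predictive_check,
    summarize_posterior,
)

from conftest import table_from_captures

FAST = NPLCMConfig(iterations=4000, burn_in=1000, thinning=3, seed=0)


def make_posterior(N_draws):
    draws = len(N_draws)
    return NPLCMPosterior(
        N=np.asarray(N_draws),
        lam=np.full((draws, 2, 3), 0.5),
        pi=np.full((draws, 2), 0.5),
        alpha=np.ones(draws),
        n_observed=int(np.min(N_draws)),
        sources=("a", "b", "c"),
        config=FAST,
    )


class TestConfigValidation:
    def test_invalid_chain_settings_rejected(self):
        with pytest.raises(ValueError):
            NPLCMConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            NPLCMConfig(thinning=0)
        with pytest.raises(ValueError):
            NPLCMConfig(alpha_shape=0.0)

    def test_truncation_default_caps_at_profile_count(self):
        assert NPLCMConfig().resolve_classes(2) == 3
        assert NPLCMConfig().resolve_classes(3) == 7
        assert NPLCMConfig().resolve_classes(4) == 10


class TestSampler:
    def test_every_draw_at_least_observed_count(self, homogeneous_table):
        table, _ = homogeneous_table
        post = fit_nplcm(table, FAST)
        assert (post.N >= table.n_observed).all()

    def test_perfect_detection_pins_population_at_observed(self):
        # everyone captured by every source: zero-history probability -> 0
        rng = np.random.default_rng(0)
        caps = np.ones((60, 3), dtype=int)
        table = table_from_captures(caps, ("a", "b", "c"))
        with pytest.warns(UserWarning, match="degenerate"):
            post = fit_nplcm(table, FAST)
        assert np.median(post.N) == 60
        assert np.percentile(post.N, 97.5) <= 63

    def test_single_class_truncation_matches_m0_mle(self, homogeneous_table):
        table, _ = homogeneous_table
        cfg = NPLCMConfig(max_classes=1, iterations=4000, burn_in=1000, thinning=3, seed=2)
        post = fit_nplcm(table, cfg)
        mle = m0_profile_mle(table)
        assert np.median(post.N) == pytest.approx(mle, rel=0.1)

    def test_source_order_invariance_of_size_posterior(self):
        rng = np.random.default_rng(5)
        caps = (rng.random((600, 3)) < [0.15, 0.35, 0.25]).astype(int)
        t1 = table_from_captures(caps, ("a", "b", "c"))
        t2 = table_from_captures(caps[:, ::-1], ("c", "b", "a"))
        cfg = NPLCMConfig(iterations=8000, burn_in=2000, thinning=5, seed=3)
        m1 = np.median(fit_nplcm(t1, cfg).N)
        m2 = np.median(fit_nplcm(t2, cfg).N)
        assert m1 == pytest.approx(m2, rel=0.05)

    def test_fixed_seed_bit_reproducible(self, homogeneous_table):
        table, _ = homogeneous_table
        a = fit_nplcm(table, FAST)
        b = fit_nplcm(table, FAST)
        assert np.array_equal(a.N, b.N)
        assert np.array_equal(a.lam, b.lam)

    def test_two_source_warns_weak_identification(self):
        rng = np.random.default_rng(1)
        caps = (rng.random((300, 2)) < 0.4).astype(int)
        table = table_from_captures(caps, ("a", "b"))
        with pytest.warns(UserWarning, match="weakly identified"):
            fit_nplcm(table, FAST)


class TestSummarize:
    def test_degenerate_posterior(self):
        est = summarize_posterior(make_posterior(np.full(500, 500)))
        assert (est.point, est.ci_low, est.ci_high) == (500, 500, 500)

    def test_percentile_rule_hand_computation(self):
        est = summarize_posterior(make_posterior(np.arange(1, 1001)))
        assert est.point == pytest.approx(500.5)
        assert est.ci_low == pytest.approx(25.975)
        assert est.ci_high == pytest.approx(975.025)

    def test_right_skew_preserved(self):
        draws = np.concatenate([np.full(900, 1000), np.linspace(1000, 9000, 100)])
        est = summarize_posterior(make_posterior(draws))
        assert est.ci_high - est.point > est.point - est.ci_low

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="draws"):
            summarize_posterior(make_posterior(np.arange(1, 50)))

    def test_mcmc_settings_in_provenance(self, homogeneous_table):
        table, _ = homogeneous_table
        est = summarize_posterior(fit_nplcm(table, FAST))
        assert est.metadata["iterations"] == 4000
        assert est.metadata["seed"] == 0
        assert est.category == "three-source"


class TestPosteriorPredictive:
    def test_self_consistency_on_model_generated_data(self, homogeneous_table):
        table, _ = homogeneous_table
        post = fit_nplcm(table, FAST)
        report = posterior_predictive_check(post, table, n_sims=300, seed=1)
        # data simulated from the model family: nearly all profiles inside
        assert int(report["outside"].sum()) <= 1

    def test_perfect_detection_mass_on_all_ones_profile(self):
        caps = np.ones((60, 3), dtype=int)
        table = table_from_captures(caps, ("a", "b", "c"))
        with pytest.warns(UserWarning):
            post = fit_nplcm(table, FAST)
        report = posterior_predictive_check(post, table, n_sims=200, seed=2)
        means = dict(zip(report["profile"], report["pred_mean"]))
        assert means["111"] > 50
        assert means["111"] > 10 * max(v for k, v in means.items() if k != "111")

    def test_forced_homogeneous_fit_flags_dependent_data(self):
        # two sharply separated classes induce dependence a single-class
        # model cannot reproduce
        rng = np.random.default_rng(9)
        z = rng.choice(2, size=2000, p=[0.5, 0.5])
        lam = np.array([[0.05, 0.05, 0.05], [0.7, 0.7, 0.7]])
        caps = (rng.random((2000, 3)) < lam[z]).astype(int)
        table = table_from_captures(caps, ("a", "b", "c"))
        cfg = NPLCMConfig(max_classes=1, iterations=4000, burn_in=1000, thinning=3, seed=4)
        post = fit_nplcm(table, cfg)
        report = posterior_predictive_check(post, table, n_sims=300, seed=3)
        assert report["outside"].any()


class TestM0Oracle:
    def test_mle_exact_on_near_complete_capture(self):
        # p ~ 0.9 per list: almost everyone seen, MLE pins N at n
        rng = np.random.default_rng(3)
        caps = (rng.random((200, 3)) < 0.9).astype(int)
        table = table_from_captures(caps, ("a", "b", "c"))
        assert m0_profile_mle(table) == pytest.approx(200, abs=2)
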