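"""Likelihoods, posteriors, sensitivity adjustment and discretisation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaregulon.inference import (
    ClusterPromoterSet,
    PosteriorRecord,
    PriorSpec,
    adjust_priors,
    adjusted_cluster_posterior,
    cluster_posterior,
    promoter_loglik_background,
    promoter_loglik_regulated,
    promoter_posterior,
    resolve_theta,
    select_regulated_clusters,
    survival_probabilities,
)
from metaregulon.motifs import ScoreModel, ScoreVector


def _sv(scores, pid="p0"):
    return ScoreVector(pid, np.asarray(scores, dtype=float))


def _brute_force_loglik(scores, model, regulated):
    """Extended-precision direct product-of-densities oracle."""
    ld = np.longdouble
    total = ld(1.0)
    inv_sqrt2pi = 1.0 / np.sqrt(ld(2) * np.pi)
    for s in scores:
        s = ld(s)
        phi_g = inv_sqrt2pi / ld(model.sigma_g) * np.exp(
            -((s - ld(model.mu_g)) / ld(model.sigma_g)) ** 2 / 2)
        if regulated:
            phi_m = inv_sqrt2pi / ld(model.sigma_m) * np.exp(
                -((s - ld(model.mu_m)) / ld(model.sigma_m)) ** 2 / 2)
            total *= ld(model.alpha) * phi_m + (1 - ld(model.alpha)) * phi_g
        else:
            total *= phi_g
    return float(np.log(total))


class TestPromoterLikelihoods:
    @pytest.mark.parametrize("regulated", [True, False])
    def test_matches_brute_force_product(self, simple_model, regulated):
        rng = np.random.default_rng(0)
        for _ in range(10):
            scores = rng.normal(0, 3, size=rng.integers(1, 11))
            fn = (promoter_loglik_regulated if regulated
                  else promoter_loglik_background)
            assert fn(_sv(scores), simple_model) == pytest.approx(
                _brute_force_loglik(scores, simple_model, regulated),
                rel=1e-8)

    def test_alpha_zero_limit_collapses_to_background(self):
        # alpha -> 0: the mixture likelihood approaches the background one
        model_lo = ScoreModel(0.0, 1.0, 10.0, 2.0, alpha=1e-12)
        scores = _sv([0.1, -0.4, 0.8])
        assert promoter_loglik_regulated(scores, model_lo) == pytest.approx(
            promoter_loglik_background(scores, model_lo), abs=1e-9)

    def test_single_background_score_density(self, simple_model):
        # s = mu_g with mu_m far away: ~ log[(1-alpha) * phi(0)/sigma_g]
        expected = math.log((1 - simple_model.alpha)
                            / math.sqrt(2 * math.pi))
        assert promoter_loglik_regulated(_sv([0.0]), simple_model) == \
            pytest.approx(expected, abs=1e-6)

    def test_background_mode_closed_form(self, simple_model):
        n = 7
        ll = promoter_loglik_background(_sv([simple_model.mu_g] * n),
                                        simple_model)
        assert ll == pytest.approx(n * math.log(1 / math.sqrt(2 * math.pi)))

    def test_order_invariance(self, simple_model):
        a = promoter_loglik_background(_sv([1.0, 2.0, 3.0]), simple_model)
        b = promoter_loglik_background(_sv([3.0, 1.0, 2.0]), simple_model)
        assert a == pytest.approx(b)

    def test_empty_scores_carry_no_evidence(self, simple_model):
        empty = ScoreVector("p", np.empty(0))
        assert promoter_loglik_regulated(empty, simple_model) == 0.0
        assert promoter_loglik_background(empty, simple_model) == 0.0

    def test_site_tail_favours_mixture(self, simple_model):
        scores = _sv([9.5])  # many sigma_g above mu_g, near mu_m
        assert promoter_loglik_regulated(scores, simple_model) > \
            promoter_loglik_background(scores, simple_model)


class TestPromoterPosterior:
    def test_empty_promoter_returns_prior_exactly(self, simple_model):
        post = promoter_posterior(ScoreVector("p", np.empty(0)), simple_model)
        assert post == pytest.approx(3 / 1811, rel=1e-12)

    def test_monotone_in_score_toward_motif_mean(self, simple_model):
        # sigma_m > sigma_g here would break upper-tail monotonicity; the
        # fixture has sigma_m = 2 > sigma_g = 1, so test in the range
        # where the density ratio is increasing
        posts = [promoter_posterior(_sv([s, 0.0]), simple_model)
                 for s in (2.0, 4.0, 6.0, 8.0, 10.0)]
        assert all(a <= b + 1e-15 for a, b in zip(posts, posts[1:]))


class TestClusterPosterior:
    def test_posterior_reproducible_from_log_ratio_and_priors(self, simple_model):
        cluster = ClusterPromoterSet("c", [_sv([0.5, 1.0], "a"),
                                           _sv([9.0], "b")])
        rec = cluster_posterior(cluster, simple_model)
        lam = rec.log_likelihood_ratio_sum
        manual = 1.0 / (1.0 + math.exp(lam) * rec.priors_used.p_b
                        / rec.priors_used.p_r)
        assert rec.posterior == pytest.approx(manual, rel=1e-12)

    def test_empty_cluster_returns_prior(self, simple_model):
        rec = cluster_posterior(ClusterPromoterSet("c", []), simple_model)
        assert rec.posterior == pytest.approx(3 / 1811, rel=1e-12)
        assert rec.log_likelihood_ratio_sum == 0.0

    def test_promoter_order_invariance(self, simple_model):
        svs = [_sv([0.1, 0.2], "a"), _sv([5.0], "b"), _sv([-2.0], "c")]
        r1 = cluster_posterior(ClusterPromoterSet("c", svs), simple_model)
        r2 = cluster_posterior(ClusterPromoterSet("c", svs[::-1]), simple_model)
        assert r1.posterior == pytest.approx(r2.posterior, rel=1e-12)

    def test_duplicate_promoter_ids_rejected(self, simple_model):
        with pytest.raises(ValueError, match="duplicate"):
            ClusterPromoterSet("c", [_sv([1.0], "a"), _sv([2.0], "a")])

    def test_background_scores_give_nonpositive_evidence(self, simple_model):
        # scores at mu_g: each lambda_i >= 0, so posterior <= prior
        svs = [_sv([0.0] * 5, f"p{i}") for i in range(4)]
        rec = cluster_posterior(ClusterPromoterSet("c", svs), simple_model)
        assert rec.log_likelihood_ratio_sum >= 0.0
        assert rec.posterior <= 3 / 1811 + 1e-15


class TestSurvivalProbabilities:
    def test_cdf_limits(self, simple_model):
        assert survival_probabilities(10, -np.inf, simple_model) == (0.0, 0.0)
        assert survival_probabilities(10, np.inf, simple_model) == (1.0, 1.0)

    def test_background_median_single_window(self, simple_model):
        ub, _ = survival_probabilities(1, simple_model.mu_g, simple_model)
        assert ub == pytest.approx(0.5)

    def test_alpha_zero_makes_models_coincide(self):
        model = ScoreModel(0.0, 1.0, 10.0, 2.0, alpha=1e-15)
        ub, ur = survival_probabilities(50, 1.3, model)
        assert ur == pytest.approx(ub, rel=1e-9)

    def test_log_space_resists_underflow(self, simple_model):
        ub, ur = survival_probabilities(10000, -5.0, simple_model)
        assert 0.0 < ub < 1e-300 or ub == 0.0
        # the log computation must not produce NaN
        assert not math.isnan(ub) and not math.isnan(ur)

    def test_regulated_model_exceeds_threshold_more_often(self, simple_model):
        ub, ur = survival_probabilities(100, 6.0, simple_model)
        assert ur <= ub


class TestAdjustPriors:
    def test_equal_survival_leaves_priors_unchanged(self):
        priors = PriorSpec()
        adj = adjust_priors(priors, 0.3, 0.3)
        assert adj.p_r == pytest.approx(priors.p_r, rel=1e-12)

    def test_background_exhaustion_limit(self):
        adj = adjust_priors(PriorSpec(), u_b=1.0 - 1e-12, u_r=0.2)
        assert adj.p_r > 0.99

    def test_hand_arithmetic(self):
        # n_reg=3, n_nonreg=1808, (1-U_R)=0.5, (1-U_B)=0.05
        adj = adjust_priors(PriorSpec(3, 1811), u_b=0.95, u_r=0.5)
        assert adj.p_r == pytest.approx(1.5 / (1.5 + 90.4), rel=1e-9)
        assert adj.p_r == pytest.approx(0.0163, abs=2e-4)

    def test_zero_survival_mass_errors(self):
        with pytest.raises(ValueError):
            adjust_priors(PriorSpec(), 1.0, 1.0)


class TestAdjustedClusterPosterior:
    def test_theta_minus_infinity_equals_unadjusted(self, simple_model):
        svs = [_sv([0.3, 2.0], "a"), _sv([8.0, -1.0], "b")]
        cluster = ClusterPromoterSet("c", svs)
        plain = cluster_posterior(cluster, simple_model)
        adj = adjusted_cluster_posterior(cluster, simple_model,
                                         theta=-np.inf)
        assert adj.posterior == pytest.approx(plain.posterior, rel=1e-12)
        assert adj.n_promoters_analyzed == plain.n_promoters_analyzed
        assert adj.priors_used.p_r == pytest.approx(plain.priors_used.p_r)

    def test_threshold_restricts_analyzed_promoters(self, simple_model):
        svs = [_sv([0.3, 2.0], "a"), _sv([8.0, -1.0], "b")]
        cluster = ClusterPromoterSet("c", svs)
        rec = adjusted_cluster_posterior(cluster, simple_model, theta=5.0)
        assert rec.n_promoters_analyzed == 1
        assert rec.n_promoters_total == 2

    def test_no_retained_promoter_returns_adjusted_prior(self, simple_model):
        svs = [_sv([0.0], "a")]
        rec = adjusted_cluster_posterior(ClusterPromoterSet("c", svs),
                                         simple_model, theta=6.0,
                                         prior_n_windows=10)
        assert rec.n_promoters_analyzed == 0
        assert rec.posterior == pytest.approx(rec.priors_used.p_r, rel=1e-12)

    def test_far_threshold_falls_back_with_warning(self, simple_model):
        svs = [_sv([60.0], "a")]
        cluster = ClusterPromoterSet("c", svs)
        with pytest.warns(UserWarning, match="underflow|unadjusted"):
            rec = adjusted_cluster_posterior(cluster, simple_model,
                                             theta=50.0, prior_n_windows=5)
        plain = cluster_posterior(cluster, simple_model)
        assert rec.posterior == pytest.approx(plain.posterior)


class TestResolveTheta:
    def test_sd_specification(self, simple_model):
        assert resolve_theta("sd:6", simple_model) == pytest.approx(
            simple_model.mu_m - 6 * simple_model.sigma_m)

    @pytest.mark.parametrize("spec,expected", [
        ("-inf", -np.inf), (4.5, 4.5), ("3.25", 3.25), (None, -np.inf)])
    def test_absolute_specifications(self, spec, expected, simple_model):
        assert resolve_theta(spec, simple_model) == expected


def _records(posteriors, n_analyzed=None):
    n_analyzed = n_analyzed or [10] * len(posteriors)
    return [
        PosteriorRecord(cluster_id=f"c{i:02d}", posterior=p,
                        n_promoters_total=n, n_promoters_analyzed=n,
                        log_likelihood_ratio_sum=0.0)
        for i, (p, n) in enumerate(zip(posteriors, n_analyzed))
    ]


class TestSelectRegulatedClusters:
    def test_prefix_stops_before_diluting_mean(self):
        recs = _records([0.99, 0.95, 0.70])
        out = select_regulated_clusters(recs, phi=0.1)
        assert [r.posterior for r in out] == [0.99, 0.95]

    def test_all_pass_when_every_posterior_qualifies(self):
        recs = _records([0.95, 0.92, 0.91])
        assert len(select_regulated_clusters(recs, phi=0.1)) == 3

    def test_empty_when_top_posterior_below_threshold(self):
        assert select_regulated_clusters(_records([0.5, 0.4]), phi=0.1) == []

    def test_empty_input(self):
        assert select_regulated_clusters([], phi=0.1) == []

    def test_min_promoter_filter_applies_after_prefix(self):
        recs = _records([0.99, 0.98], n_analyzed=[10, 3])
        out = select_regulated_clusters(recs, phi=0.1, min_promoters=5)
        assert [r.cluster_id for r in out] == ["c00"]

    def test_mean_posterior_guarantee(self):
        rng = np.random.default_rng(3)
        recs = _records(rng.random(50))
        out = select_regulated_clusters(recs, phi=0.25)
        if out:
            prefix = sorted(recs, key=lambda r: (-r.posterior, r.cluster_id))
            assert np.mean([r.posterior
                            for r in prefix[:len(out)]]) >= 0.75

    @given(st.lists(st.floats(0, 1), max_size=20), st.floats(0.01, 0.5))
    @settings(max_examples=200, deadline=None)
    def test_matches_exhaustive_prefix_search(self, posteriors, phi):
        recs = _records(posteriors)
        out = select_regulated_clusters(recs, phi=phi)
        # oracle: try every prefix length of the sorted list
        srt = sorted(posteriors, reverse=True)
        best = 0
        for n in range(1, len(srt) + 1):
            if np.mean(srt[:n]) >= 1 - phi:
                best = n
        assert len(out) == best
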