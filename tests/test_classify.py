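"""Gaussian likelihoods, Bayes posteriors, no-call gates, end-to-end calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import meltcall as mc
from meltcall.classify import (
    LOW_POSTERIOR,
    OUTSIDE_ELLIPSOID,
    classify_batch,
    coverage_threshold,
    mahalanobis_sq,
)
from tests.conftest import make_truth_map, toy_model


class TestLogLikelihood:
    def test_at_mean_with_identity_covariance(self):
        mu = np.zeros(3)
        ll = mc.log_likelihood(mu, mu, np.eye(3))
        assert ll == pytest.approx(-1.5 * np.log(2 * np.pi), abs=1e-10)
        assert ll == pytest.approx(-2.75682, abs=1e-5)

    def test_determinant_term_with_scaled_covariance(self):
        mu = np.zeros(3)
        ll = mc.log_likelihood(mu, mu, np.diag([4.0, 1.0, 1.0]))
        assert ll == pytest.approx(-1.5 * np.log(2 * np.pi) - 0.5 * np.log(4), abs=1e-10)
        assert ll == pytest.approx(-3.44996, abs=1e-4)

    def test_symmetry_about_the_mean(self):
        mu = np.array([1.0, -2.0, 0.5])
        delta = np.array([0.3, 0.1, -0.7])
        assert mc.log_likelihood(mu + delta, mu, np.eye(3)) == pytest.approx(
            mc.log_likelihood(mu - delta, mu, np.eye(3)), abs=1e-12
        )

    def test_matches_scipy_multivariate_normal(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(3, 3))
        C = A @ A.T + np.eye(3)
        mu = rng.normal(size=3)
        v = rng.normal(size=3)
        assert mc.log_likelihood(v, mu, C) == pytest.approx(
            stats.multivariate_normal(mu, C).logpdf(v), abs=1e-10
        )


class TestPosteriors:
    def test_equal_likelihoods_uniform_priors_give_thirds(self):
        p = mc.posteriors(np.array([-5.0, -5.0, -5.0]), np.full(3, 1 / 3))
        assert np.allclose(p, 1 / 3)

    def test_prior_pass_through_for_equal_likelihoods(self):
        p = mc.posteriors(np.array([-10.0, -10.0, -10.0]), np.array([0.5, 0.25, 0.25]))
        assert np.allclose(p, [0.5, 0.25, 0.25])

    def test_extreme_log_likelihoods_stay_normalized(self):
        p = mc.posteriors(np.array([-1e6, -1e6 + 3, -2e6]), np.full(3, 1 / 3))
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert p[1] > p[0] > p[2]

    @given(
        ll=st.lists(st.floats(-700, 0), min_size=2, max_size=6),
        raw_priors=st.lists(st.floats(0.01, 1), min_size=2, max_size=6),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_posteriors_always_sum_to_one(self, ll, raw_priors):
        k = min(len(ll), len(raw_priors))
        priors = np.array(raw_priors[:k])
        priors /= priors.sum()
        p = mc.posteriors(np.array(ll[:k]), priors)
        assert abs(p.sum() - 1.0) <= 1e-9
        assert np.all(p >= 0)

    def test_prior_monotonicity(self):
        # raising one class prior (renormalized) never lowers its posterior
        ll = np.array([-3.0, -2.0, -4.0])
        for w in [0.1, 0.3, 0.5, 0.8]:
            pr1 = np.array([w, (1 - w) / 2, (1 - w) / 2])
            pr2 = np.array([w + 0.1, (0.9 - w) / 2, (0.9 - w) / 2])
            assert mc.posteriors(ll, pr2)[0] >= mc.posteriors(ll, pr1)[0]

    def test_oracle_equivalence_with_direct_bayes_formula(self):
        # log-space computation vs naive Eq-style evaluation on random instances
        rng = np.random.default_rng(123)
        for _ in range(1000):
            ll = rng.uniform(-30, 0, size=3)
            pr = rng.dirichlet(np.ones(3))
            direct = pr * np.exp(ll)
            direct = direct / direct.sum()
            assert np.allclose(mc.posteriors(ll, pr), direct, atol=1e-10)


class TestContainment:
    def test_point_at_mean_is_inside_with_zero_distance(self):
        inside, d2 = mc.containment(np.zeros(3), np.zeros(3), np.eye(3), 0.9999)
        assert inside and d2 == 0.0

    def test_chi_square_boundary_at_9999_coverage(self):
        thr = stats.chi2.ppf(0.9999, 3)
        assert thr == pytest.approx(21.11, abs=0.01)
        v = np.array([np.sqrt(thr + 0.01), 0.0, 0.0])
        inside, d2 = mc.containment(v, np.zeros(3), np.eye(3), 0.9999)
        assert not inside
        v = np.array([np.sqrt(thr - 0.01), 0.0, 0.0])
        inside, _ = mc.containment(v, np.zeros(3), np.eye(3), 0.9999)
        assert inside

    def test_coverage_one_limit_contains_everything(self):
        inside, _ = mc.containment(np.full(3, 100.0), np.zeros(3), np.eye(3), 1.0)
        assert inside

    def test_predictive_threshold_exceeds_chi_square_and_converges_back(self):
        chi = coverage_threshold(0.9999, 3)
        assert coverage_threshold(0.9999, 3, 32) > chi
        assert coverage_threshold(0.9999, 3, 10_000_000) == pytest.approx(chi, rel=1e-3)


class TestClassifyPoint:
    def test_point_at_cluster_mean_called_confidently(self):
        model = toy_model([[0, 0, 0], [10, 0, 0], [0, 10, 0]],
                          [np.eye(3)] * 3, labels=["WT", "HET", "HOM"])
        call = mc.classify_point(np.zeros(3), model)
        assert call.call == "WT"
        assert call.max_posterior > 0.995
        assert call.no_call_reason is None

    def test_midpoint_between_two_classes_is_low_posterior_no_call(self):
        model = toy_model([[0, 0, 0], [4, 0, 0], [100, 100, 0]], [np.eye(3)] * 3)
        call = mc.classify_point(np.array([2.0, 0.0, 0.0]), model)
        assert call.call is None
        assert call.no_call_reason == LOW_POSTERIOR
        p = sorted(call.posteriors.values())
        assert p[-1] == pytest.approx(0.5, abs=1e-6)
        assert p[-2] == pytest.approx(0.5, abs=1e-6)

    def test_far_point_is_outside_ellipsoid_no_call(self):
        model = toy_model([[0, 0, 0], [4, 0, 0]], [np.eye(3)] * 2)
        call = mc.classify_point(np.array([50.0, 50.0, 50.0]), model)
        assert call.call is None
        assert call.no_call_reason == OUTSIDE_ELLIPSOID

    def test_low_posterior_reported_first_when_both_gates_fail(self):
        model = toy_model([[0, 0, 0], [0.5, 0, 0]], [1e-4 * np.eye(3)] * 2)
        call = mc.classify_point(np.array([0.25, 3.0, 0.0]), model)
        assert call.call is None
        assert call.no_call_reason == LOW_POSTERIOR

    def test_posteriors_recorded_for_every_class_and_sum_to_one(self):
        model = toy_model([[0, 0, 0], [4, 0, 0], [0, 4, 0]], [np.eye(3)] * 3)
        call = mc.classify_point(np.array([1.0, 0.5, 0.2]), model)
        assert set(call.posteriors) == set(model.labels)
        assert sum(call.posteriors.values()) == pytest.approx(1.0, abs=1e-9)
        assert set(call.d2) == set(model.labels)


class TestBatchEquivalence:
    def test_batch_and_scalar_paths_agree_on_random_instances(self):
        rng = np.random.default_rng(9)
        model = toy_model(
            [rng.normal(size=3) for _ in range(3)],
            [np.eye(3) * s for s in (1.0, 2.0, 0.5)],
        )
        V = rng.normal(scale=3.0, size=(200, 3))
        batch = classify_batch(V, model.mu_matrix(), model.cov_stack(),
                               model.prior_vector(), model.posterior_min,
                               model.ellipsoid_coverage,
                               n_train=np.array([model.n_train[g] for g in model.labels]))
        for i in range(0, 200, 17):
            call = mc.classify_point(V[i], model)
            assert np.allclose(list(call.posteriors.values()), batch.posteriors[i],
                               atol=1e-12)
            assert (call.call is not None) == bool(batch.called[i])


class TestEndToEnd:
    def test_well_separated_assay_fully_concordant_no_no_calls(self, default_fixture):
        calls = mc.classify_dataset(default_fixture["dataset"], default_fixture["model"])
        truth = make_truth_map(default_fixture["truth"])
        assert len(calls) == 120
        assert all(c.is_call for c in calls)
        assert all(c.call == truth[(c.plate_id, c.well_id)] for c in calls)
        assert min(c.max_posterior for c in calls) >= 0.995

    def test_overlap_assay_produces_no_calls_and_no_wrong_calls(self, overlap_fixture):
        calls = mc.classify_dataset(overlap_fixture["dataset"], overlap_fixture["model"])
        truth = make_truth_map(overlap_fixture["truth"])
        no_calls = [c for c in calls if not c.is_call]
        made = [c for c in calls if c.is_call]
        assert len(no_calls) >= 1
        assert all(c.call == truth[(c.plate_id, c.well_id)] for c in made)
        assert all(c.max_posterior >= 0.995 for c in made)

    def test_one_sigma_separation_regime_never_makes_unsafe_calls(self):
        # two Gaussians one sd apart: the posterior gate suppresses everything
        # between them; whatever is called must carry >= 0.995 posterior
        rng = np.random.default_rng(21)
        model = toy_model([[0.0, 0.0], [1.0, 0.0]], [np.eye(2)] * 2)
        V = np.vstack([rng.normal([0, 0], 1, (300, 2)), rng.normal([1, 0], 1, (300, 2))])
        batch = classify_batch(V, model.mu_matrix(), model.cov_stack(),
                               model.prior_vector(), 0.995, 0.9999)
        assert (~batch.called).sum() >= 1
        called_posteriors = batch.posteriors[np.arange(len(V)), batch.winner][batch.called]
        assert np.all(called_posteriors >= 0.995)
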