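"""ANCKG averaging, correlation features, spherical transform, Gaussian fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import meltcall as mc
from meltcall.errors import GridMismatchError, MetadataError, SingularCovarianceError
from meltcall.preprocess import DerivativeCurve
from meltcall.train import normality_report


def curve(values, start=75.0, step=0.05):
    return DerivativeCurve(start, step, np.asarray(values, dtype=float))


class TestAnckg:
    def test_group_of_identical_curves_gives_that_curve(self):
        c = mc.normalize(curve(np.sin(np.linspace(0, 3, 100))))
        out = mc.compute_anckg({"WT": [c, c, c]})
        assert np.allclose(out["WT"].values, c.values, atol=1e-12)

    def test_pointwise_mean_of_three_curves(self):
        rng = np.random.default_rng(0)
        cs = [mc.normalize(curve(rng.normal(size=100))) for _ in range(3)]
        out = mc.compute_anckg({"g": cs})
        raw_mean = np.mean([c.values for c in cs], axis=0)
        expected = (raw_mean - raw_mean.mean()) / raw_mean.std(ddof=1)
        assert np.allclose(out["g"].values, expected)

    def test_cancelling_curves_surface_as_degenerate_average(self):
        base = np.sin(np.linspace(0, 3, 100))
        a = mc.normalize(curve(base))
        b = mc.normalize(curve(-base))
        with pytest.raises(mc.errors.DegenerateCurveError):
            mc.compute_anckg({"g": [a, b]})

    def test_empty_group_is_an_error(self):
        with pytest.raises(MetadataError):
            mc.compute_anckg({"g": []})

    def test_mismatched_grids_rejected(self):
        a = mc.normalize(curve(np.sin(np.linspace(0, 3, 100)), start=75.0))
        b = mc.normalize(curve(np.sin(np.linspace(0, 3, 100)), start=76.0))
        with pytest.raises(GridMismatchError):
            mc.compute_anckg({"g": [a, b]})


class TestCorrelationVector:
    def test_curve_equal_to_anckg_gives_unit_correlation(self):
        c = mc.normalize(curve(np.sin(np.linspace(0, 3, 100))))
        r = mc.correlation_vector(c, {"g": c}, ["g"])
        assert r[0] == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_pearson_value(self):
        a = curve([1.0, 2.0, 3.0])
        b = curve([1.0, 2.0, 4.0])
        r = mc.correlation_vector(a, {"g": b}, ["g"])
        assert r[0] == pytest.approx(0.98198, abs=1e-5)

    def test_affine_rescaling_of_curve_leaves_r_unchanged(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=100)
        anckg = mc.normalize(curve(rng.normal(size=100)))
        r1 = mc.correlation_vector(curve(base), {"g": anckg}, ["g"])
        r2 = mc.correlation_vector(curve(3.2 * base + 11), {"g": anckg}, ["g"])
        assert r1[0] == pytest.approx(r2[0], abs=1e-12)


class TestSphericalTransform:
    def test_unit_basis_vector_maps_to_length_one_zero_angles(self):
        v = mc.spherical_transform(np.array([1.0, 0.0, 0.0]))
        assert np.allclose(v, [1.0, 0.0, 0.0])

    def test_all_ones_vector_worked_example(self):
        v = mc.spherical_transform(np.array([1.0, 1.0, 1.0]))
        assert np.allclose(v, [np.sqrt(3), np.pi / 4, np.arctan(1 / np.sqrt(2))],
                           atol=1e-5)
        assert np.allclose(v, [1.73205, 0.78540, 0.61548], atol=1e-5)

    def test_inverse_of_worked_example(self):
        r = mc.inverse_spherical(np.array([np.sqrt(3), np.pi / 4,
                                           np.arctan(1 / np.sqrt(2))]))
        assert np.allclose(r, [1.0, 1.0, 1.0], atol=1e-9)

    def test_inverse_is_homogeneous_in_length(self):
        v = np.array([0.8, 0.3, -0.2])
        doubled = v.copy()
        doubled[0] *= 2
        assert np.allclose(mc.inverse_spherical(doubled),
                           2 * mc.inverse_spherical(v), atol=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            mc.spherical_transform(np.zeros(3))

    @given(
        r=arrays(np.float64, st.integers(2, 5),
                 elements=st.floats(-1, 1, allow_nan=False, width=32)).filter(
            lambda a: a[0] > 1e-3 and np.linalg.norm(a) > 1e-3
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip_identity_for_positive_first_component(self, r):
        r = np.asarray(r, dtype=float)
        back = mc.inverse_spherical(mc.spherical_transform(r))
        assert np.allclose(back, r, atol=1e-9)


class TestFitDistributions:
    def test_parameter_recovery_from_known_gaussian(self):
        rng = np.random.default_rng(42)
        mu = np.array([1.5, 0.6, 0.4])
        A = np.array([[0.04, 0.0, 0.0], [0.01, 0.03, 0.0], [0.0, 0.01, 0.02]])
        C = A @ A.T
        V = rng.multivariate_normal(mu, C, size=10_000)
        fitted = mc.fit_genotype_distributions({"g": V})
        mu_hat, C_hat, eps = fitted["g"]
        se = np.sqrt(np.diag(C) / len(V))
        assert np.all(np.abs(mu_hat - mu) <= 4 * se)
        assert np.linalg.norm(C_hat - C) / np.linalg.norm(C) <= 0.10

    def test_too_few_vectors_is_singular_covariance_error(self):
        V = np.random.default_rng(0).normal(size=(3, 3))
        with pytest.raises(SingularCovarianceError, match="g"):
            mc.fit_genotype_distributions({"g": V})

    def test_identical_vectors_exercise_the_ridge_path(self):
        V = np.tile([1.0, 0.5, 0.2], (10, 1))
        fitted = mc.fit_genotype_distributions({"g": V})
        mu_hat, C_hat, eps = fitted["g"]
        assert np.allclose(mu_hat, [1.0, 0.5, 0.2])
        assert eps > 0
        np.linalg.cholesky(C_hat)  # must be positive definite after the ridge

    def test_genotypes_get_independent_covariances_not_pooled(self, default_fixture):
        model = default_fixture["model"]
        covs = [model.cov[g] for g in model.labels]
        assert not np.allclose(covs[0], covs[1])
        assert not np.allclose(covs[1], covs[2])


class TestTrainModel:
    def test_training_plate_design_yields_valid_three_class_model(self, default_fixture):
        model = default_fixture["model"]
        assert model.n_classes == 3
        assert sum(model.n_train.values()) == 96  # 32 samples in triplicate
        assert sum(model.priors.values()) == pytest.approx(1.0)
        for g in model.labels:
            np.linalg.cholesky(model.cov[g])
            assert model.mu[g].shape == (3,)
            assert abs(model.anckg[g].values.mean()) < 1e-9

    def test_two_genotype_dataset_gives_two_dimensional_features(self):
        cfg = mc.default_assay_config(seed=5)
        cfg.genotypes = cfg.genotypes[:2]  # WT + HET only
        layout = cfg.plates[0]
        layout.samples = [(s, ["WT", "HET"][i % 2], n, role)
                          for i, (s, _, n, role) in enumerate(layout.samples)]
        cfg.plates = [layout]
        cfg.plate_offsets = {"train1": 0.0}
        ds, _ = mc.simulate_dataset(cfg)
        model = mc.train_model(
            ds, config=mc.PreprocessConfig(classification_range=(75.0, 83.0)), seed=5
        )
        assert model.n_classes == 2
        assert model.mu["WT"].shape == (2,)

    def test_training_set_with_single_genotype_is_an_error(self):
        cfg = mc.default_assay_config(seed=5)
        layout = cfg.plates[0]
        layout.samples = [(s, "WT", n, role) for (s, _, n, role) in layout.samples]
        cfg.plates = [layout]
        cfg.plate_offsets = {"train1": 0.0}
        ds, _ = mc.simulate_dataset(cfg)
        with pytest.raises(MetadataError):
            mc.train_model(
                ds, config=mc.PreprocessConfig(classification_range=(75.0, 83.0))
            )

    def test_feature_invariance_training_on_rescaled_copies_gives_same_model(self):
        cfg = mc.default_assay_config(seed=7)
        ds, _ = mc.simulate_dataset(cfg)
        pp = mc.PreprocessConfig(classification_range=(75.0, 83.0))
        m1 = mc.train_model(ds, config=pp, seed=7)
        for key, tr in ds.traces.items():
            tr.fluorescence = 2.5 * tr.fluorescence + 40.0
        m2 = mc.train_model(ds, config=pp, seed=7)
        for g in m1.labels:
            assert np.allclose(m1.mu[g], m2.mu[g], atol=1e-9)
            assert np.allclose(m1.cov[g], m2.cov[g], atol=1e-12)

    def test_self_consistency_own_anckg_correlation_is_maximal(self, default_fixture):
        result = default_fixture["result"]
        labels = result.model.labels
        for g in labels:
            R = result.r_vectors[g]
            own = labels.index(g)
            assert np.all(np.argmax(R, axis=1) == own)


class TestNormalityReport:
    def test_reports_both_spherical_and_raw_parameters(self, default_fixture):
        rep = normality_report(default_fixture["result"])
        params = set(rep["parameter"])
        assert {"l", "a1", "a2", "r1", "r2", "r3"} <= params
        assert not rep["insufficient"].any()

    def test_small_group_flagged_insufficient(self, default_fixture):
        import dataclasses
        result = default_fixture["result"]
        small = dataclasses.replace(
            result,
            r_vectors={g: v[:5] for g, v in result.r_vectors.items()},
            v_vectors={g: v[:5] for g, v in result.v_vectors.items()},
        )
        rep = normality_report(small)
        assert rep["insufficient"].all()

    def test_heavy_tailed_vectors_are_detected(self):
        # power check: inject a heavy tail, Shapiro should reject
        rng = np.random.default_rng(3)
        x = rng.standard_t(df=1.5, size=(100, 3))
        from scipy import stats
        p = stats.shapiro(x[:, 0]).pvalue
        rejections = sum(
            stats.shapiro(rng.standard_t(df=1.5, size=100)).pvalue < 0.01
            for _ in range(20)
        )
        assert rejections >= 15
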