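"""Shared fixtures: synthetic datasets and trained models at the study scale."""

import numpy as np
import pytest

import meltcall as mc

SEED = 1  # canonical fixture seed used throughout the suite


def make_truth_map(truth):
    return {(r.plate, r.well): r.genotype for r in truth.itertuples()}


@pytest.fixture(scope="session")
def default_fixture():
    """Well-separated 3-genotype assay: dataset, truth and trained model."""
    cfg = mc.default_assay_config(seed=SEED)
    dataset, truth = mc.simulate_dataset(cfg)
    pp = mc.PreprocessConfig(classification_range=(75.0, 83.0))
    result = mc.train_with_details(dataset, config=pp, seed=SEED)
    return {"config": cfg, "dataset": dataset, "truth": truth,
            "result": result, "model": result.model}


@pytest.fixture(scope="session")
def overlap_fixture():
    """Overlapping wild-type/homozygote assay (deliberate no-call regime)."""
    cfg = mc.overlap_assay_config(seed=SEED)
    dataset, truth = mc.simulate_dataset(cfg)
    pp = mc.PreprocessConfig(classification_range=(75.0, 84.0))
    result = mc.train_with_details(dataset, config=pp, seed=SEED)
    return {"config": cfg, "dataset": dataset, "truth": truth,
            "result": result, "model": result.model}


def toy_model(mus, covs, labels=None, priors=None, posterior_min=0.995,
              coverage=0.9999, n_train=100_000):
    """GenotypeModel built directly in feature space (no curves).

    Large default n_train makes the predictive containment quantile
    numerically equal to the χ² quantile, so tests can reason with
    closed-form Gaussian geometry.
    """
    mus = [np.asarray(m, dtype=float) for m in mus]
    covs = [np.asarray(c, dtype=float) for c in covs]
    k = len(mus)
    labels = labels or [f"G{i}" for i in range(k)]
    priors = priors or {g: 1.0 / k for g in labels}
    return mc.GenotypeModel(
        labels=list(labels),
        anckg={},
        mu=dict(zip(labels, mus)),
        cov=dict(zip(labels, covs)),
        n_train={g: n_train for g in labels},
        priors=dict(priors),
        t_range=(75.0, 83.0),
        reference_pc=None,
        preprocess=mc.PreprocessConfig(classification_range=(75.0, 83.0)),
        posterior_min=posterior_min,
        ellipsoid_coverage=coverage,
    )
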