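"""Bayes classification of spherical feature vectors with dual no-call gating.

The class-conditional density of a feature vector v for genotype g_i is a
multivariate normal N(μ_i, C_i); posteriors follow from Bayes' theorem with
the class priors. A well is called as the genotype with the largest posterior
unless either gate fires:

* low_posterior — the winning posterior is below ``posterior_min`` (curves
  falling between two clusters);
* outside_ellipsoid — the point lies outside the winner's MVN coverage
  ellipsoid (squared Mahalanobis distance beyond the χ²_{N_c} quantile),
  flagging points far from every training cluster, e.g. unseen variants.

Both gates are always evaluated and recorded; when both fail, low_posterior
is reported. Likelihoods are computed in log space with max-subtraction: the
raw Gaussian density underflows double precision for distant points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .errors import UndefinedPosteriorError
from .melt_io import MeltDataset, Role, WellKey
from .preprocess import DerivativeCurve, preprocess_dataset
from .train import GenotypeModel, correlation_vector, spherical_transform

LOW_POSTERIOR = "low_posterior"
OUTSIDE_ELLIPSOID = "outside_ellipsoid"


@dataclass
class GenotypeCall:
    """Result of classifying one well."""

    plate_id: str
    well_id: str
    sample_id: str
    posteriors: Dict[str, float]
    call: Optional[str]  # genotype label, or None for a no-call
    no_call_reason: Optional[str]
    max_posterior: float
    best_label: str  # argmax-posterior label even when no call was made
    d2: Dict[str, float]  # squared Mahalanobis distance to every genotype
    containment_quantile: float  # χ² quantile the winner's d² was compared to
    r: Optional[np.ndarray] = None  # correlation vector (kept for visualization)
    v: Optional[np.ndarray] = None  # spherical feature vector

    @property
    def is_call(self) -> bool:
        return self.call is not None


# ---------------------------------------------------------------------------
# core numerics


def log_likelihood(v: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> float:
    """Gaussian log density via Cholesky factorization (no explicit inverse)."""
    v = np.asarray(v, dtype=float)
    mu = np.asarray(mu, dtype=float)
    d = v.size
    L = np.linalg.cholesky(np.asarray(cov, dtype=float))
    y = sla.solve_triangular(L, v - mu, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(-0.5 * y @ y - 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet)


def mahalanobis_sq(v: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> float:
    L = np.linalg.cholesky(np.asarray(cov, dtype=float))
    y = sla.solve_triangular(L, np.asarray(v, float) - np.asarray(mu, float), lower=True)
    return float(y @ y)


def posteriors(log_liks: np.ndarray, priors: np.ndarray) -> np.ndarray:
    """Bayes posteriors from log-likelihoods, normalized in log space.

    p(g_i|v) = P(g_i) p(v|g_i) / Σ_j P(g_j) p(v|g_j); the output sums to 1.
    """
    log_liks = np.asarray(log_liks, dtype=float)
    priors = np.asarray(priors, dtype=float)
    with np.errstate(divide="ignore"):
        logp = log_liks + np.log(priors)
    m = np.max(logp)
    if not np.isfinite(m):
        raise UndefinedPosteriorError("all class likelihoods vanished")
    w = np.exp(logp - m)
    return w / w.sum()


def containment(
    v: np.ndarray, mu: np.ndarray, cov: np.ndarray, coverage: float
) -> Tuple[bool, float]:
    """Is v inside the genotype's MVN coverage ellipsoid?

    The ellipsoid containing a ``coverage`` fraction of N(μ, C) is
    {x : (x−μ)ᵀC⁻¹(x−μ) ≤ χ²_d(coverage)} — the χ² quantile form of the
    multivariate normal cumulative coverage.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    d2 = mahalanobis_sq(v, mu, cov)
    thresh = float(stats.chi2.ppf(coverage, df=np.asarray(v).size))
    return d2 <= thresh, d2


# ---------------------------------------------------------------------------
# batch classification (shared by per-well calls and Monte Carlo simulation)


@dataclass
class BatchResult:
    posteriors: np.ndarray  # (n, k)
    winner: np.ndarray  # (n,) int index into labels
    d2: np.ndarray  # (n, k) squared Mahalanobis distances
    called: np.ndarray  # (n,) bool
    reason: np.ndarray  # (n,) object: None / low_posterior / outside_ellipsoid
    chi2_threshold: float  # largest per-class containment threshold (summary)
    thresholds: np.ndarray = None  # (k,) per-class containment thresholds


def coverage_threshold(
    coverage: float, d: int, n_train: Optional[int] = None
) -> float:
    """Squared-Mahalanobis threshold containing ``coverage`` of a genotype.

    With known (μ, C) this is the χ²_d quantile. When the Gaussian was
    estimated from ``n_train`` curves, the squared Mahalanobis distance of a
    *fresh* curve to the estimated parameters follows the scaled-F predictive
    law d²  ~  d(n²−1)/(n(n−d)) · F(d, n−d), whose tail is heavier than χ²'s;
    gating fresh curves at the χ² quantile would then no-call a surplus of
    perfectly typical curves at triplicate-scale training sizes. Passing
    ``n_train`` selects the predictive quantile (it converges to χ² as
    n_train → ∞).
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    if coverage == 1:
        return float("inf")
    if n_train is None or n_train <= d:
        return float(stats.chi2.ppf(coverage, df=d))
    n = n_train
    scale = d * (n * n - 1) / (n * (n - d))
    return float(scale * stats.f.ppf(coverage, d, n - d))


def classify_batch(
    V: np.ndarray,
    mus: np.ndarray,
    covs: np.ndarray,
    priors: np.ndarray,
    posterior_min: float,
    coverage: float,
    n_train: Optional[np.ndarray] = None,
) -> BatchResult:
    """Vectorized classification of n feature vectors against k Gaussians."""
    V = np.atleast_2d(np.asarray(V, dtype=float))
    n, d = V.shape
    k = mus.shape[0]
    log_liks = np.empty((n, k))
    d2 = np.empty((n, k))
    for i in range(k):
        L = np.linalg.cholesky(covs[i])
        y = sla.solve_triangular(L, (V - mus[i]).T, lower=True)
        q = np.einsum("ij,ij->j", y, y)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        d2[:, i] = q
        log_liks[:, i] = -0.5 * q - 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet
    with np.errstate(divide="ignore"):
        logp = log_liks + np.log(priors)
    m = logp.max(axis=1, keepdims=True)
    finite = np.isfinite(m[:, 0])
    post = np.full((n, k), np.nan)
    if finite.any():
        w = np.exp(logp[finite] - m[finite])
        post[finite] = w / w.sum(axis=1, keepdims=True)
    winner = np.where(finite, np.nanargmax(np.where(np.isnan(post), -np.inf, post), axis=1), 0)
    max_post = np.where(finite, post[np.arange(n), winner], 0.0)
    if n_train is None:
        thresholds = np.full(k, coverage_threshold(coverage, d))
    else:
        thresholds = np.array(
            [coverage_threshold(coverage, d, int(nt)) for nt in n_train]
        )
    thresh = float(thresholds.max())
    d2_winner = d2[np.arange(n), winner]
    inside = d2_winner <= thresholds[winner]
    low = max_post < posterior_min
    called = finite & ~low & inside
    reason = np.empty(n, dtype=object)
    reason[:] = None
    # low_posterior reported first when both gates fail
    reason[low] = LOW_POSTERIOR
    reason[~low & ~inside] = OUTSIDE_ELLIPSOID
    reason[~finite] = OUTSIDE_ELLIPSOID  # numerically impossible points
    return BatchResult(posteriors=post, winner=winner, d2=d2, called=called,
                       reason=reason, chi2_threshold=thresh, thresholds=thresholds)


# ---------------------------------------------------------------------------
# per-well interface


def classify_point(
    v: np.ndarray,
    model: GenotypeModel,
    well_ref: WellKey = ("", ""),
    sample_id: str = "",
    r: Optional[np.ndarray] = None,
) -> GenotypeCall:
    """Classify a single spherical feature vector."""
    batch = classify_batch(
        v[None, :] if np.ndim(v) == 1 else np.asarray(v),
        model.mu_matrix(),
        model.cov_stack(),
        model.prior_vector(),
        model.posterior_min,
        model.ellipsoid_coverage,
        n_train=np.array([model.n_train[g] for g in model.labels]),
    )
    labels = model.labels
    post = batch.posteriors[0]
    widx = int(batch.winner[0])
    called = bool(batch.called[0])
    post_dict = {g: float(post[i]) for i, g in enumerate(labels)}
    return GenotypeCall(
        plate_id=well_ref[0],
        well_id=well_ref[1],
        sample_id=sample_id,
        posteriors=post_dict,
        call=labels[widx] if called else None,
        no_call_reason=None if called else str(batch.reason[0]),
        max_posterior=float(post[widx]) if np.isfinite(post[widx]) else 0.0,
        best_label=labels[widx],
        d2={g: float(batch.d2[0, i]) for i, g in enumerate(labels)},
        containment_quantile=float(batch.thresholds[widx]),
        r=None if r is None else np.asarray(r, dtype=float),
        v=np.asarray(v, dtype=float),
    )


def classify_well(
    curve_or_v: Union[DerivativeCurve, np.ndarray],
    model: GenotypeModel,
    well_ref: WellKey = ("", ""),
    sample_id: str = "",
) -> GenotypeCall:
    """Classify one well from a preprocessed derivative curve or a feature vector.

    A DerivativeCurve must already be on the model's restricted grid (the
    dataset-level entry point :func:`classify_dataset` handles preprocessing,
    including the per-plate temperature shift against the model's stored
    reference positive control).
    """
    if isinstance(curve_or_v, DerivativeCurve):
        r = correlation_vector(curve_or_v, model.anckg, model.labels)
        v = spherical_transform(r)
        ref = curve_or_v.well_ref or well_ref
        return classify_point(v, model, well_ref=ref, sample_id=sample_id, r=r)
    return classify_point(np.asarray(curve_or_v, dtype=float), model,
                          well_ref=well_ref, sample_id=sample_id)


def classify_dataset(
    dataset: MeltDataset,
    model: GenotypeModel,
    roles: Sequence[Role] = (Role.UNKNOWN,),
) -> List[GenotypeCall]:
    """Preprocess and classify every well of the given roles.

    Preprocessing reuses the model's stored settings and reference positive
    control, so plates are shifted into the training set's temperature frame
    before classification.
    """
    dataset.validate_join()
    final, _shifts, _ref = preprocess_dataset(
        dataset, model.preprocess, model.t_range, reference_pc=model.reference_pc
    )
    calls: List[GenotypeCall] = []
    for key, m in dataset.meta.items():
        if m.role not in roles or key not in final:
            continue
        calls.append(classify_well(final[key], model, well_ref=key, sample_id=m.sample_id))
    return calls
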