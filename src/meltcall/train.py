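"""Training: ANCKG curves, correlation features, spherical transform, per-genotype Gaussians.

Each normalized derivative curve is correlated against the averaged normalized
curve of every known genotype (ANCKG), giving a correlation vector r of length
N_c (the number of genotype classes). Raw correlations are bounded and skewed,
so r is mapped to hyperspherical coordinates v = (l, a_1, …, a_{N_c−1}) —

    l   = ‖r‖₂
    a_k = arctan( r_{k+1} / sqrt(r_1² + … + r_k²) )

— whose components are approximately normally distributed within a genotype.
Each genotype then gets its own mean vector μ_i and covariance matrix C_i
(no pooled-covariance assumption, unlike LDA: cluster shapes genuinely differ
between genotypes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import (
    DegenerateCurveError,
    GridMismatchError,
    MetadataError,
    SingularCovarianceError,
)
from .melt_io import MeltDataset, Role, WellKey
from .preprocess import (
    DerivativeCurve,
    PreprocessConfig,
    ShiftedCurves,
    finalize_curves,
    normalize,
    shift_dataset,
)

#: condition-number threshold above which a covariance ridge is applied
_COND_MAX = 1e10
#: relative ridge magnitude: eps * trace(C)/N_c added to the diagonal
_RIDGE_EPS = 1e-8


# ---------------------------------------------------------------------------
# feature construction


def compute_anckg(
    curves_by_label: Dict[str, Sequence[DerivativeCurve]]
) -> Dict[str, DerivativeCurve]:
    """Averaged Normalized Curve of Known Genotype, per genotype.

    Curves in each group are averaged pointwise on their shared grid and the
    average is re-normalized to zero mean / unit sd, keeping ANCKGs on the
    same scale as member curves (correlations are unaffected by the rescale).
    """
    out: Dict[str, DerivativeCurve] = {}
    ref: Optional[DerivativeCurve] = None
    for label, curves in curves_by_label.items():
        curves = list(curves)
        if not curves:
            raise MetadataError(f"genotype {label!r} has no training curves")
        first = curves[0]
        for c in curves[1:]:
            if not c.same_grid(first):
                raise GridMismatchError(
                    f"training curves for genotype {label!r} are not on a common grid "
                    f"({c.well_ref} vs {first.well_ref})"
                )
        if ref is not None and not first.same_grid(ref):
            raise GridMismatchError("ANCKG groups are not on a common grid")
        ref = first
        mean_vals = np.mean([c.values for c in curves], axis=0)
        avg = DerivativeCurve(
            grid_start=first.grid_start,
            grid_step=first.grid_step,
            values=mean_vals,
            well_ref=None,
            applied_shift=0.0,
            stages=first.stages,
        )
        try:
            out[label] = normalize(avg)
        except DegenerateCurveError:
            raise DegenerateCurveError(
                f"genotype {label!r}: averaged curve has zero variance (member "
                "curves cancel); cannot form an ANCKG"
            )
    return out


def correlation_vector(
    curve: DerivativeCurve, anckgs: Dict[str, DerivativeCurve], labels: Sequence[str]
) -> np.ndarray:
    """Pearson correlation of one curve with each ANCKG, in label order."""
    r = np.empty(len(labels))
    for i, g in enumerate(labels):
        a = anckgs[g]
        if not curve.same_grid(a):
            raise GridMismatchError(
                f"well {curve.well_ref}: curve grid does not match the ANCKG grid "
                f"(curve {curve.grid_start:.2f}+{len(curve.values)}pts, "
                f"ANCKG {a.grid_start:.2f}+{len(a.values)}pts)"
            )
        if curve.values.std() == 0 or a.values.std() == 0:
            raise DegenerateCurveError(
                f"well {curve.well_ref}: zero-variance curve in correlation"
            )
        r[i] = np.corrcoef(curve.values, a.values)[0, 1]
    return r


def spherical_transform(r: np.ndarray) -> np.ndarray:
    """Map a correlation vector to hyperspherical coordinates (l, a_1, …).

    l = ‖r‖₂; a_k = arctan(r_{k+1} / sqrt(Σ_{j≤k} r_j²)). The single-argument
    arctan means the sign of r₁ is not represented; in-range melt curves always
    correlate strongly positively with at least one ANCKG, and pathological
    all-negative points are gated out by the coverage ellipsoid downstream.
    """
    r = np.asarray(r, dtype=float)
    l = float(np.linalg.norm(r))
    if l == 0:
        raise ValueError("cannot transform the zero correlation vector")
    v = np.empty(r.size)
    v[0] = l
    rho = np.sqrt(np.cumsum(r**2))
    for k in range(1, r.size):
        denom = rho[k - 1]
        if denom == 0:
            v[k] = np.copysign(np.pi / 2, r[k]) if r[k] != 0 else 0.0
        else:
            v[k] = np.arctan(r[k] / denom)
    return v


def inverse_spherical(v: np.ndarray) -> np.ndarray:
    """Invert the hyperspherical transform (r₁ ≥ 0 by convention).

    Homogeneous in l; exact inverse of :func:`spherical_transform` on the
    domain r₁ > 0.
    """
    v = np.asarray(v, dtype=float)
    d = v.size
    r = np.empty(d)
    rho = v[0]
    for k in range(d - 1, 0, -1):
        r[k] = rho * np.sin(v[k])
        rho = rho * np.cos(v[k])
    r[0] = rho
    return r


def fit_genotype_distributions(
    vectors_by_label: Dict[str, np.ndarray]
) -> Dict[str, Tuple[np.ndarray, np.ndarray, float]]:
    """Per-genotype mean vector and sample covariance (n−1 denominator).

    Returns label -> (mu, C, ridge_eps). Near-singular covariances (condition
    number above 1e10, common for triplicate-scale training sets with tightly
    clustered curves) get a recorded diagonal ridge of eps·trace(C)/d.
    """
    out: Dict[str, Tuple[np.ndarray, np.ndarray, float]] = {}
    for label, V in vectors_by_label.items():
        V = np.asarray(V, dtype=float)
        n, d = V.shape
        if n <= d:
            raise SingularCovarianceError(
                f"genotype {label!r}: {n} training vectors cannot support a "
                f"{d}-dimensional covariance (need at least {d + 1})"
            )
        if n < 3 * d:
            warnings.warn(
                f"genotype {label!r}: only {n} training vectors for {d} feature "
                "dimensions; covariance estimate will be noisy",
                stacklevel=2,
            )
        mu = V.mean(axis=0)
        C = np.cov(V, rowvar=False, ddof=1)
        C = np.atleast_2d(C)
        eps_applied = 0.0
        eps = _RIDGE_EPS
        while True:
            cond = np.linalg.cond(C)
            if np.isfinite(cond) and cond <= _COND_MAX and _is_pd(C):
                break
            bump = eps * np.trace(C) / d
            if bump <= 0:
                bump = eps
            C = C + bump * np.eye(d)
            eps_applied += bump
            eps *= 10
            if eps > 1e6:
                raise SingularCovarianceError(
                    f"genotype {label!r}: covariance cannot be regularized"
                )
        out[label] = (mu, C, eps_applied)
    return out


def _is_pd(C: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(C)
        return True
    except np.linalg.LinAlgError:
        return False


# ---------------------------------------------------------------------------
# the trained artifact


@dataclass
class GenotypeModel:
    """Everything needed to genotype an unknown melt curve.

    labels            ordered genotype names (defines feature order)
    anckg             per-genotype averaged normalized derivative curve
    mu, cov           per-genotype Gaussian parameters in spherical space
    n_train           training curves per genotype
    priors            class priors P(g_i), summing to 1 (uniform by default)
    t_range           classification temperature range (°C)
    reference_pc      averaged positive control of the first training plate
    preprocess        settings the training curves were produced with
    posterior_min     no-call gate: winning posterior must reach this value
    ellipsoid_coverage  no-call gate: winner's MVN coverage ellipsoid
    ridge             per-genotype covariance ridge applied (0 if none)
    """

    labels: List[str]
    anckg: Dict[str, DerivativeCurve]
    mu: Dict[str, np.ndarray]
    cov: Dict[str, np.ndarray]
    n_train: Dict[str, int]
    priors: Dict[str, float]
    t_range: Tuple[float, float]
    reference_pc: Optional[DerivativeCurve]
    preprocess: PreprocessConfig
    posterior_min: float = 0.995
    ellipsoid_coverage: float = 0.9999
    ridge: Dict[str, float] = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def mu_matrix(self) -> np.ndarray:
        return np.stack([self.mu[g] for g in self.labels])

    def cov_stack(self) -> np.ndarray:
        return np.stack([self.cov[g] for g in self.labels])

    def prior_vector(self) -> np.ndarray:
        return np.array([self.priors[g] for g in self.labels])

    def equals(self, other: "GenotypeModel", atol: float = 0.0) -> bool:
        """Field-by-field equality (arrays compared exactly by default)."""
        if self.labels != other.labels or self.n_train != other.n_train:
            return False
        if self.t_range != tuple(other.t_range):
            return False
        if (self.posterior_min, self.ellipsoid_coverage) != (
            other.posterior_min,
            other.ellipsoid_coverage,
        ):
            return False
        for g in self.labels:
            for a, b in (
                (self.mu[g], other.mu[g]),
                (self.cov[g], other.cov[g]),
                (self.anckg[g].values, other.anckg[g].values),
            ):
                if not np.allclose(a, b, rtol=0, atol=atol):
                    return False
            if abs(self.priors[g] - other.priors[g]) > atol:
                return False
        return True


@dataclass
class TrainingResult:
    """Model plus the per-well training features used to build it."""

    model: GenotypeModel
    r_vectors: Dict[str, np.ndarray]  # label -> (N_i, N_c) correlation vectors
    v_vectors: Dict[str, np.ndarray]  # label -> (N_i, N_c) spherical vectors
    shifts: Dict[str, float]
    well_order: Dict[str, List[WellKey]]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def _features_for_range(
    shifted: ShiftedCurves,
    training_keys_by_label: Dict[str, List[WellKey]],
    labels: Sequence[str],
    t_range: Tuple[float, float],
) -> Tuple[Dict[str, DerivativeCurve], Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Restrict + normalize training curves on a candidate range, build features.

    A training curve's correlation with its *own* genotype's ANCKG is computed
    against the leave-one-out average (the group mean excluding that curve).
    Including the curve in its own average biases the correlation upward and
    shrinks its spread, so the fitted (μ, C) would understate how far fresh
    curves of the same genotype scatter — and the coverage ellipsoid would
    then no-call perfectly normal wells. Pearson correlation is invariant to
    the ANCKG renormalization, so the raw leave-one-out mean is used directly.
    The model stores the full-group ANCKG for classifying unknowns.
    """
    all_keys = [k for keys in training_keys_by_label.values() for k in keys]
    final = finalize_curves({k: shifted.curves[k] for k in all_keys}, *t_range)
    grouped = {g: [final[k] for k in training_keys_by_label[g]] for g in labels}
    anckg = compute_anckg(grouped)
    r_vectors: Dict[str, np.ndarray] = {}
    v_vectors: Dict[str, np.ndarray] = {}
    for g in labels:
        curves = grouped[g]
        n_g = len(curves)
        X = np.stack([c.values for c in curves])
        group_sum = X.sum(axis=0)
        R = np.empty((n_g, len(labels)))
        for i, c in enumerate(curves):
            for j, other in enumerate(labels):
                if other == g and n_g > 1:
                    loo_mean = (group_sum - X[i]) / (n_g - 1)
                    if loo_mean.std() == 0:
                        raise DegenerateCurveError(
                            f"genotype {g!r}: leave-one-out average is constant"
                        )
                    R[i, j] = _pearson(X[i], loo_mean)
                else:
                    R[i, j] = correlation_vector(c, anckg, [other])[0]
        r_vectors[g] = R
        v_vectors[g] = np.stack([spherical_transform(r) for r in R])
    return anckg, r_vectors, v_vectors


def frame_sigma(shifted: ShiftedCurves) -> float:
    """Plate temperature-frame uncertainty (°C) from positive-control scatter.

    Each positive-control well yields its own shift estimate against the
    reference; their pooled within-plate variance s² measures the per-well
    alignment noise. A plate's frame (the averaged-control shift) is then
    known to s²/n_pc, and the operative error between a future plate and the
    reference plate is the sum of both frames' uncertainties: 2·s²/n̄_pc.
    Because s² rests on only a handful of control wells (two or three per
    plate), its 95% χ² upper confidence bound is used rather than the point
    estimate; the bound tightens toward s² as control degrees of freedom
    accumulate.
    """
    from scipy import stats as _st

    ss = 0.0
    dof = 0
    counts = []
    for plate, vals in shifted.pc_well_shifts.items():
        counts.append(len(vals))
        if len(vals) >= 2:
            v = np.asarray(vals, dtype=float)
            ss += ((v - v.mean()) ** 2).sum()
            dof += len(v) - 1
    if dof == 0 or not counts:
        return 0.0
    s2_ucb = ss / float(_st.chi2.ppf(0.05, dof))
    n_bar = float(np.mean(counts))
    return float(np.sqrt(2.0 * s2_ucb / n_bar))


def _shift_sensitivities(
    anckg: Dict[str, DerivativeCurve], labels: Sequence[str]
) -> Dict[str, np.ndarray]:
    """∂v/∂(temperature shift) per genotype, by central finite difference.

    The derivative says how a genotype's spherical feature vector moves when
    an entire plate is displaced coherently along the temperature axis —
    the direction in which residual plate-alignment error perturbs clusters.
    """
    out: Dict[str, np.ndarray] = {}
    for g in labels:
        c = anckg[g]
        t = c.temperatures
        h = c.grid_step
        v_side = []
        for sign in (+1, -1):
            shifted_vals = np.interp(t, t + sign * h, c.values)
            r = np.array(
                [float(np.corrcoef(shifted_vals, anckg[j].values)[0, 1]) for j in labels]
            )
            v_side.append(spherical_transform(r))
        out[g] = (v_side[0] - v_side[1]) / (2 * h)
    return out


def _fit_model_for_range(
    shifted: ShiftedCurves,
    training_keys_by_label: Dict[str, List[WellKey]],
    labels: List[str],
    t_range: Tuple[float, float],
    config: PreprocessConfig,
    priors: Optional[Dict[str, float]],
    posterior_min: float,
    ellipsoid_coverage: float,
) -> Tuple[GenotypeModel, Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Fit ANCKGs, features and per-genotype Gaussians on one temperature range.

    The fitted covariance of each genotype is augmented with the propagated
    plate-frame uncertainty, C_i ← C_i + σ_frame²·g_i g_iᵀ, where g_i is the
    genotype's feature sensitivity to a coherent temperature displacement and
    σ_frame is estimated from the positive-control shift scatter. Training
    curves all share one plate frame, so their sample covariance cannot see
    this error source — yet every future plate carries an independent frame
    residual; without the augmentation, typical curves from a slightly
    misaligned plate would fail the coverage gate.
    """
    anckg, r_vectors, v_vectors = _features_for_range(
        shifted, training_keys_by_label, labels, t_range
    )
    fitted = fit_genotype_distributions(v_vectors)
    sigma_f = frame_sigma(shifted)
    cov = {g: fitted[g][1] for g in labels}
    if sigma_f > 0:
        sens = _shift_sensitivities(anckg, labels)
        cov = {g: cov[g] + sigma_f**2 * np.outer(sens[g], sens[g]) for g in labels}
    if priors is None:
        priors_out = {g: 1.0 / len(labels) for g in labels}
    else:
        total = sum(priors.values())
        priors_out = {g: p / total for g, p in priors.items()}
    model = GenotypeModel(
        labels=labels,
        anckg=anckg,
        mu={g: fitted[g][0] for g in labels},
        cov=cov,
        n_train={g: len(training_keys_by_label[g]) for g in labels},
        priors=priors_out,
        t_range=tuple(t_range),
        reference_pc=shifted.reference_pc,
        preprocess=config,
        posterior_min=posterior_min,
        ellipsoid_coverage=ellipsoid_coverage,
        ridge={g: fitted[g][2] for g in labels},
    )
    return model, r_vectors, v_vectors


def train_with_details(
    dataset: MeltDataset,
    config: Optional[PreprocessConfig] = None,
    priors: Optional[Dict[str, float]] = None,
    posterior_min: float = 0.995,
    ellipsoid_coverage: float = 0.9999,
    range_search=None,
    seed: int = 0,
) -> TrainingResult:
    """Run the full training procedure; see :func:`train_model`."""
    config = config or PreprocessConfig()
    dataset.validate_join()

    training_keys_by_label: Dict[str, List[WellKey]] = {}
    for key, m in dataset.meta.items():
        if m.role == Role.TRAINING and key in dataset.traces:
            training_keys_by_label.setdefault(m.genotype_label, []).append(key)
    labels = sorted(training_keys_by_label)
    if len(labels) < 2:
        raise MetadataError(
            f"training requires at least 2 genotypes, found {labels or 'none'}"
        )

    shifted = shift_dataset(dataset, config)

    if config.classification_range == "auto":
        from .mc_opt import RangeSearchConfig, optimize_temperature_range

        search = range_search or RangeSearchConfig(seed=seed)
        result = optimize_temperature_range(
            dataset,
            config,
            search,
            priors=priors,
            posterior_min=posterior_min,
            ellipsoid_coverage=ellipsoid_coverage,
            _shifted=shifted,
        )
        t_range = (result.t_start, result.t_end)
    else:
        t_range = tuple(config.classification_range)

    model, r_vectors, v_vectors = _fit_model_for_range(
        shifted, training_keys_by_label, labels, t_range, config,
        priors, posterior_min, ellipsoid_coverage,
    )
    return TrainingResult(
        model=model,
        r_vectors=r_vectors,
        v_vectors=v_vectors,
        shifts=shifted.shifts,
        well_order=training_keys_by_label,
    )


def train_model(
    dataset: MeltDataset,
    config: Optional[PreprocessConfig] = None,
    priors: Optional[Dict[str, float]] = None,
    posterior_min: float = 0.995,
    ellipsoid_coverage: float = 0.9999,
    range_search=None,
    seed: int = 0,
) -> GenotypeModel:
    """Build a GenotypeModel from a training dataset of known genotypes.

    Runs the preprocessing pipeline (with per-plate temperature shifts against
    the first training plate's averaged positive control), resolves the
    classification temperature range ("auto" delegates to the Monte Carlo
    range optimizer), computes ANCKGs and spherical feature vectors, and fits
    an independent Gaussian (μ_i, C_i) per genotype. Priors default to uniform.
    """
    return train_with_details(
        dataset,
        config=config,
        priors=priors,
        posterior_min=posterior_min,
        ellipsoid_coverage=ellipsoid_coverage,
        range_search=range_search,
        seed=seed,
    ).model


# ---------------------------------------------------------------------------
# training diagnostic: normality of the spherical parameters


def normality_report(result: TrainingResult, min_n: int = 8):
    """Shapiro-Wilk normality p-values for every feature, per genotype.

    Reports both the spherical parameters (l, a_1, …) and the raw correlations
    (r_1, …): within a genotype the raw correlations are skewed and bounded
    while their spherical transform is approximately normal — the contrast
    that justifies the Gaussian class-conditional model. Groups with fewer
    than ``min_n`` vectors are flagged insufficient rather than tested.
    """
    import pandas as pd

    model = result.model
    rows = []
    for g in model.labels:
        V = result.v_vectors[g]
        R = result.r_vectors[g]
        names = ["l"] + [f"a{k}" for k in range(1, model.n_classes)]
        names += [f"r{k}" for k in range(1, model.n_classes + 1)]
        data = np.hstack([V, R])
        for j, name in enumerate(names):
            x = data[:, j]
            if len(x) < min_n:
                rows.append(
                    {"genotype": g, "parameter": name, "n": len(x),
                     "statistic": np.nan, "p_value": np.nan, "insufficient": True}
                )
                continue
            if np.ptp(x) == 0:
                stat, p = np.nan, np.nan
            else:
                stat, p = stats.shapiro(x)
            rows.append(
                {"genotype": g, "parameter": name, "n": len(x),
                 "statistic": stat, "p_value": p, "insufficient": False}
            )
    return pd.DataFrame(rows)
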