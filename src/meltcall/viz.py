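"""2D cluster visualization of melt curves.

Each curve's correlation vector r (restricted to three basis genotypes) is
projected onto a symmetric tri-axis layout: unit axis directions at 90°, 210°
and 330°, point = Σ_i r_i·u_i. A curve perfectly correlated with one ANCKG
and uncorrelated with the others lands exactly on that genotype's axis tip at
distance 1 — the axes mark the maximum-correlation boundaries — and a curve
equally correlated with all three sits at the origin (the three axis
directions sum to zero). Training-set coverage ellipses are produced by Monte
Carlo propagation of each genotype's fitted Gaussian through the inverse
spherical transform and the projection (honest about the nonlinearity, and
exact in the small-variance limit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .classify import GenotypeCall
from .train import GenotypeModel, inverse_spherical

#: axis directions (degrees) for the three basis genotypes
TRI_AXIS_ANGLES_DEG = (90.0, 210.0, 330.0)

#: called-genotype palette by label position (wild type, heterozygote,
#: homozygote by convention); no-calls are gray
DEFAULT_PALETTE = ("#2ca02c", "#1f77b4", "#d62728")
NO_CALL_COLOR = "#808080"


def axis_vectors() -> np.ndarray:
    """(3, 2) unit vectors of the tri-axis layout."""
    ang = np.deg2rad(TRI_AXIS_ANGLES_DEG)
    return np.stack([np.cos(ang), np.sin(ang)], axis=1)


def project_point(r: np.ndarray, basis_idx: Optional[Sequence[int]] = None) -> np.ndarray:
    """Project one correlation vector (restricted to 3 basis components) to 2D."""
    return project_points(np.atleast_2d(r), basis_idx)[0]


def project_points(R: np.ndarray, basis_idx: Optional[Sequence[int]] = None) -> np.ndarray:
    """Project (n, ·) correlation vectors to (n, 2) tri-axis coordinates.

    The projection is linear in r, so affine fluorescence rescaling of a
    curve (which leaves r unchanged) does not move its point.
    """
    R = np.atleast_2d(np.asarray(R, dtype=float))
    if basis_idx is not None:
        R = R[:, list(basis_idx)]
    if R.shape[1] != 3:
        raise ValueError("tri-axis projection needs exactly 3 basis correlations")
    return R @ axis_vectors()


@dataclass
class EllipseSpec:
    """One genotype's training-coverage ellipse in projection coordinates."""

    label: str
    center: np.ndarray  # (2,)
    semi_axes: Tuple[float, float]  # (major, minor)
    angle_deg: float  # rotation of the major axis
    coverage: float


@dataclass
class ClusterPlotSpec:
    """Everything needed to draw (or export) a cluster plot."""

    axis_labels: Tuple[str, str, str]
    points: pd.DataFrame  # columns: plate, well, sample, x, y, call, color
    ellipses: List[EllipseSpec]


def training_ellipses(
    model: GenotypeModel,
    basis: Optional[Sequence[str]] = None,
    coverage: float = 0.95,
    n_mc: int = 10_000,
    seed: int = 0,
) -> List[EllipseSpec]:
    """Coverage ellipses of the training distributions in projection space.

    For each genotype, n_mc spherical vectors are sampled from N(μ_i, C_i),
    mapped back to correlation space, projected, and summarized by a 2D
    Gaussian whose χ²₂ coverage quantile gives the ellipse. Deterministic for
    a fixed seed. A degenerate (near-zero) covariance collapses the ellipse
    onto the projected mean.
    """
    basis = list(basis) if basis is not None else list(model.labels[:3])
    if len(basis) != 3:
        raise ValueError("choose exactly 3 basis genotypes for the tri-axis layout")
    basis_idx = [model.labels.index(g) for g in basis]
    q = float(stats.chi2.ppf(coverage, df=2))
    out: List[EllipseSpec] = []
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xE1]))
    for g in model.labels:
        V = rng.multivariate_normal(model.mu[g], model.cov[g], size=n_mc, method="cholesky")
        R = np.stack([inverse_spherical(v) for v in V])
        P = project_points(R, basis_idx)
        center = P.mean(axis=0)
        C = np.cov(P, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(np.atleast_2d(C))
        evals = np.clip(evals, 0.0, None)
        # eigh returns ascending order; major axis last
        semi = (float(np.sqrt(q * evals[1])), float(np.sqrt(q * evals[0])))
        angle = float(np.degrees(np.arctan2(evecs[1, 1], evecs[0, 1])))
        out.append(EllipseSpec(label=g, center=center, semi_axes=semi,
                               angle_deg=angle, coverage=coverage))
    return out


def build_plot_spec(
    calls: Sequence[GenotypeCall],
    model: GenotypeModel,
    basis: Optional[Sequence[str]] = None,
    coverage: float = 0.95,
    n_mc: int = 10_000,
    seed: int = 0,
    palette: Sequence[str] = DEFAULT_PALETTE,
) -> ClusterPlotSpec:
    """Assemble projected points (colored by call) and training ellipses."""
    basis = list(basis) if basis is not None else list(model.labels[:3])
    basis_idx = [model.labels.index(g) for g in basis]
    color_of = {g: palette[i % len(palette)] for i, g in enumerate(model.labels)}
    rows = []
    for c in calls:
        if c.r is None:
            raise ValueError(
                f"call for {c.plate_id}/{c.well_id} carries no correlation vector; "
                "classify from curves (not bare feature vectors) to visualize"
            )
        x, y = project_point(np.asarray(c.r), basis_idx)
        rows.append(
            {
                "plate": c.plate_id,
                "well": c.well_id,
                "sample": c.sample_id,
                "x": float(x),
                "y": float(y),
                "call": c.call if c.call is not None else "NO_CALL",
                "color": color_of[c.call] if c.call is not None else NO_CALL_COLOR,
            }
        )
    points = pd.DataFrame(
        rows, columns=["plate", "well", "sample", "x", "y", "call", "color"]
    )
    ellipses = training_ellipses(model, basis=basis, coverage=coverage,
                                 n_mc=n_mc, seed=seed)
    return ClusterPlotSpec(axis_labels=tuple(basis), points=points, ellipses=ellipses)


def render_cluster_plot(spec: ClusterPlotSpec, path) -> None:
    """Draw the tri-axis cluster plot to a static image (PNG/SVG by suffix)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    fig, ax = plt.subplots(figsize=(6, 6))
    U = axis_vectors()
    for (ux, uy), label in zip(U, spec.axis_labels):
        ax.plot([0, ux], [0, uy], color="0.3", lw=1, zorder=1)
        ax.annotate(label, (1.12 * ux, 1.12 * uy), ha="center", va="center")
    for e in spec.ellipses:
        ax.add_patch(
            Ellipse(
                xy=e.center,
                width=2 * e.semi_axes[0],
                height=2 * e.semi_axes[1],
                angle=e.angle_deg,
                fill=False,
                edgecolor="0.15",
                lw=1.2,
                zorder=2,
            )
        )
        ax.annotate(e.label, e.center, fontsize=8, ha="center", va="bottom",
                    xytext=(0, 4), textcoords="offset points")
    if len(spec.points):
        for call, grp in spec.points.groupby("call", sort=False):
            ax.scatter(grp["x"], grp["y"], s=14, c=grp["color"].iloc[0],
                       label=call, zorder=3, alpha=0.8)
        ax.legend(loc="lower right", fontsize=8)
    lim = 1.35
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title("Melt-curve genotype clusters (tri-axis correlation projection)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
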