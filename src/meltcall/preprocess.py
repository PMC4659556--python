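"""Raw melt traces -> normalized negative-derivative curves.

The preprocessing pipeline runs in a fixed order:

    resample -> Savitzky-Golay derivative -> plate temperature shift
             -> range restriction -> zero-mean/unit-sd normalization

Resampling puts every well on a uniform temperature lattice (multiples of
``grid_step``), the Savitzky-Golay first-derivative filter produces −dF/dT,
positive-control wells estimate one corrective temperature shift per plate
(instruments report biased temperatures run-to-run), and the final
normalization makes downstream correlations invariant to fluorescence gain
and offset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    DegenerateCurveError,
    GridMismatchError,
    MissingControlsError,
    RangeError,
    TraceTooShortError,
)

#: tolerance (in grid steps) used when snapping temperatures to the lattice
_LATTICE_TOL = 1e-6

WellKey = Tuple[str, str]  # (plate_id, well_id)


@dataclass
class GriddedTrace:
    """Fluorescence resampled onto a uniform temperature grid."""

    grid_start: float
    grid_step: float
    fluorescence: np.ndarray
    well_ref: Optional[WellKey] = None

    @property
    def temperatures(self) -> np.ndarray:
        return self.grid_start + self.grid_step * np.arange(len(self.fluorescence))


@dataclass
class DerivativeCurve:
    """A −dF/dT curve on a uniform grid.

    ``applied_shift`` records the plate temperature correction already folded
    into ``grid_start``; ``stages`` records the pipeline stages the curve has
    passed through, in order.
    """

    grid_start: float
    grid_step: float
    values: np.ndarray
    well_ref: Optional[WellKey] = None
    applied_shift: float = 0.0
    stages: Tuple[str, ...] = ("resample", "derivative")

    @property
    def temperatures(self) -> np.ndarray:
        return self.grid_start + self.grid_step * np.arange(len(self.values))

    @property
    def grid_end(self) -> float:
        return self.grid_start + self.grid_step * (len(self.values) - 1)

    def same_grid(self, other: "DerivativeCurve") -> bool:
        return (
            len(self.values) == len(other.values)
            and math.isclose(self.grid_step, other.grid_step, rel_tol=1e-12)
            and abs(self.grid_start - other.grid_start) < self.grid_step * _LATTICE_TOL
        )


@dataclass
class PreprocessConfig:
    """Tunable preprocessing parameters.

    grid_step
        Resampling interval in °C. 0.05 matches 20 acquisitions per degree,
        the densest acquisition used by the assays this tool targets.
    savgol_window
        Width in °C of the Savitzky-Golay derivative filter window.
    savgol_polyorder
        Local polynomial order of the filter (2 = exact for quadratics).
    shift_search_halfwidth
        Exhaustive plate-shift search covers ±this many °C on the grid.
    classification_range
        (t_start, t_end) in °C, or "auto" to delegate range selection to the
        Monte Carlo misclassification-rate optimizer.
    """

    grid_step: float = 0.05
    savgol_window: float = 1.0
    savgol_polyorder: int = 2
    shift_search_halfwidth: float = 5.0
    classification_range: Union[str, Tuple[float, float]] = "auto"

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        if self.savgol_window_points() < self.savgol_polyorder + 2:
            raise ValueError(
                "savgol_window must span at least polyorder+2 grid points "
                f"(window {self.savgol_window}°C at step {self.grid_step}°C spans "
                f"{self.savgol_window_points()})"
            )
        if self.classification_range != "auto":
            t0, t1 = self.classification_range
            if not t0 < t1:
                raise ValueError("classification_range must satisfy t_start < t_end")

    def savgol_window_points(self) -> int:
        """Odd point count of the derivative filter window."""
        return 2 * int(math.floor(self.savgol_window / (2 * self.grid_step))) + 1


# ---------------------------------------------------------------------------
# stage 1: resampling


def resample_uniform(
    temperatures: Sequence[float],
    fluorescence: Sequence[float],
    grid_step: float,
    well_ref: Optional[WellKey] = None,
) -> GriddedTrace:
    """Linearly interpolate a raw trace onto the uniform lattice.

    The output grid is ceil(Tmin/step)*step … floor(Tmax/step)*step so no
    point requires extrapolation. Linear interpolation is used deliberately:
    it is monotone and cannot overshoot near sharp melt transitions.
    """
    t = np.asarray(temperatures, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    if t.size < 2:
        raise TraceTooShortError(f"trace {well_ref}: need at least 2 points, got {t.size}")
    if not np.all(np.diff(t) > 0):
        raise ValueError(f"trace {well_ref}: temperatures must be strictly increasing")
    i0 = int(math.ceil(t[0] / grid_step - _LATTICE_TOL))
    i1 = int(math.floor(t[-1] / grid_step + _LATTICE_TOL))
    if i1 < i0 + 1:
        raise TraceTooShortError(
            f"trace {well_ref}: span {t[0]}–{t[-1]}°C too short for grid step {grid_step}"
        )
    grid = np.arange(i0, i1 + 1) * grid_step
    vals = np.interp(grid, t, f)
    return GriddedTrace(grid_start=i0 * grid_step, grid_step=grid_step,
                        fluorescence=vals, well_ref=well_ref)


# ---------------------------------------------------------------------------
# stage 2: negative Savitzky-Golay derivative


def neg_derivative_savgol(
    trace: GriddedTrace, window_deg: float = 1.0, polyorder: int = 2
) -> DerivativeCurve:
    """−dF/dT via a Savitzky-Golay first-derivative FIR filter.

    The window is converted to an odd point count on the grid. Edge points are
    obtained by fitting the same-order polynomial to the one-sided window (the
    filter's interpolating edge mode), so the curve keeps its full length —
    edges are usually discarded later by the range restriction anyway.
    """
    step = trace.grid_step
    w = 2 * int(math.floor(window_deg / (2 * step))) + 1
    if w < polyorder + 2:
        raise ValueError(
            f"Savitzky-Golay window of {window_deg}°C spans only {w} points at "
            f"step {step}°C; need at least polyorder+2 = {polyorder + 2}"
        )
    if len(trace.fluorescence) < w:
        raise TraceTooShortError(
            f"trace {trace.well_ref}: {len(trace.fluorescence)} points < filter window {w}"
        )
    deriv = savgol_filter(trace.fluorescence, window_length=w, polyorder=polyorder,
                          deriv=1, delta=step, mode="interp")
    return DerivativeCurve(
        grid_start=trace.grid_start,
        grid_step=step,
        values=-deriv,
        well_ref=trace.well_ref,
        applied_shift=0.0,
        stages=("resample", "derivative"),
    )


# ---------------------------------------------------------------------------
# lattice helpers


def _lattice_index(curve: DerivativeCurve) -> int:
    idx = curve.grid_start / curve.grid_step
    snapped = round(idx)
    if abs(idx - snapped) > _LATTICE_TOL:
        raise GridMismatchError(
            f"curve {curve.well_ref} grid_start {curve.grid_start} is not on the "
            f"{curve.grid_step}°C lattice"
        )
    return int(snapped)


def average_curves(curves: Sequence[DerivativeCurve]) -> DerivativeCurve:
    """Pointwise mean of lattice-aligned curves over their common overlap."""
    if not curves:
        raise ValueError("no curves to average")
    step = curves[0].grid_step
    starts = [_lattice_index(c) for c in curves]
    ends = [s + len(c.values) - 1 for s, c in zip(starts, curves)]
    lo, hi = max(starts), min(ends)
    if hi < lo:
        raise GridMismatchError("curves to average have no overlapping grid points")
    stack = np.stack([c.values[lo - s : hi - s + 1] for s, c in zip(starts, curves)])
    return DerivativeCurve(
        grid_start=lo * step,
        grid_step=step,
        values=stack.mean(axis=0),
        well_ref=None,
        applied_shift=0.0,
        stages=curves[0].stages,
    )


# ---------------------------------------------------------------------------
# stage 3: plate temperature shifting


def compute_plate_shift(
    plate_pc_curves: Sequence[DerivativeCurve],
    reference: DerivativeCurve,
    config: PreprocessConfig,
    refine: bool = True,
) -> float:
    """Corrective shift (°C) aligning a plate's averaged positive control to the reference.

    The plate's positive-control derivative curves are averaged pointwise and
    the Pearson correlation with the reference curve is evaluated for every
    candidate shift on the grid within ±shift_search_halfwidth. The argmax is
    returned; exact ties break toward the smallest |shift|, then toward the
    negative shift. Candidates whose post-shift overlap with the reference is
    under 1°C are excluded.

    With ``refine`` (the default), the discrete argmax is sharpened by fitting
    a parabola through the correlation at the winning shift and its two grid
    neighbours and returning the vertex (clamped to ±step/2 around the
    winner). Grid-quantized shifts leave a residual of up to half a grid step
    that displaces an entire plate coherently relative to the training
    clusters; sub-grid refinement removes it. Set ``refine=False`` for the
    purely discrete search.
    """
    if not plate_pc_curves:
        raise MissingControlsError(
            "plate has no positive-control wells; temperature shifting requires at "
            "least one positive control per plate (without it, inter-plate "
            "temperature bias produces systematic miscalls)"
        )
    step = config.grid_step
    avg = average_curves(list(plate_pc_curves))
    a0 = _lattice_index(avg)
    r0 = _lattice_index(reference)
    a1 = a0 + len(avg.values) - 1
    r1 = r0 + len(reference.values) - 1
    k_max = int(round(config.shift_search_halfwidth / step))
    min_overlap_pts = int(round(1.0 / step)) + 1

    best: Optional[Tuple[float, float, float]] = None  # (-corr_rounded, |s|, s)
    best_shift: Optional[float] = None
    best_k: Optional[int] = None
    corr_by_k: Dict[int, float] = {}
    for k in range(-k_max, k_max + 1):
        lo = max(a0 + k, r0)
        hi = min(a1 + k, r1)
        if hi - lo + 1 < min_overlap_pts:
            continue
        x = avg.values[lo - (a0 + k) : hi - (a0 + k) + 1]
        y = reference.values[lo - r0 : hi - r0 + 1]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        corr = float(np.corrcoef(x, y)[0, 1])
        corr_by_k[k] = corr
        s = k * step
        key = (-round(corr, 12), abs(s), s)
        if best is None or key < best:
            best = key
            best_shift = s
            best_k = k
    if best_shift is None or best_k is None:
        raise RangeError(
            "no candidate shift leaves at least 1°C of overlap with the reference "
            "positive control"
        )
    if refine:
        ks = [k for k in range(best_k - 4, best_k + 5) if k in corr_by_k]
        if len(ks) >= 5:
            kk = np.array(ks, dtype=float) - best_k
            cc = np.array([corr_by_k[k] for k in ks])
            a, b, _c = np.polyfit(kk, cc, 2)
            if a < 0:  # proper maximum
                frac = float(np.clip(-b / (2 * a), -1.0, 1.0))
                best_shift = (best_k + frac) * step
    return best_shift


def apply_shift(curve: DerivativeCurve, shift: float) -> DerivativeCurve:
    """Relabel the temperature axis by ``shift`` °C; values are untouched."""
    return replace(
        curve,
        grid_start=curve.grid_start + shift,
        applied_shift=curve.applied_shift + shift,
        stages=curve.stages + ("shift",) if "shift" not in curve.stages else curve.stages,
        values=curve.values.copy(),
    )


def apply_shift_lattice(curve: DerivativeCurve, shift: float) -> DerivativeCurve:
    """Shift a curve and keep it on the canonical grid lattice.

    A shift that is a whole number of grid steps is a pure relabeling; a
    sub-grid shift additionally linearly interpolates the values back onto
    the lattice so that curves from different plates stay point-aligned.
    """
    step = curve.grid_step
    k = shift / step
    if abs(k - round(k)) < _LATTICE_TOL:
        return apply_shift(curve, round(k) * step)
    t_shifted = curve.temperatures + shift
    i0 = int(math.ceil(t_shifted[0] / step - _LATTICE_TOL))
    i1 = int(math.floor(t_shifted[-1] / step + _LATTICE_TOL))
    grid = np.arange(i0, i1 + 1) * step
    vals = np.interp(grid, t_shifted, curve.values)
    return replace(
        curve,
        grid_start=i0 * step,
        values=vals,
        applied_shift=curve.applied_shift + shift,
        stages=curve.stages + ("shift",) if "shift" not in curve.stages else curve.stages,
    )


# ---------------------------------------------------------------------------
# stage 4: range restriction


def restrict_range(curve: DerivativeCurve, t_start: float, t_end: float) -> DerivativeCurve:
    """Keep only grid points inside the closed interval [t_start, t_end]."""
    if t_start >= t_end:
        raise ValueError("t_start must be < t_end")
    t = curve.temperatures
    eps = curve.grid_step * _LATTICE_TOL
    mask = (t >= t_start - eps) & (t <= t_end + eps)
    n = int(mask.sum())
    if (n - 1) * curve.grid_step < 1.0 - eps:
        raise RangeError(
            f"well {curve.well_ref}: classification range [{t_start}, {t_end}]°C "
            f"overlaps the curve ({t[0]:.2f}–{t[-1]:.2f}°C) by less than 1°C"
        )
    idx = np.nonzero(mask)[0]
    return replace(
        curve,
        grid_start=float(t[idx[0]]),
        values=curve.values[idx[0] : idx[-1] + 1].copy(),
        stages=curve.stages + ("restrict",) if "restrict" not in curve.stages else curve.stages,
    )


# ---------------------------------------------------------------------------
# stage 5: normalization


def normalize(curve: DerivativeCurve) -> DerivativeCurve:
    """Scale values to zero mean and unit standard deviation (n−1 denominator).

    Idempotent, and invariant to affine fluorescence transforms with positive
    gain — the property that makes correlation features instrument-agnostic.
    """
    v = curve.values
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateCurveError(
            f"well {curve.well_ref}: constant derivative curve (flat melt = failed "
            "reaction); cannot normalize"
        )
    return replace(
        curve,
        values=(v - v.mean()) / sd,
        stages=curve.stages + ("normalize",) if "normalize" not in curve.stages else curve.stages,
    )


# ---------------------------------------------------------------------------
# dataset-level pipeline

from .melt_io import MeltDataset, Role  # noqa: E402  (no cycle: melt_io imports nothing from here)


@dataclass
class ShiftedCurves:
    """Per-well shifted derivative curves before range restriction."""

    curves: Dict[WellKey, DerivativeCurve]
    shifts: Dict[str, float]  # plate_id -> applied shift
    reference_pc: DerivativeCurve
    #: per-plate individual positive-control shift estimates (vs the reference);
    #: their within-plate scatter measures how precisely a plate's temperature
    #: frame can be known from its controls
    pc_well_shifts: Dict[str, List[float]] = field(default_factory=dict)


def derive_all(dataset: MeltDataset, config: PreprocessConfig) -> Dict[WellKey, DerivativeCurve]:
    """Resample + derivative for every well in the dataset."""
    out: Dict[WellKey, DerivativeCurve] = {}
    for key, trace in dataset.traces.items():
        gridded = resample_uniform(trace.temperatures, trace.fluorescence,
                                   config.grid_step, well_ref=key)
        out[key] = neg_derivative_savgol(gridded, config.savgol_window,
                                         config.savgol_polyorder)
    return out


def shift_dataset(
    dataset: MeltDataset,
    config: PreprocessConfig,
    reference_pc: Optional[DerivativeCurve] = None,
) -> ShiftedCurves:
    """Derivative curves for all wells, with one temperature shift per plate.

    If ``reference_pc`` is None the averaged positive control of the first
    plate (in order of appearance) becomes the reference, as in training;
    classification reuses the reference stored in the model.
    """
    curves = derive_all(dataset, config)
    plates = dataset.plate_order()
    pc_by_plate: Dict[str, List[DerivativeCurve]] = {p: [] for p in plates}
    for key, meta in dataset.meta.items():
        if meta.role == Role.POSITIVE_CONTROL and key in curves:
            pc_by_plate[meta.plate_id].append(curves[key])
    for p in plates:
        if not pc_by_plate[p]:
            raise MissingControlsError(
                f"plate {p} has no positive-control wells; temperature shifting "
                "requires at least one positive control per plate"
            )
    if reference_pc is None:
        reference_pc = average_curves(pc_by_plate[plates[0]])
    shifts: Dict[str, float] = {}
    pc_well_shifts: Dict[str, List[float]] = {}
    shifted: Dict[WellKey, DerivativeCurve] = {}
    for p in plates:
        shifts[p] = compute_plate_shift(pc_by_plate[p], reference_pc, config)
        pc_well_shifts[p] = [
            compute_plate_shift([pc], reference_pc, config) for pc in pc_by_plate[p]
        ]
    for key, curve in curves.items():
        shifted[key] = apply_shift_lattice(curve, shifts[dataset.meta[key].plate_id])
    return ShiftedCurves(curves=shifted, shifts=shifts, reference_pc=reference_pc,
                         pc_well_shifts=pc_well_shifts)


def finalize_curves(
    shifted: Dict[WellKey, DerivativeCurve], t_start: float, t_end: float
) -> Dict[WellKey, DerivativeCurve]:
    """Restrict every shifted curve to the classification range and normalize."""
    return {
        key: normalize(restrict_range(c, t_start, t_end)) for key, c in shifted.items()
    }


def preprocess_dataset(
    dataset: MeltDataset,
    config: PreprocessConfig,
    t_range: Tuple[float, float],
    reference_pc: Optional[DerivativeCurve] = None,
) -> Tuple[Dict[WellKey, DerivativeCurve], Dict[str, float], DerivativeCurve]:
    """Full pipeline: resample → derivative → shift → restrict → normalize."""
    sc = shift_dataset(dataset, config, reference_pc=reference_pc)
    final = finalize_curves(sc.curves, t_range[0], t_range[1])
    return final, sc.shifts, sc.reference_pc
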