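"""Synthetic multi-plate HRM datasets with known ground truth.

Melt transitions are modeled as logistic steps — the classifier is
deliberately model-agnostic, so the simulator only needs realistic transition
shapes, melting-temperature shifts between genotypes, heteroduplex second
peaks, a decaying background, inter-plate temperature bias, and measurement
noise:

    F(T) = intercept + slope·(T − δ) + Σ_j A_j · logistic((tm_j − (T − δ))/w_j) + ε

where δ is the plate's temperature offset (the instrument records biased
temperatures, so features appear at tm + δ and the preprocessing shift search
should recover −δ) and ε ~ N(0, noise_sd) independently per reading.
Heterozygotes carry two half-amplitude transitions at the two homozygote
melting temperatures, mirroring the heteroduplex double-peak signature.

Within-genotype cluster spread in real plates is dominated not by reading
noise but by smooth per-well effects — intra-plate thermal gradients shift a
well's apparent melting temperatures by a few hundredths of a degree, and
template-concentration differences scale the transition amplitude. The
simulator therefore draws, per well, a Tm jitter (shared by all of the
well's transitions) and a multiplicative amplitude factor in addition to the
per-reading Gaussian noise.

Three preconfigured assays cover the study conditions the pipeline is
validated against: a well-separated three-genotype assay, an overlapping
wild-type/homozygote assay that produces deliberate no-calls, and a
two-region snapback assay (low-temperature probe element plus amplicon).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import MissingControlsError
from .melt_io import MeltDataset, Role, Trace, WellKey, WellMeta


@dataclass(frozen=True)
class TransitionSpec:
    """One melt transition: amplitude · logistic((tm − T)/width)."""

    tm: float  # °C
    width: float  # °C, transition steepness scale
    amplitude: float  # fluorescence units

    def __post_init__(self) -> None:
        if not 0.1 <= self.width <= 5:
            raise ValueError(f"width {self.width} outside [0.1, 5]°C")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")


@dataclass(frozen=True)
class GenotypeSpec:
    """A genotype's melt signature (one or more transitions)."""

    label: str
    transitions: Tuple[TransitionSpec, ...]

    def __post_init__(self) -> None:
        if len(self.transitions) < 1:
            raise ValueError(f"genotype {self.label!r} needs at least one transition")


@dataclass
class PlateLayout:
    """Well plan for one simulated plate."""

    plate_id: str
    n_positive_controls: int = 3
    # (sample_id, genotype_label, n_replicates, role)
    samples: List[Tuple[str, str, int, Role]] = field(default_factory=list)


@dataclass
class AssaySimConfig:
    """Study conditions for a simulated assay.

    samples_per_degree defaults to 20 (dense small-amplicon acquisition); the
    snapback preset uses 10. The background is a linearly decaying dye
    baseline — the component the normalization is meant to absorb.
    Per-well random effects: ``well_tm_jitter_sd`` (°C) — apparent-Tm scatter
    from intra-plate thermal gradients, shared by a well's transitions;
    ``transition_tm_jitter_sd`` (°C) — small independent per-transition Tm
    scatter on top of it; ``well_amp_cv`` (relative) — amplitude scatter from
    template-concentration differences (removed by normalization, present for
    raw-data realism); ``well_width_cv`` (relative) — transition-steepness
    scatter (salt/buffer variation); ``well_bg_slope_sd`` — background-slope
    scatter (dye and volume differences), which does change normalized curve
    shape; ``well_drift_amp`` — amplitude (fluorescence units) of a smooth
    low-frequency per-well optical drift, modeled as ``drift_harmonics``
    random-phase cosines over the span. ``sample_tm_sd`` (°C) is a per-DNA-
    sample Tm effect shared by a sample's triplicate wells: salt and template
    concentration differences between preps shift apparent Tm by of order
    0.1°C. Positive controls are replicates of one control DNA prep, so this
    effect widens genotype clusters without degrading the positive-control
    temperature frame — as in real plates. Together these give
    within-genotype clusters full-rank covariance.
    """

    genotypes: List[GenotypeSpec]
    t_span: Tuple[float, float] = (55.0, 95.0)
    samples_per_degree: int = 20
    background: Tuple[float, float] = (150.0, -1.0)  # intercept, slope (<0)
    noise_sd: float = 3.0
    well_tm_jitter_sd: float = 0.02
    well_amp_cv: float = 0.05
    transition_tm_jitter_sd: float = 0.015
    well_width_cv: float = 0.05
    well_bg_slope_sd: float = 0.15
    well_drift_amp: float = 1.0
    drift_harmonics: int = 3
    well_skew_sd: float = 0.05
    sample_tm_sd: float = 0.02
    plate_offsets: Dict[str, float] = field(default_factory=dict)
    plates: List[PlateLayout] = field(default_factory=list)
    pc_genotype: Optional[str] = None  # defaults to the first genotype (wild type)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.t_span
        for g in self.genotypes:
            for tr in g.transitions:
                if not lo + 3 * tr.width <= tr.tm <= hi - 3 * tr.width:
                    raise ValueError(
                        f"{g.label}: tm {tr.tm}°C too close to the span edge "
                        f"({lo}–{hi}°C, width {tr.width}°C)"
                    )
        if self.pc_genotype is None:
            self.pc_genotype = self.genotypes[0].label

    def genotype(self, label: str) -> GenotypeSpec:
        for g in self.genotypes:
            if g.label == label:
                return g
        raise KeyError(label)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def simulate_curve(
    genotype_spec: GenotypeSpec,
    config: AssaySimConfig,
    rng: np.random.Generator,
    plate_offset: float = 0.0,
    sample_tm_offset: float = 0.0,
) -> Trace:
    """One raw melt trace for a genotype on a plate with temperature bias δ.

    The recorded grid spans ``t_span``; fluorescence is evaluated at the true
    temperature T − δ, so every feature appears δ later on the recorded axis.
    Per-well random effects (Tm jitter shared by all transitions, one
    multiplicative amplitude factor) are drawn before the per-reading noise.
    """
    lo, hi = config.t_span
    n = int(round((hi - lo) * config.samples_per_degree)) + 1
    t = np.linspace(lo, hi, n)
    true_t = t - plate_offset
    dtm = rng.normal(0.0, config.well_tm_jitter_sd) if config.well_tm_jitter_sd > 0 else 0.0
    amp = float(np.exp(rng.normal(0.0, config.well_amp_cv))) if config.well_amp_cv > 0 else 1.0
    wfac = float(np.exp(rng.normal(0.0, config.well_width_cv))) if config.well_width_cv > 0 else 1.0
    intercept, slope = config.background
    slope = slope + (rng.normal(0.0, config.well_bg_slope_sd) if config.well_bg_slope_sd > 0 else 0.0)
    f = intercept + slope * true_t
    skew = rng.normal(0.0, config.well_skew_sd) if config.well_skew_sd > 0 else 0.0
    for tr in genotype_spec.transitions:
        dtr = rng.normal(0.0, config.transition_tm_jitter_sd) if config.transition_tm_jitter_sd > 0 else 0.0
        w = tr.width * wfac
        x = tr.tm + sample_tm_offset + dtm + dtr - true_t
        # skew: transition slightly steeper on one flank than the other
        w_local = w * np.exp(skew * np.tanh(x / (2 * w)))
        f = f + amp * tr.amplitude * _logistic(x / w_local)
    if config.well_drift_amp > 0:
        span = hi - lo
        for h in range(1, config.drift_harmonics + 1):
            c = rng.normal(0.0, config.well_drift_amp / h)
            phi = rng.uniform(0.0, 2 * np.pi)
            f = f + c * np.cos(2 * np.pi * h * (true_t - lo) / span + phi)
    if config.noise_sd > 0:
        f = f + rng.normal(0.0, config.noise_sd, size=n)
    return Trace(temperatures=t, fluorescence=f)


def _well_ids(n: int) -> List[str]:
    rows = "ABCDEFGHIJKLMNOP"
    out = []
    for i in range(n):
        out.append(f"{rows[i // 24]}{i % 24 + 1}")
    return out


def simulate_dataset(config: AssaySimConfig) -> Tuple[MeltDataset, pd.DataFrame]:
    """Simulate every plate of the assay; returns the dataset and a truth table.

    Positive controls are drawn from ``pc_genotype`` (wild-type DNA by
    default). The truth table has one row per well: plate, well, sample,
    role, true genotype — the simulated analog of sequencing ground truth.
    """
    if not config.plates:
        raise ValueError("config.plates is empty")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0x5E]))
    ds = MeltDataset()
    truth_rows = []
    for layout in config.plates:
        if layout.n_positive_controls < 1:
            raise MissingControlsError(
                f"plate {layout.plate_id}: layout must include at least one "
                "positive-control well"
            )
        offset = config.plate_offsets.get(layout.plate_id, 0.0)
        n_wells = layout.n_positive_controls + sum(n for _, _, n, _ in layout.samples)
        ids = _well_ids(n_wells)
        cursor = 0
        pc_spec = config.genotype(config.pc_genotype)
        for j in range(layout.n_positive_controls):
            wid = ids[cursor]
            cursor += 1
            key = (layout.plate_id, wid)
            ds.traces[key] = simulate_curve(pc_spec, config, rng, offset)
            ds.meta[key] = WellMeta(
                well_id=wid, plate_id=layout.plate_id, sample_id=f"PC{j + 1:02d}",
                role=Role.POSITIVE_CONTROL,
            )
            truth_rows.append(
                {"plate": layout.plate_id, "well": wid, "sample": f"PC{j + 1:02d}",
                 "role": Role.POSITIVE_CONTROL.value, "genotype": config.pc_genotype}
            )
        for sample_id, genotype, n_rep, role in layout.samples:
            spec = config.genotype(genotype)
            # one prep-level Tm offset per DNA sample, shared by its triplicate
            dtm_sample = (
                rng.normal(0.0, config.sample_tm_sd) if config.sample_tm_sd > 0 else 0.0
            )
            for _ in range(n_rep):
                wid = ids[cursor]
                cursor += 1
                key = (layout.plate_id, wid)
                ds.traces[key] = simulate_curve(spec, config, rng, offset, dtm_sample)
                ds.meta[key] = WellMeta(
                    well_id=wid, plate_id=layout.plate_id, sample_id=sample_id,
                    role=role,
                    genotype_label=genotype if role == Role.TRAINING else None,
                )
                truth_rows.append(
                    {"plate": layout.plate_id, "well": wid, "sample": sample_id,
                     "role": role.value, "genotype": genotype}
                )
    ds.validate_join()
    return ds, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# plate-plan helpers


def _training_plate(
    plate_id: str, labels: Sequence[str], n_samples: int = 32, n_rep: int = 3
) -> PlateLayout:
    """One training plate: n_samples DNA samples in triplicate, genotypes cycled."""
    samples = [
        (f"T{i + 1:02d}", labels[i % len(labels)], n_rep, Role.TRAINING)
        for i in range(n_samples)
    ]
    return PlateLayout(plate_id=plate_id, n_positive_controls=3, samples=samples)


def _validation_plate(
    plate_id: str, labels: Sequence[str], n_samples: int = 40, n_rep: int = 3
) -> PlateLayout:
    samples = [
        (f"S{i + 1:02d}", labels[i % len(labels)], n_rep, Role.UNKNOWN)
        for i in range(n_samples)
    ]
    return PlateLayout(plate_id=plate_id, n_positive_controls=3, samples=samples)


# ---------------------------------------------------------------------------
# preconfigured assays (the study conditions the pipeline is validated under)


def default_assay_config(seed: int = 0) -> AssaySimConfig:
    """Well-separated three-genotype small-amplicon assay.

    Homozygote melting temperatures 1.0°C apart (WT 79.0, HOM 80.0°C) with
    0.5°C-wide transitions; the heterozygote melts as two half-amplitude
    transitions at both homozygote temperatures. One training plate (32
    samples in triplicate = 96 training wells) and one validation plate (40
    samples in triplicate = 120 wells) with a +0.7°C injected temperature
    bias.
    """
    wt = GenotypeSpec("WT", (TransitionSpec(79.0, 0.5, 100.0),))
    het = GenotypeSpec(
        "HET", (TransitionSpec(79.0, 0.5, 50.0), TransitionSpec(80.0, 0.5, 50.0))
    )
    hom = GenotypeSpec("HOM", (TransitionSpec(80.0, 0.5, 100.0),))
    labels = ["WT", "HET", "HOM"]
    return AssaySimConfig(
        genotypes=[wt, het, hom],
        t_span=(55.0, 95.0),
        samples_per_degree=20,
        background=(150.0, -1.0),
        plate_offsets={"train1": 0.0, "val1": 0.7},
        plates=[_training_plate("train1", labels), _validation_plate("val1", labels)],
        seed=seed,
    )


def overlap_assay_config(seed: int = 0) -> AssaySimConfig:
    """Assay with overlapping wild-type and homozygote clusters.

    WT and HOM melting temperatures sit 0.15°C apart while the heterozygote
    (heteroduplex transition 1°C lower) stays well separated. The noise level
    is set so the WT/HOM cluster separation leaves a small between-cluster
    band: most curves are called confidently, curves falling between the two
    clusters are given deliberate no-calls rather than risky calls.
    """
    wt = GenotypeSpec("WT", (TransitionSpec(80.0, 0.5, 100.0),))
    het = GenotypeSpec(
        "HET", (TransitionSpec(79.0, 0.5, 50.0), TransitionSpec(80.1, 0.5, 50.0))
    )
    hom = GenotypeSpec("HOM", (TransitionSpec(80.15, 0.5, 100.0),))
    labels = ["WT", "HET", "HOM"]
    return AssaySimConfig(
        genotypes=[wt, het, hom],
        t_span=(55.0, 95.0),
        samples_per_degree=20,
        background=(150.0, -1.0),
        plate_offsets={"train1": 0.0, "val1": -0.3},
        plates=[_training_plate("train1", labels), _validation_plate("val1", labels)],
        seed=seed,
    )


def snapback_assay_config(seed: int = 0) -> AssaySimConfig:
    """Two-region snapback assay: probe element (59–66°C) plus amplicon (78–82°C).

    The probe region separates genotypes strongly (4°C apart); the amplicon
    region only weakly (0.15°C). Analyzing the combined range should
    therefore estimate a misclassification rate no worse than either region
    alone, and far better than the amplicon region by itself. Acquisition is
    10 samples per degree over 45–95°C.
    """
    wt = GenotypeSpec(
        "WT", (TransitionSpec(60.5, 0.6, 40.0), TransitionSpec(80.0, 0.5, 100.0))
    )
    het = GenotypeSpec(
        "HET",
        (
            TransitionSpec(60.5, 0.6, 20.0),
            TransitionSpec(64.5, 0.6, 20.0),
            TransitionSpec(80.0, 0.5, 50.0),
            TransitionSpec(80.15, 0.5, 50.0),
        ),
    )
    hom = GenotypeSpec(
        "HOM", (TransitionSpec(64.5, 0.6, 40.0), TransitionSpec(80.15, 0.5, 100.0))
    )
    labels = ["WT", "HET", "HOM"]
    return AssaySimConfig(
        genotypes=[wt, het, hom],
        t_span=(45.0, 95.0),
        samples_per_degree=10,
        background=(150.0, -1.0),
        plate_offsets={"train1": 0.0},
        plates=[_training_plate("train1", labels)],
        seed=seed,
    )


def narrowband_assay_config(seed: int = 0) -> AssaySimConfig:
    """Assay informative only near 78–82°C, flanked by pure-noise regions.

    With substantial noise, widening the analysis range past the melt region
    only dilutes the genotype signal, so the range optimizer should stay close
    to the informative window.
    """
    wt = GenotypeSpec("WT", (TransitionSpec(79.2, 0.5, 100.0),))
    het = GenotypeSpec(
        "HET", (TransitionSpec(79.2, 0.5, 50.0), TransitionSpec(80.2, 0.5, 50.0))
    )
    hom = GenotypeSpec("HOM", (TransitionSpec(80.2, 0.5, 100.0),))
    labels = ["WT", "HET", "HOM"]
    return AssaySimConfig(
        genotypes=[wt, het, hom],
        t_span=(60.0, 95.0),
        samples_per_degree=20,
        background=(150.0, -1.0),
        noise_sd=4.0,
        plate_offsets={"train1": 0.0},
        plates=[_training_plate("train1", labels)],
        seed=seed,
    )
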