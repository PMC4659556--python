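"""Monte Carlo misclassification estimation and temperature-range selection.

Given a trained model, the expected truth×call probability cross table is
estimated by drawing feature vectors from each genotype's fitted Gaussian
N(μ_i, C_i) in spherical space and running them through the classifier
(including both no-call gates). Its prior-weighted off-diagonal mass is the
expected misclassification rate — the objective the range optimizer
minimizes: every candidate temperature range is used to retrain the features
(ANCKG, μ_i, C_i) and the range with the lowest estimated misclassification
wins, with ties broken toward the widest range, then the lowest start.
"""

from __future__ import annotations

import math
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classify import classify_batch
from .errors import MeltError
from .melt_io import MeltDataset, NO_CALL, Role, WellKey
from .preprocess import PreprocessConfig, ShiftedCurves, shift_dataset
from .train import GenotypeModel, _fit_model_for_range

log = logging.getLogger(__name__)

EXCLUDE = "exclude"
COUNT_AS_ERROR = "count_as_error"


@dataclass
class CrossTable:
    """Truth × call probability table estimated by Monte Carlo.

    ``table[i, j]`` is the estimated probability that a melt curve whose true
    genotype is ``truth_labels[i]`` is called ``call_labels[j]``; the last
    call column is NO_CALL. Rows sum to 1 exactly (tally construction).
    """

    truth_labels: List[str]
    call_labels: List[str]  # truth labels + NO_CALL
    table: np.ndarray  # (k, k+1)
    n_per_class: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.table, index=self.truth_labels, columns=self.call_labels)


@dataclass
class MisclassSummary:
    rate: float
    no_call_rate: float
    policy: str


def simulate_cross_table(
    model: GenotypeModel, n_per_class: int = 10_000, seed: int = 0
) -> CrossTable:
    """Estimate the expected cross table by sampling each genotype's Gaussian.

    For each genotype, ``n_per_class`` vectors v ~ N(μ_i, C_i) are drawn with
    a seeded generator and classified against the model (posterior gate and
    coverage-ellipsoid gate included); the fraction of draws per outcome
    fills the row. Same seed + same model → bit-identical table.
    """
    labels = model.labels
    k = len(labels)
    mus = model.mu_matrix()
    covs = model.cov_stack()
    priors = model.prior_vector()
    table = np.zeros((k, k + 1))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xC0]))
    for i in range(k):
        V = rng.multivariate_normal(mus[i], covs[i], size=n_per_class, method="cholesky")
        res = classify_batch(V, mus, covs, priors, model.posterior_min,
                             model.ellipsoid_coverage,
                             n_train=np.array([model.n_train[g] for g in labels]))
        outcome = np.where(res.called, res.winner, k)  # k = NO_CALL column
        counts = np.bincount(outcome, minlength=k + 1)
        table[i] = counts / n_per_class
    return CrossTable(
        truth_labels=list(labels),
        call_labels=list(labels) + [NO_CALL],
        table=table,
        n_per_class=n_per_class,
        seed=int(seed),
    )


def misclassification_rate(
    ct: CrossTable,
    priors: Optional[Dict[str, float]] = None,
    no_call_policy: str = EXCLUDE,
) -> MisclassSummary:
    """Prior-weighted off-diagonal mass of the cross table.

    rate = Σ_i P(g_i) Σ_{j≠i, j≠NO_CALL} table[i, j]. The no-call rate is
    returned alongside; ``no_call_policy`` controls whether it is added to the
    objective (a no-call is not a misclassification clinically, so the default
    excludes it).
    """
    if no_call_policy not in (EXCLUDE, COUNT_AS_ERROR):
        raise ValueError(f"unknown no_call_policy {no_call_policy!r}")
    k = len(ct.truth_labels)
    if priors is None:
        p = np.full(k, 1.0 / k)
    else:
        p = np.array([priors[g] for g in ct.truth_labels], dtype=float)
        p = p / p.sum()
    off = 0.0
    nc = 0.0
    for i in range(k):
        row = ct.table[i]
        off += p[i] * (row[:k].sum() - row[i])
        nc += p[i] * row[k]
    rate = off + nc if no_call_policy == COUNT_AS_ERROR else off
    return MisclassSummary(rate=float(rate), no_call_rate=float(nc), policy=no_call_policy)


# ---------------------------------------------------------------------------
# temperature-range optimization


@dataclass
class RangeSearchConfig:
    """Exhaustive-grid search settings for the classification range.

    Candidate starts/ends default to a ``grid_spacing``-°C grid over the span
    the data actually covers; every pair at least ``min_width``°C wide is
    evaluated with ``n_mc`` Monte Carlo draws per genotype. Per-candidate
    seeds are derived from ``seed`` counter-style so candidates are
    comparable and the whole search is reproducible from one number.
    """

    grid_spacing: float = 1.0
    min_width: float = 2.0
    n_mc: int = 10_000
    seed: int = 0
    start_candidates: Optional[Sequence[float]] = None
    end_candidates: Optional[Sequence[float]] = None
    no_call_policy: str = EXCLUDE


@dataclass
class RangeSearchResult:
    t_start: float
    t_end: float
    misclass_rate: float
    no_call_rate: float
    diagnostics: pd.DataFrame  # t_start, t_end, misclass_rate, no_call_rate, status


def _candidate_grid(
    shifted: ShiftedCurves, keys: Sequence[WellKey], search: RangeSearchConfig
) -> Tuple[List[float], List[float]]:
    lo = max(shifted.curves[k].grid_start for k in keys)
    hi = min(shifted.curves[k].grid_end for k in keys)
    sp = search.grid_spacing
    starts = (
        list(search.start_candidates)
        if search.start_candidates is not None
        else list(np.arange(math.ceil(lo / sp) * sp, hi, sp))
    )
    ends = (
        list(search.end_candidates)
        if search.end_candidates is not None
        else list(np.arange(math.ceil(lo / sp) * sp, hi + 1e-9, sp))
    )
    starts = [s for s in starts if lo - 1e-9 <= s <= hi + 1e-9]
    ends = [e for e in ends if lo - 1e-9 <= e <= hi + 1e-9]
    return starts, ends


def optimize_temperature_range(
    dataset: MeltDataset,
    config: Optional[PreprocessConfig] = None,
    search: Optional[RangeSearchConfig] = None,
    priors: Optional[Dict[str, float]] = None,
    posterior_min: float = 0.995,
    ellipsoid_coverage: float = 0.9999,
    _shifted: Optional[ShiftedCurves] = None,
) -> RangeSearchResult:
    """Select the classification range minimizing estimated misclassification.

    For every candidate (t_start, t_end) the genotype features are refit on
    that range and the misclassification rate is estimated by Monte Carlo with
    a per-candidate seed derived from the master seed. Candidates where
    training fails (e.g. a degenerate curve on a flat region) are skipped and
    recorded, not fatal. Ties break toward the widest range, then the lowest
    start. Plate shifts are computed once on full-span positive controls and
    reused — they are range-independent.
    """
    config = config or PreprocessConfig()
    search = search or RangeSearchConfig()
    shifted = _shifted if _shifted is not None else shift_dataset(dataset, config)

    training_keys_by_label: Dict[str, List[WellKey]] = {}
    for key, m in dataset.meta.items():
        if m.role == Role.TRAINING and key in dataset.traces:
            training_keys_by_label.setdefault(m.genotype_label, []).append(key)
    labels = sorted(training_keys_by_label)
    all_keys = [k for keys in training_keys_by_label.values() for k in keys]

    starts, ends = _candidate_grid(shifted, all_keys, search)
    candidates = [
        (s, e)
        for s in starts
        for e in ends
        if e - s >= search.min_width - 1e-9
    ]
    if not candidates:
        raise MeltError("no candidate temperature ranges satisfy the width constraint")

    if priors is not None:
        total = sum(priors.values())
        priors = {g: p / total for g, p in priors.items()}

    rows = []
    best_key = None
    best: Optional[RangeSearchResult] = None
    for idx, (s, e) in enumerate(candidates):
        cand_seed = int(
            np.random.SeedSequence([int(search.seed) & 0x7FFFFFFF, idx]).generate_state(1)[0]
            & 0x7FFFFFFF
        )
        try:
            model, _r, _v = _fit_model_for_range(
                shifted, training_keys_by_label, labels, (s, e), config,
                priors, posterior_min, ellipsoid_coverage,
            )
        except MeltError as exc:
            log.info("range [%.2f, %.2f] skipped: %s", s, e, exc)
            rows.append({"t_start": s, "t_end": e, "misclass_rate": np.nan,
                         "no_call_rate": np.nan, "status": f"skipped: {exc}"})
            continue
        ct = simulate_cross_table(model, n_per_class=search.n_mc, seed=cand_seed)
        summary = misclassification_rate(ct, priors=model.priors,
                                         no_call_policy=search.no_call_policy)
        rows.append({"t_start": s, "t_end": e, "misclass_rate": summary.rate,
                     "no_call_rate": summary.no_call_rate, "status": "ok"})
        key = (round(summary.rate, 12), -(e - s), s)
        if best_key is None or key < best_key:
            best_key = key
            best = RangeSearchResult(
                t_start=s, t_end=e, misclass_rate=summary.rate,
                no_call_rate=summary.no_call_rate, diagnostics=pd.DataFrame(),
            )
    if best is None:
        raise MeltError("training failed on every candidate temperature range")
    best.diagnostics = pd.DataFrame(rows)
    return best
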