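# Methods

## Signal model and preprocessing

A melt trace is fluorescence F versus temperature T, acquired densely
(10–20 readings per °C) while the product melts. Genotype information lives
in the shape and position of the melt transition(s); everything else —
fluorescence gain, background decay, instrument temperature bias — is
nuisance. Preprocessing removes the nuisance in a fixed order:

1. **Resample** by linear interpolation onto a uniform grid (default
   0.05°C, matching 20 samples/°C). Linear interpolation is monotone and
   cannot overshoot at sharp transitions; the grid is the lattice
   `ceil(Tmin/step)·step … floor(Tmax/step)·step`, so no extrapolation.
2. **Derivative**: −dF/dT via a Savitzky–Golay first-derivative FIR filter,
   window 1°C, polynomial order 2 (exact for locally quadratic
   fluorescence). Edge points use the filter's interpolating edge mode;
   they are normally discarded by the later range restriction anyway.
3. **Plate temperature shift.** Instruments report biased temperatures that
   drift between runs, so each plate carries 2–3 positive-control wells
   (known wild-type DNA). The plate's averaged control derivative is slid
   against a reference control (the first training plate's average) over
   ±5°C on the grid; the correlation argmax, refined to sub-grid resolution
   by a least-squares parabola over ±4 grid steps, is the plate's
   corrective shift. Tie-breaks in the discrete search go to the smallest
   |shift|, then the negative one. Curves shifted by a sub-grid amount are
   linearly re-interpolated back onto the lattice so all plates stay
   point-aligned. Sub-grid refinement matters: a half-grid-step residual
   displaces every well of a plate coherently, which is a large systematic
   relative to within-genotype cluster spread.
4. **Restrict** to the classification window (closed interval), either
   configured or chosen by the range optimizer.
5. **Normalize** to zero mean, unit standard deviation (n−1 denominator).
   This makes all downstream features exactly invariant to per-well
   fluorescence gain and offset.

## Features and class-conditional model

Each normalized curve is Pearson-correlated with the Averaged Normalized
Curve of each Known Genotype (ANCKG — the per-genotype mean of training
curves, re-normalized), giving r ∈ [−1,1]^{N_c}. Within a genotype the
correlations crowd the upper boundary and are strongly skewed, so r is
mapped to hyperspherical coordinates v = (l, a_1, …, a_{N_c−1}) with
l = ‖r‖₂ and a_k = arctan(r_{k+1}/√(Σ_{j≤k} r_j²)); these are approximately
normal within a genotype (the test suite measures the Shapiro–Wilk
rejection rate at the nominal level on fresh simulated curves). The
single-argument arctangent cannot represent the sign of r₁; curves in the
assay's working range always correlate strongly positively with at least
one ANCKG, and pathological points are caught by the coverage gate. The map
is inverted (r₁ ≥ 0 branch) for Monte Carlo work and visualization.

Three estimation details depart from the most naive implementation, each
forced by triplicate-scale training sets (here 96 wells, ~32 per genotype):

* **Leave-one-out ANCKGs for training features.** A training curve's
  correlation with its own class average is computed against the average
  *excluding that curve*. Including it biases r upward and shrinks the
  fitted spread, so fresh curves of the same genotype would look like
  outliers to the coverage gate. The stored ANCKG used for unknowns remains
  the full-group mean.
* **Covariance ridge.** If a fitted C_i has condition number above 1e10 it
  receives a recorded diagonal ridge ε·trace(C)/N_c (ε starting at 1e-8),
  escalated until positive definite.
* **Plate-frame uncertainty propagation.** All training curves share one
  temperature frame, so their sample covariance cannot contain the
  frame-alignment error that every *future* plate carries. The per-well
  control shifts estimate the alignment noise s²; the operative
  plate-to-reference frame variance is σ_frame² = 2·s²_ucb/n̄_pc (a 95% χ²
  upper confidence bound, since s² rests on a handful of control wells).
  Each class covariance is augmented C_i ← C_i + σ_frame²·g_i g_iᵀ, where
  g_i = ∂v/∂shift is the class's feature sensitivity to a coherent
  temperature displacement (central finite difference of the shifted
  ANCKG's features). Without this term, a plate whose frame residual draws
  ~2σ produces a batch of spurious no-calls.

Class priors default to uniform (training panels are assembled to cover all
genotypes, not to match population frequency) and are configurable.

## Classification and no-call gates

Log-likelihoods use a Cholesky factorization (no explicit inverse);
posteriors are normalized in log space with max-subtraction, since the raw
Gaussian density underflows for distant points. A well is called as the
maximum-posterior genotype unless

* the winning posterior is below `posterior_min` (default 0.995) —
  `low_posterior`, the between-clusters case; or
* the winner's squared Mahalanobis distance exceeds the class's coverage
  quantile (default coverage 0.9999) — `outside_ellipsoid`, the
  far-from-everything case (failed reactions, unseen variants).

Both gates are always evaluated and recorded; `low_posterior` is reported
when both fail. The containment quantile for *classification* is the scaled-F
(Hotelling predictive) quantile d(n²−1)/(n(n−d))·F_{d,n−d}(coverage) with n
the class's training count: for parameters estimated from n curves this is
the exact coverage law for a fresh curve and is noticeably wider than χ²_d
at n ≈ 32 (36.7 vs 21.1 at coverage 0.9999, d = 3); it converges to χ² as
n → ∞. The standalone `containment()` helper keeps the plain χ² form for
the known-parameter case. Both thresholds are model fields, not constants.

## Monte Carlo error estimation and range selection

`simulate_cross_table` draws n vectors per genotype from the fitted
N(μ_i, C_i) with a seeded generator and runs them through the full
classifier (both gates), tallying a truth × call probability table whose
rows sum to 1 exactly; its prior-weighted off-diagonal mass is the expected
misclassification rate. No-calls are excluded from the objective by default
(a no-call is not a misclassification clinically); `count_as_error` is
available and is the right choice when comparing analysis ranges, because
ranges that resolve genotypes poorly convert errors into no-calls.

`optimize_temperature_range` evaluates every candidate (t_start, t_end) on
a configurable grid (defaults: 1°C spacing, ≥2°C width; desk-scale analyses
in the examples and acceptance script use 4°C spacing with 1500–3000 draws
per genotype to keep runtimes in seconds), retraining ANCKG/μ/C per
candidate. Plate shifts are computed once on full-span controls and reused
— they are range-independent. Per-candidate seeds derive from the master
seed counter-style, so the search is reproducible from one number. Ties
break to the widest range, then the lowest start; candidates where training
fails (e.g. degenerate flat regions) are skipped and recorded.

## Visualization

The cluster plot projects each curve's correlation vector (restricted to
three chosen basis genotypes) onto unit axes at 90°, 210° and 330°:
point = Σ r_i·u_i. The axes are maximum-correlation boundaries — a curve
perfectly correlated with one ANCKG and uncorrelated with the others lands
on that axis tip at distance 1 — and equal correlation with all three maps
to the origin. Training ellipses are built by Monte Carlo: sample the
fitted Gaussian, map through the inverse spherical transform and the
projection, fit a 2D Gaussian to the cloud, draw its χ²₂ coverage ellipse.
This is honest about the transform's curvature and exact in the
small-variance limit. Colors follow the called genotype; no-calls are gray.

## Synthetic data

The generator is the package's study-conditions module, not a convenience
fixture. A genotype is one or more logistic transitions
A·logistic((tm−T)/w); heterozygotes get two half-amplitude transitions at
the two homozygote temperatures (the heteroduplex double-peak signature —
at 1°C spacing with 0.5°C widths this appears as a broadened peak rather
than two resolved maxima, as in real small-amplicon assays). On top sit a
linearly decaying background and, critically, the variability structure of
real plates:

| effect | default | emulates |
|---|---|---|
| reading noise sd | 3 units (3% of amplitude) | detector/shot noise |
| per-well Tm jitter | 0.02°C | intra-plate thermal gradients |
| per-transition Tm jitter | 0.015°C | duplex-level variability |
| per-sample Tm effect | 0.02°C | template/salt differences between DNA preps (shared by a sample's triplicate; absent from controls, which are one prep) |
| amplitude CV | 5% | template concentration (removed by normalization) |
| width CV | 5% | buffer/salt effects on transition steepness |
| background-slope sd | 0.15 | dye and volume differences |
| smooth drift | 1 unit, 3 harmonics | optical drift |
| per-well skew | 0.05 | flank asymmetry variation |
| plate offset | preset-specific | inter-run temperature bias |

The defaults were chosen once so that within-genotype clusters have
full-rank, moderately anisotropic covariance with ~10 sd separation between
1°C-spaced homozygote classes, and the plate-frame residual is ~0.5
within-cluster sd — the regime in which clean real assays operate. Presets:
`default` (two plates, +0.7°C bias on the validation plate), `overlap`
(wild type and homozygote 0.15°C apart ≈ 5 sd: the deliberate-no-call
regime), `snapback` (probe region 60.5/64.5°C strongly informative,
amplicon region 80.0/80.15°C weakly informative, 10 samples/°C over
45–95°C), `narrowband` (informative only near 78–82°C, noisy elsewhere —
the range optimizer's test bed).

What the simulator does **not** emulate: spatially structured thermal
gradients (jitter is i.i.d., not a smooth plate map), dye redistribution
and saturation effects, amplification failures and primer-dimer artifacts,
baseline exponential decay (the background is linear), and real
heteroduplex thermodynamics (shapes are sums of logistics). Passing tests
therefore demonstrate the pipeline's statistical behaviour under realistic
variance structure, not instrument-specific robustness.

## Numerical choices and degenerate inputs

Grid arithmetic is integer-lattice based (tolerance 1e-6 step) so plates
align exactly after shifting. Duplicate temperature rows collapse by the
mean at parse time. Constant curves (flat melt = failed reaction) raise a
degenerate-curve error at normalization; a genotype whose members average
to a constant raises at ANCKG formation; a genotype with ≤ N_c training
curves raises a singular-covariance error. All-vanishing likelihoods map to
a no-call (`outside_ellipsoid`), not a crash. Exact correlation ties in the
shift search are resolved by a documented deterministic rule. Model files
are versioned JSON; a version mismatch is an explicit error.

## Problem sizes

Default study scale: one training plate (96 training wells + 3 controls),
one validation plate (120 unknown wells + 3 controls), traces of 801 points
(55–95°C at 0.05°C). Monte Carlo cross tables use 10⁴ draws per genotype by
default; the closed-form comparison in the acceptance script uses 10⁵; the
range searches in examples and acceptance use coarse 4°C candidate grids
with 1500–3000 draws per genotype. These sizes were chosen to keep any
single analysis in seconds on one core while leaving Monte Carlo standard
errors well below the effects being measured.

## Known limitations

* With ~30 training curves per genotype, fitted covariances are noisy; the
  predictive-F gate and the frame-uncertainty term compensate for the two
  dominant failure modes, but occasional (~0.05% of wells) borderline
  coverage no-calls remain — as they do in real assays.
* The sign of r₁ is not represented in the spherical transform (see above).
* One shift per plate: within-plate spatial temperature structure is not
  corrected (checkerboard controls or internal temperature standards would
  be needed).
* The range optimizer is an exhaustive grid; its cost grows quadratically
  in candidates, so dense grids over wide spans should lower `n_mc` or
  coarsen spacing.
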