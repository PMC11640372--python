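# Methods

## Signal model and feature statistic

A dialysis session is a uniformly sampled HR trace (nominally 1 Hz; traces on
other grids are linearly interpolated onto integer seconds, refusing gaps
longer than 30 s rather than inventing data across them). Features are
computed on eight nested windows `[0, 300k)` seconds, `k = 1..8`, all sharing
one anchor sample. The anchor is configurable: in retrospective analysis it is
placed 45 minutes before a known IDH onset; a live deployment anchors at the
session start.

Within a window the trace is smoothed by the least-squares polynomial of
degree 20. The fit is solved in a Chebyshev basis on time normalized to
[−1, 1]: this is the same least-squares optimum as raw monomials (the spanned
space is identical) but is numerically stable at degree 20 over thousands of
samples, where a raw-monomial Vandermonde system is unusable. Because the
basis contains the constant, residuals sum to zero, so the fitted curve's mean
equals the raw window mean — which makes the choice of "mean line" (raw vs.
fitted mean) provably inconsequential; the implementation uses the raw mean
and tests the equality.

The per-window statistic is the pair of **maximum excursion areas**: deviations
`d = fitted − mean` are segmented into maximal runs of strictly positive /
strictly negative sign (exact zeros belong to no run; after smoothing, a zero
is a measure-zero event, and strictness makes run semantics unambiguous), the
area of a run is `Σ|d|` at 1 s width (rectangle rule — consistent with the
saturation arithmetic 6000 = 20 × 300; no trapezoid correction), and the
upper/lower maxima are taken, 0 when a side has no run. Ties in the maximum
are broken toward the earliest run; only the identity of the reported segment,
never the area, depends on the tie rule. All indices are 0-based with
half-open ranges.

Two exact invariances follow from linearity of the fit and are tested:
translation (adding a constant to HR changes no area) and positive scaling of
deviations (areas scale by the same factor). A brute-force O(n²) enumeration
of contiguous constant-sign ranges serves as the oracle for the run/max logic.

## Indicator

Each side of the gauge is `min(100, area / saturation × 100)` with a shared
saturation of 6000 bpm·s — the area of a 20-unit deviation sustained for five
minutes. The warning tier is determined by the larger of the two sides
against thresholds 10 / 46 / 83 percent. The published account gives single
per-patient percentages without stating a combination rule; the maximum of
the two sides is the conservative (alarm-favoring) choice, consistent with
the observation that either a sustained low-HR period or a compensatory
high-HR spike alone precedes IDH. Saturation and thresholds are configurable
(per-patient personalisation of the saturation is explicitly anticipated);
the defaults above are the documented reference values. The areas conflate
bpm-based HR deviations with mmHg in the source material's reading; the
package stores areas in bpm·s throughout and does not invent a unit
conversion.

## Classifier

Architecture 16 → (16 tanh)×k → 2 softmax, k ∈ [2, 5]. Training is full-batch
scaled conjugate gradient (Møller's algorithm: conjugate directions with a
Hessian-vector estimate by finite differencing of the gradient and a
Levenberg-Marquardt-style scaling, no learning rate) on the mean
cross-entropy; one iteration consumes the whole training set and counts as an
epoch, default 20. Weights are Glorot-uniform initialised from the seeded
generator; everything downstream of the seed is deterministic, and two runs
with the same seed produce bit-identical weights and reports. Inputs are
min-max scaled to [−1, 1] with parameters fitted on the training split only
(transformed values are clipped to ±3 so far-out-of-range inputs cannot
produce wild activations; constant features map to 0). The split is
stratified 70/15/15, seed-controlled; the source material does not state one,
so the common toolbox default was adopted. Early stopping on the validation
split exists but is off by default (training runs the fixed epoch budget).
Exact probability ties predict IDH — the alarm-favoring side. Metrics are
computed exactly by the four printed formulas; a metric with zero denominator
is reported as `None` (undefined), never coerced to 0, to avoid silently
inflating PPV on degenerate test sets.

## Synthetic cohort generator

The generator emulates the statistical structure the method consumes, not
dialysis physiology. A case is

```
HR(t) = baseline + pulse train(t) + white noise,  t = 0..2699 s
```

- **Pulse train**: ten flat-top pulses with cosine edges, alternating sign,
  whose durations grow from 140 s to 365 s across the session. The class
  templates differ only in the area layout: IDH pulses grow steeply (ending in
  a long deep below-mean period and a large late above-mean pulse — the
  hypotension + compensation signature), normal pulses stay small and evenly
  mixed. Template areas were laid out so that the pipeline-extracted
  per-window maxima track the class mean growth curves (the eight-window
  target vectors in `ClassProfile`) and so that upper and lower totals are
  close to balanced — an imbalanced train pushes the window mean off-centre
  and the entire complement of the dominant side accumulates opposite-sign
  area.
- **Calibration**: per case, the final (40-min) upper and lower areas are
  matched to the case's sampled targets by a damped two-parameter fixed
  point: a global amplitude `c0` (every excursion area is exactly linear in
  it, because the fit is linear and the total area above the window mean
  always equals the total below) and a tilt `r` between the two final pulses.
  Extraction runs through the *real* pipeline — fit, segmentation, max — on
  the series as emitted (noise included), so recorded targets are
  pipeline-true. Tolerance 0.5%, at most 25 iterations; the documented
  contract is 2%, and a case that cannot reach 2% raises `CalibrationError`
  with diagnostics. In practice convergence takes 2–5 iterations (~10 ms per
  case).
- **Dispersion**: the upper and lower 40-min targets are multiplied by
  independent mean-one lognormal draws, `exp(N(−σ²/2, σ))` with σ = 0.15, so
  cohort means stay centred on the target values while cases vary
  realistically (areas are positive and right-skewed). σ = 0.15 keeps normal
  cases below the 46% gauge line and sends the large majority of IDH cases
  past the 83% warning line.
- **Baseline and noise**: baseline HR uniform in (60, 100) bpm, white noise
  σ = 1.5 bpm. Features are exactly translation invariant, so the baseline is
  cosmetic; it is shifted minimally when needed to keep the trace inside
  (25, 245) bpm so validation never trips on noise tails. Intermediate-window
  targets (5–35 min) are matched only loosely (the nested-window statistics of
  one trace are over-constrained — eight pairs of maxima cannot be controlled
  jointly); empirically the per-class cohort means stay within ~±25% of their
  targets and grow monotonically across windows.

Per-case seeds are spawned from the master seed via `SeedSequence`, class
counts are exact, and cohort order is shuffled deterministically.

**What passing tests do and do not show.** The synthetic cohorts reproduce
the *second-order description* of the clinical data (class-conditional area
growth means, their spread, the indicator narratives) — not raw HR morphology,
arrhythmias, sensor dropout, inter-patient baselines beyond a uniform draw, or
any blood-pressure signal. Classifier accuracies near 100% on these cohorts
say the pipeline and training are correct and that the published class
separation is easily learnable; they are not a clinical performance estimate.

## Problem sizes and numerical choices

Acceptance-style quantities are computed on 1000 cases per class for the
cohort means and a 530+420 cohort for the classifier — large enough that the
CLT error of a cohort mean (σ/√n ≈ 0.5%) sits well inside the 2% comparison
band. The polynomial degree (20) is used for every window including the
5-minute one; the degree is a parameter of `fit_curve`/`extract_features` for
experimentation. Excursion areas sum the fitted-minus-mean deviations, not the
raw HR, matching the definition of the statistic as the area between the
fitted curve and the mean line.

## Known limitations

- The gauge tier rule (max of two sides) and the four-tier split are a
  synthesis of scattered reference percentages (10, 46, 83); other
  combination rules are plausible and configurable.
- The generator's pulse grammar is one of many trajectories consistent with
  the published growth curves; conclusions that depend on HR *morphology*
  rather than excursion areas should not be drawn from it.
- `train` does not guard against tiny cohorts beyond requiring both classes
  present; with fewer than ~10 cases per class the stratified split can leave
  empty validation/test parts.
- Session metadata (label, subject id) travels in a JSON sidecar next to the
  HR CSV; there is no provision for device formats or HL7/FHIR.
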