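"""Synthetic dialysis-session HR generator with class-conditional excursion structure.

Emulates the statistical structure the warning method consumes: 45-min
sessions at 1 Hz whose nested-window maximum excursion areas grow like the
reported class-conditional mean curves. IDH sessions carry progressively
deeper below-mean periods ending in a large late compensatory above-mean
excursion; normal sessions carry small alternating bumps evenly mixed about
the mean.

Each case is closed-loop calibrated THROUGH the real pipeline (polynomial
fit, excursion segmentation, max area): pulse amplitudes are rescaled until
the extracted upper and lower areas at the 40-min window match the case's
sampled targets, so generator targets are pipeline-true, not nominal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hr_features import HRSeries, SessionLabel, window_features

__all__ = [
    "ClassProfile",
    "SyntheticCase",
    "CalibrationError",
    "normal_profile",
    "idh_profile",
    "generate_case",
    "generate_cohort",
    "cohort_summary",
]

# Default class-conditional mean growth targets for the max excursion areas
# (bpm*s) across the eight cumulative windows (5..40 min).
NORMAL_UPPER_TARGETS = (379.5991, 638.9006, 860.6037, 975.1489, 1147.24, 1331.16, 1496.005, 1677.268)
NORMAL_LOWER_TARGETS = (367.9417, 650.9886, 802.9613, 1010.646, 1150.35, 1236.38, 1411.816, 1668.84)
IDH_UPPER_TARGETS = (825.661, 1477.035, 1950.916, 2739.734, 3182.923, 4010.57, 4681.352, 5546.794)
IDH_LOWER_TARGETS = (671.2035, 1291.615, 1949.163, 2726.722, 3154.916, 3917.041, 4657.922, 5119.467)

SESSION_LEN_S = 2700  # 45 min at 1 Hz
ANALYSIS_LEN_S = 2400  # the 40-min feature window

# Pulse layout templates: (sign, start_s, duration_s, nominal area as a
# fraction of the class's final-window target on that side). Durations grow
# so late excursions are long and shallow (prolonged dip + compensatory
# spike for IDH) and the degree-20 fit resolves every pulse.
_PULSE_STARTS_DURS = (
    (10, 140),
    (150, 140),
    (300, 140),
    (450, 180),
    (660, 200),
    (880, 220),
    (1120, 260),
    (1400, 280),
    (1700, 310),
    (2030, 365),
)

_IDH_AREAS = (700, 750, 1250, 1350, 2550, 2300, 3700, 3400, 4900, 5547)
_NORMAL_AREAS = (400, 380, 730, 640, 1100, 950, 1350, 1380, 1600, 1677)

_EDGE_FRAC = 0.25  # cosine taper fraction at each pulse edge; area = 0.75*amp*dur


def _template(areas: tuple[float, ...], final_upper: float, final_lower: float):
    """(sign, start, dur, area_fraction-of-final-target) rows; signs alternate -,+."""
    rows = []
    for i, ((start, dur), area) in enumerate(zip(_PULSE_STARTS_DURS, areas)):
        sign = -1 if i % 2 == 0 else 1
        ref = final_upper if sign > 0 else final_lower
        rows.append((sign, start, dur, area / ref))
    return tuple(rows)


@dataclass(frozen=True)
class ClassProfile:
    """Generator settings for one class.

    area_targets_*: mean max-area growth curve (bpm*s) over the 8 windows;
    only the final (40-min) values are hard-calibrated per case, the earlier
    ones shape the pulse template loosely. dispersion: sigma of the mean-one
    lognormal case-level multiplier applied independently to the upper and
    lower targets. noise_sd: white measurement noise (bpm) on top of the
    smooth trajectory. baseline_hr_range: uniform draw of the resting HR.
    """

    label: SessionLabel
    area_targets_upper: tuple[float, ...]
    area_targets_lower: tuple[float, ...]
    dispersion: float = 0.15
    baseline_hr_range: tuple[float, float] = (60.0, 100.0)
    noise_sd: float = 1.5

    def __post_init__(self) -> None:
        for name in ("area_targets_upper", "area_targets_lower"):
            t = getattr(self, name)
            if len(t) != 8 or any(v <= 0 for v in t):
                raise ValueError(f"{name} must be 8 positive values")
            if any(b < a for a, b in zip(t, t[1:])):
                raise ValueError(f"{name} must be non-decreasing")
        if self.dispersion < 0 or self.noise_sd < 0:
            raise ValueError("dispersion and noise_sd must be >= 0")
        lo, hi = self.baseline_hr_range
        if not (0 < lo <= hi):
            raise ValueError("invalid baseline_hr_range")


def normal_profile(**overrides) -> ClassProfile:
    kw = dict(
        label=SessionLabel.NORMAL,
        area_targets_upper=NORMAL_UPPER_TARGETS,
        area_targets_lower=NORMAL_LOWER_TARGETS,
    )
    kw.update(overrides)
    return ClassProfile(**kw)


def idh_profile(**overrides) -> ClassProfile:
    kw = dict(
        label=SessionLabel.IDH,
        area_targets_upper=IDH_UPPER_TARGETS,
        area_targets_lower=IDH_LOWER_TARGETS,
    )
    kw.update(overrides)
    return ClassProfile(**kw)


@dataclass
class SyntheticCase:
    series: HRSeries
    label: SessionLabel
    realized_targets: dict[str, float]
    seed: int


class CalibrationError(RuntimeError):
    pass


def _pulse(t: np.ndarray, start: float, dur: float) -> np.ndarray:
    """Unit-amplitude flat-top pulse with cosine edges on [start, start+dur)."""
    edge = _EDGE_FRAC * dur
    u = t - start
    out = np.zeros_like(t)
    rising = (u >= 0) & (u < edge)
    flat = (u >= edge) & (u < dur - edge)
    falling = (u >= dur - edge) & (u < dur)
    out[rising] = 0.5 * (1 - np.cos(np.pi * u[rising] / edge))
    out[flat] = 1.0
    out[falling] = 0.5 * (1 - np.cos(np.pi * (dur - u[falling]) / edge))
    return out


def _deviation(template, t: np.ndarray, target_u: float, target_l: float,
               c0: float, r: float) -> np.ndarray:
    """Pulse train with two calibration controls.

    c0 scales every pulse (every excursion area scales exactly linearly with
    it); r tilts the two final pulses against each other (final upper x r,
    final lower / r). Because the fitted curve's total area above the window
    mean always equals the total below, per-side global scaling is not an
    independent control — amplitude plus tilt is.
    """
    n = len(template)
    final_upper = max(i for i, row in enumerate(template) if row[0] > 0)
    final_lower = max(i for i, row in enumerate(template) if row[0] < 0)
    dev = np.zeros_like(t)
    for i, (sign, start, dur, frac) in enumerate(template):
        area = frac * (target_u if sign > 0 else target_l) * c0
        if i == final_upper:
            area *= r
        elif i == final_lower:
            area /= r
        amp = area / ((1.0 - _EDGE_FRAC) * dur)
        dev += sign * amp * _pulse(t, start, dur)
    return dev


def _extracted_final_areas(dev: np.ndarray, degree: int = 20) -> tuple[float, float]:
    wf = window_features(dev[:ANALYSIS_LEN_S], ANALYSIS_LEN_S, degree=degree)
    return wf.upper_area, wf.lower_area


def generate_case(profile: ClassProfile, seed: int) -> SyntheticCase:
    """One seeded session: baseline + calibrated pulse structure + white noise."""
    rng = np.random.default_rng(seed)
    baseline = float(rng.uniform(*profile.baseline_hr_range))
    if profile.dispersion > 0:
        s = profile.dispersion
        m_u = float(np.exp(rng.normal(-0.5 * s * s, s)))  # mean-one lognormal
        m_l = float(np.exp(rng.normal(-0.5 * s * s, s)))
    else:
        m_u = m_l = 1.0
    target_u = profile.area_targets_upper[-1] * m_u
    target_l = profile.area_targets_lower[-1] * m_l

    if profile.label == SessionLabel.IDH:
        template = _template(_IDH_AREAS, IDH_UPPER_TARGETS[-1], IDH_LOWER_TARGETS[-1])
    else:
        template = _template(_NORMAL_AREAS, NORMAL_UPPER_TARGETS[-1], NORMAL_LOWER_TARGETS[-1])

    t = np.arange(SESSION_LEN_S, dtype=float)
    # Noise is drawn before calibration and included in the loop: the contract
    # is that areas extracted from the series as emitted hit the targets.
    noise = rng.normal(0.0, profile.noise_sd, SESSION_LEN_S) if profile.noise_sd > 0 else 0.0
    c0, r = 1.0, 1.0
    tol = 0.005
    best = (np.inf, c0, r)
    for it in range(25):
        dev = _deviation(template, t, target_u, target_l, c0, r) + noise
        got_u, got_l = _extracted_final_areas(dev)
        if got_u <= 0 or got_l <= 0:
            raise CalibrationError(
                f"degenerate extraction (upper={got_u:.1f}, lower={got_l:.1f}) "
                f"for seed {seed}"
            )
        err = max(abs(got_u / target_u - 1.0), abs(got_l / target_l - 1.0))
        if err < best[0]:
            best = (err, c0, r)
        if err < tol:
            break
        # amplitude fixes the geometric mean exactly; the tilt is damped
        # because excursion boundaries can jump under reshaping
        c0 *= math.sqrt((target_u * target_l) / (got_u * got_l))
        r *= ((target_u / target_l) / (got_u / got_l)) ** 0.5
    else:
        err, c0, r = best
        if err >= 0.02:
            raise CalibrationError(
                f"calibration did not converge in 25 iterations for seed {seed}: "
                f"best relative error {err:.3f} (targets upper {target_u:.1f}, "
                f"lower {target_l:.1f})"
            )
        dev = _deviation(template, t, target_u, target_l, c0, r) + noise

    hr = baseline + dev
    # Shift minimally so the trace stays well inside the valid HR band;
    # features are translation invariant, so this is free.
    shift = max(0.0, 25.0 - hr.min())
    shift -= max(0.0, hr.max() + shift - 245.0)
    hr = hr + shift
    series = HRSeries(
        time_s=t,
        hr_bpm=hr,
        rate_hz=1.0,
        label=profile.label,
        subject_id=f"syn-{profile.label.value.lower()}-{seed}",
    )
    return SyntheticCase(
        series=series,
        label=profile.label,
        realized_targets={"upper_2400": target_u, "lower_2400": target_l},
        seed=int(seed),
    )


def generate_cohort(
    n_normal: int,
    n_idh: int,
    profiles: tuple[ClassProfile, ClassProfile] | None = None,
    master_seed: int = 0,
) -> list[SyntheticCase]:
    """Seeded labeled cohort; per-case seeds spawned from the master seed.

    Exact class counts; deterministic shuffled order.
    """
    if n_normal < 0 or n_idh < 0:
        raise ValueError("cohort sizes must be >= 0")
    prof_normal, prof_idh = profiles or (normal_profile(), idh_profile())
    n_total = n_normal + n_idh
    if n_total == 0:
        return []
    ss = np.random.SeedSequence(master_seed)
    seeds = ss.generate_state(n_total, dtype=np.uint32) & 0x7FFFFFFF
    cases = [generate_case(prof_normal, int(s)) for s in seeds[:n_normal]]
    cases += [generate_case(prof_idh, int(s)) for s in seeds[n_normal:]]
    order = np.random.default_rng(ss.spawn(1)[0]).permutation(n_total)
    return [cases[i] for i in order]


def cohort_summary(cases: list[SyntheticCase], spec=None, degree: int = 20):
    """Per-class mean upper/lower area at each window, as a tidy DataFrame.

    Rows: (label, side); columns: window length in seconds.
    """
    import pandas as pd

    from .hr_features import WindowSpec, extract_features

    spec = spec or WindowSpec()
    present = {c.label for c in cases}
    for lab in (SessionLabel.IDH, SessionLabel.NORMAL):
        if lab not in present:
            raise ValueError(f"class {lab.value} missing from cohort")
    sums: dict[SessionLabel, list[np.ndarray]] = {lab: [] for lab in present}
    for case in cases:
        fv, _ = extract_features(case.series, spec, degree=degree)
        sums[case.label].append(fv.values.reshape(spec.count, 2))
    rows, index = [], []
    for lab in (SessionLabel.NORMAL, SessionLabel.IDH):
        mean = np.mean(sums[lab], axis=0)  # (count, 2): [:, 0] upper, [:, 1] lower
        for j, side in enumerate(("upper", "lower")):
            rows.append(mean[:, j])
            index.append((lab.value, side))
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["label", "side"]),
        columns=list(spec.lengths_s),
    )
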