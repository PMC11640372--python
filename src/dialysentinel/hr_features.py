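"""Cumulative-window excursion-area features from a dialysis-session heart-rate trace.

The core statistic: within each cumulative window the HR trace is smoothed by a
degree-20 least-squares polynomial, the window mean is drawn as a horizontal
reference line, and the largest contiguous area between the fitted curve and
the mean line — above (upper) and below (lower) — is recorded. Eight nested
windows (5, 10, ..., 40 min) yield a 16-element feature vector per session.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np
from numpy.polynomial import chebyshev as _cheb

__all__ = [
    "SessionLabel",
    "HRSeries",
    "WindowSpec",
    "FittedCurve",
    "ExcursionSign",
    "Excursion",
    "WindowFeatures",
    "FeatureVector",
    "resample_to_1hz",
    "make_windows",
    "fit_curve",
    "excursion_segments",
    "max_area",
    "extract_features",
    "FEATURE_NAMES",
]

HR_MIN_BPM = 20.0
HR_MAX_BPM = 250.0
MAX_GAP_S = 30.0


class SessionLabel(str, enum.Enum):
    """Session outcome: IDH = systolic BP fell by >20 mmHg at least once."""

    IDH = "IDH"
    NORMAL = "NORMAL"


@dataclass
class HRSeries:
    """One session's HR trace: strictly increasing times, physiologic bpm values."""

    time_s: np.ndarray
    hr_bpm: np.ndarray
    rate_hz: float = 1.0
    label: SessionLabel | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.hr_bpm = np.asarray(self.hr_bpm, dtype=float)
        if self.time_s.ndim != 1 or self.hr_bpm.ndim != 1:
            raise ValueError("time_s and hr_bpm must be 1-D arrays")
        if self.time_s.size != self.hr_bpm.size:
            raise ValueError(
                f"length mismatch: {self.time_s.size} times vs {self.hr_bpm.size} HR values"
            )
        if self.time_s.size < 2:
            raise ValueError("an HR series needs at least 2 samples")
        if self.time_s[0] < 0:
            raise ValueError("time_s must be non-negative")
        if not np.all(np.diff(self.time_s) > 0):
            i = int(np.flatnonzero(np.diff(self.time_s) <= 0)[0])
            raise ValueError(f"time_s not strictly increasing at index {i + 1}")
        if not np.all(np.isfinite(self.hr_bpm)):
            i = int(np.flatnonzero(~np.isfinite(self.hr_bpm))[0])
            raise ValueError(f"non-finite hr_bpm at index {i}")
        bad = (self.hr_bpm <= HR_MIN_BPM) | (self.hr_bpm >= HR_MAX_BPM)
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"hr_bpm out of physiologic range ({HR_MIN_BPM}, {HR_MAX_BPM}) "
                f"at index {i}: {self.hr_bpm[i]}"
            )
        if self.label is not None:
            self.label = SessionLabel(self.label)

    def __len__(self) -> int:
        return int(self.time_s.size)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    def is_uniform_1hz(self) -> bool:
        dt = np.diff(self.time_s)
        return bool(np.all(dt == 1.0)) and float(self.time_s[0]).is_integer()


@dataclass(frozen=True)
class WindowSpec:
    """Nested cumulative analysis windows sharing one anchor sample.

    Default: eight windows of 5, 10, ..., 40 minutes anchored at sample 0
    (a hindsight anchor 45 min before IDH onset, or the session start live).
    """

    start_index: int = 0
    lengths_s: tuple[int, ...] = (300, 600, 900, 1200, 1500, 1800, 2100, 2400)

    def __post_init__(self) -> None:
        object.__setattr__(self, "lengths_s", tuple(int(v) for v in self.lengths_s))
        if self.start_index < 0:
            raise ValueError("start_index must be >= 0")
        if not self.lengths_s:
            raise ValueError("lengths_s must be non-empty")
        prev = 0
        for v in self.lengths_s:
            if v <= prev:
                raise ValueError("lengths_s must be strictly increasing")
            if v % 300 != 0:
                raise ValueError(f"window length {v} is not a multiple of 300 s")
            prev = v

    @property
    def count(self) -> int:
        return len(self.lengths_s)


@dataclass(frozen=True)
class FittedCurve:
    """Least-squares polynomial smoother evaluated on the window grid.

    The fit is computed in a Chebyshev basis on time normalized to [-1, 1]:
    mathematically the same least-squares optimum as raw monomials, but
    numerically stable at degree 20 over thousands of samples. Because the
    basis contains the constant, residuals sum to zero, so the fitted curve
    has exactly the raw window mean.
    """

    degree: int
    values: np.ndarray
    basis_note: str = "least-squares Chebyshev fit on time normalized to [-1, 1]"


class ExcursionSign(str, enum.Enum):
    UPPER = "UPPER"
    LOWER = "LOWER"


@dataclass(frozen=True)
class Excursion:
    """A maximal run of constant-sign deviation (fitted - mean), half-open indices."""

    start_index: int
    end_index: int
    sign: ExcursionSign
    area: float  # bpm*s at 1 Hz (rectangle rule, 1 s width)


@dataclass(frozen=True)
class WindowFeatures:
    length_s: int
    mean_hr: float
    upper_area: float
    lower_area: float


def _feature_names(spec: WindowSpec) -> list[str]:
    names: list[str] = []
    for L in spec.lengths_s:
        names += [f"upper_{L}", f"lower_{L}"]
    return names


FEATURE_NAMES: tuple[str, ...] = tuple(_feature_names(WindowSpec()))


@dataclass
class FeatureVector:
    """Classifier input: (upper, lower) max areas per window, window order."""

    values: np.ndarray
    label: SessionLabel | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("feature values must be 1-D")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite and >= 0")
        if self.label is not None:
            self.label = SessionLabel(self.label)

    def __len__(self) -> int:
        return int(self.values.size)


def resample_to_1hz(series: HRSeries) -> HRSeries:
    """Resample onto an integer-second 1 Hz grid by linear interpolation.

    A series already on the grid is returned unchanged. Gaps longer than
    30 s between original samples are refused rather than interpolated.
    """
    if series.duration_s < 2:
        raise ValueError("series too short to resample (duration < 2 s)")
    gaps = np.diff(series.time_s)
    if np.any(gaps > MAX_GAP_S):
        i = int(np.flatnonzero(gaps > MAX_GAP_S)[0])
        raise ValueError(
            f"gap of {gaps[i]:.1f} s between t={series.time_s[i]:.1f} and "
            f"t={series.time_s[i + 1]:.1f} exceeds {MAX_GAP_S:.0f} s"
        )
    if series.is_uniform_1hz():
        return series
    t0 = math.ceil(series.time_s[0])
    t1 = math.floor(series.time_s[-1])
    grid = np.arange(t0, t1 + 1, dtype=float)
    if grid.size < 2:
        raise ValueError("fewer than 2 integer-second grid points in series span")
    hr = np.interp(grid, series.time_s, series.hr_bpm)
    return replace(series, time_s=grid, hr_bpm=hr)


def make_windows(series: HRSeries, spec: WindowSpec | None = None) -> list[tuple[int, int]]:
    """Half-open sample ranges of the nested windows, all anchored at start_index."""
    spec = spec or WindowSpec()
    needed = spec.start_index + spec.lengths_s[-1]
    if len(series) < needed:
        raise ValueError(
            f"series too short: {needed} samples required "
            f"(anchor {spec.start_index} + {spec.lengths_s[-1]} s), got {len(series)}"
        )
    return [(spec.start_index, spec.start_index + L) for L in spec.lengths_s]


def fit_curve(window_hr: np.ndarray, degree: int = 20) -> FittedCurve:
    """Degree-`degree` least-squares polynomial smoother of one window."""
    y = np.asarray(window_hr, dtype=float)
    if y.ndim != 1:
        raise ValueError("window_hr must be 1-D")
    if not np.all(np.isfinite(y)):
        raise ValueError("window_hr must be finite")
    if y.size <= degree:
        raise ValueError(f"window length {y.size} must exceed polynomial degree {degree}")
    x = np.linspace(-1.0, 1.0, y.size)
    coef = _cheb.chebfit(x, y, degree)
    fitted = _cheb.chebval(x, coef)
    return FittedCurve(degree=degree, values=fitted)


def excursion_segments(fitted: FittedCurve | np.ndarray, mean_hr: float) -> list[Excursion]:
    """Maximal strictly-positive / strictly-negative runs of (fitted - mean).

    Samples where the deviation is exactly zero belong to no excursion and
    split runs. Areas use the 1 Hz rectangle rule: sum of |deviation|.
    """
    values = fitted.values if isinstance(fitted, FittedCurve) else np.asarray(fitted, float)
    if values.size == 0:
        raise ValueError("fitted curve is empty")
    dev = values - mean_hr
    sign = np.sign(dev).astype(int)
    out: list[Excursion] = []
    start = 0
    n = sign.size
    for i in range(1, n + 1):
        if i == n or sign[i] != sign[start]:
            if sign[start] != 0:
                seg_sign = ExcursionSign.UPPER if sign[start] > 0 else ExcursionSign.LOWER
                area = float(np.abs(dev[start:i]).sum())
                out.append(Excursion(start, i, seg_sign, area))
            start = i
    return out


def max_area(excursions: list[Excursion], sign: ExcursionSign) -> float:
    """Largest excursion area of the given sign; 0 if none. Ties: earliest wins."""
    best = 0.0
    for exc in excursions:  # list is in start order, so > keeps the earliest tie
        if exc.sign == sign and exc.area > best:
            best = exc.area
    return best


def window_features(window_hr: np.ndarray, length_s: int, degree: int = 20) -> WindowFeatures:
    """Mean, fit, and upper/lower max excursion areas for one window."""
    mean_hr = float(np.mean(window_hr))
    fitted = fit_curve(window_hr, degree=degree)
    segs = excursion_segments(fitted, mean_hr)
    return WindowFeatures(
        length_s=length_s,
        mean_hr=mean_hr,
        upper_area=max_area(segs, ExcursionSign.UPPER),
        lower_area=max_area(segs, ExcursionSign.LOWER),
    )


def extract_features(
    series: HRSeries,
    spec: WindowSpec | None = None,
    degree: int = 20,
) -> tuple[FeatureVector, list[WindowFeatures]]:
    """Per-window statistics and the concatenated feature vector.

    The mean line and the polynomial fit are recomputed on every cumulative
    window: both change as the window grows, which is what makes the nested
    areas informative about when an excursion happened.
    """
    spec = spec or WindowSpec()
    dt = np.diff(series.time_s)
    if not np.all(dt == 1.0):
        raise ValueError("series must be uniformly sampled at 1 Hz; resample_to_1hz first")
    ranges = make_windows(series, spec)
    per_window: list[WindowFeatures] = []
    vec: list[float] = []
    for (a, b), L in zip(ranges, spec.lengths_s):
        wf = window_features(series.hr_bpm[a:b], L, degree=degree)
        per_window.append(wf)
        vec += [wf.upper_area, wf.lower_area]
    fv = FeatureVector(np.array(vec), label=series.label, subject_id=series.subject_id)
    return fv, per_window
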