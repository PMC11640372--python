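"""Two-sided IDH warning gauge.

Each side of the gauge is a capped percentage: the window's lower / upper
maximum excursion area divided by a saturation constant (default 6000 bpm*s,
a 20 bpm deviation sustained for 5 min). The warning tier is taken from the
larger of the two sides — either a sustained hypotensive (low-HR) period or
a compensatory high-HR spike alone is a precursor, so the gauge alarms on
whichever side is worse.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass

from .hr_features import HRSeries, WindowFeatures, WindowSpec, extract_features

__all__ = [
    "WarningTier",
    "IndicatorConfig",
    "IndicatorState",
    "compute_state",
    "track_session",
    "render_gauge",
    "parse_gauge_text",
]


class WarningTier(str, enum.Enum):
    STABLE = "STABLE"
    NORMAL = "NORMAL"
    ELEVATED = "ELEVATED"
    WARNING = "WARNING"


_TIER_ORDER = (WarningTier.STABLE, WarningTier.NORMAL, WarningTier.ELEVATED, WarningTier.WARNING)


@dataclass(frozen=True)
class IndicatorConfig:
    """Gauge scaling and tier thresholds.

    saturation: area at which one side reads 100%. Default 6000 bpm*s.
    tiers: three increasing percent cut points (stable < t0 <= normal < t1 <=
    elevated < t2 <= warning). Defaults 10 / 46 / 83: below 10% sessions look
    flat, normal sessions stay under 46%, and most IDH sessions exceed 83%.
    """

    saturation: float = 6000.0
    tiers: tuple[float, float, float] = (10.0, 46.0, 83.0)

    def __post_init__(self) -> None:
        if self.saturation <= 0:
            raise ValueError("saturation must be > 0")
        t = self.tiers
        if len(t) != 3 or not (0 < t[0] < t[1] < t[2] <= 100):
            raise ValueError("tiers must be 3 strictly increasing values in (0, 100]")


@dataclass(frozen=True)
class IndicatorState:
    """Gauge reading for one window: two capped percentages and a tier."""

    low_pct: float
    high_pct: float
    tier: WarningTier
    window_length_s: int


def _tier_for(pct: float, cfg: IndicatorConfig) -> WarningTier:
    t0, t1, t2 = cfg.tiers
    if pct < t0:
        return WarningTier.STABLE
    if pct < t1:
        return WarningTier.NORMAL
    if pct < t2:
        return WarningTier.ELEVATED
    return WarningTier.WARNING


def compute_state(features: WindowFeatures, cfg: IndicatorConfig | None = None) -> IndicatorState:
    """Map one window's two max areas to the gauge state."""
    cfg = cfg or IndicatorConfig()
    if features.upper_area < 0 or features.lower_area < 0:
        raise ValueError("areas must be >= 0")
    low = min(100.0, features.lower_area / cfg.saturation * 100.0)
    high = min(100.0, features.upper_area / cfg.saturation * 100.0)
    return IndicatorState(
        low_pct=low,
        high_pct=high,
        tier=_tier_for(max(low, high), cfg),
        window_length_s=features.length_s,
    )


def track_session(
    series: HRSeries,
    spec: WindowSpec | None = None,
    cfg: IndicatorConfig | None = None,
    degree: int = 20,
) -> list[IndicatorState]:
    """Gauge state per cumulative window, in window order.

    Each state depends only on samples up to its window end, so the sequence
    is exactly what a bedside display would have shown every 5 minutes.
    """
    _, per_window = extract_features(series, spec, degree=degree)
    return [compute_state(wf, cfg) for wf in per_window]


_BAR_WIDTH = 10

_TEXT_RE = re.compile(
    r"low \|(?P<lbar>[#\-]+)\| +(?P<low>\d+(?:\.\d+)?)% +"
    r"high \|(?P<hbar>[#\-]+)\| +(?P<high>\d+(?:\.\d+)?)% +"
    r"\[(?P<tier>[A-Z]+)\] +t=(?P<t>\d+)s"
)


def render_gauge(state: IndicatorState, mode: str = "text", path: str | None = None):
    """Render one gauge state.

    mode="text": a fixed-width two-sided bar string (pure: same state, same
    string). mode="figure": a matplotlib horizontal gauge; saved to `path`
    if given, the Figure is returned either way.
    """
    if mode == "text":
        lfill = round(state.low_pct / 100 * _BAR_WIDTH)
        hfill = round(state.high_pct / 100 * _BAR_WIDTH)
        lbar = "#" * lfill + "-" * (_BAR_WIDTH - lfill)
        hbar = "#" * hfill + "-" * (_BAR_WIDTH - hfill)
        return (
            f"low |{lbar}| {state.low_pct:5.1f}%  "
            f"high |{hbar}| {state.high_pct:5.1f}%  "
            f"[{state.tier.value}]  t={state.window_length_s}s"
        )
    if mode == "figure":
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 1.6))
        ax.barh([0], [-state.low_pct], color="tab:red", height=0.6)
        ax.barh([0], [state.high_pct], color="tab:blue", height=0.6)
        for x in (-100, 100):
            ax.axvline(x, color="0.3", lw=0.8)
        ax.set_xlim(-105, 105)
        ax.set_yticks([])
        ax.set_xlabel("low HR side (%)                high HR side (%)")
        ax.set_title(f"{state.tier.value}  (window {state.window_length_s} s)")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path)
        return fig
    raise ValueError(f"unknown render mode: {mode!r}")


def parse_gauge_text(text: str) -> IndicatorState:
    """Recover the state encoded by render_gauge(..., mode='text')."""
    m = _TEXT_RE.search(text)
    if m is None:
        raise ValueError("not a gauge string")
    return IndicatorState(
        low_pct=float(m["low"]),
        high_pct=float(m["high"]),
        tier=WarningTier(m["tier"]),
        window_length_s=int(m["t"]),
    )
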