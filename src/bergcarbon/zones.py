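"""Depth-stratified correlation of sea-ice duration with benthic blue carbon.

Coastal sea-ice loss pulls benthic carbon in opposite directions: it
lengthens phytoplankton blooms (more food, faster benthic growth) but
also frees icebergs to scour the shallows.  Which effect wins depends on
depth, because scour frequency falls off rapidly with depth while bloom
food reaches the whole shelf.  The analysis therefore stratifies samples
into depth zones and correlates blue-carbon stock against annual sea-ice
duration within each zone:

    zone A          [0, 10) m     scour dominates: positive correlation
    zone B          [10, 40) m    effects balance: no relationship
    zone of         [40, 200) m   too few samples for meaningful analysis
      ignorance
    zone C          [200, 500) m  bloom effect dominates: negative
    zone D          [500, 1000] m no relationship

A companion fit relates annual fast-ice duration to the proportion of
monitored shallow seabed scoured that year (negative: fast ice blocks
wind-driven iceberg travel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ZoneResult",
    "FastIceScourFit",
    "DEFAULT_ZONE_BOUNDS",
    "pearson",
    "classify_depth_zone",
    "zone_correlations",
    "fastice_scour_fit",
]

#: Depth-zone upper bounds in metres: A < 10 <= B < 40 <= ignorance < 200
#: <= C < 500 <= D <= 1000.  Overridable in every function that uses them.
DEFAULT_ZONE_BOUNDS: tuple[float, float, float, float, float] = (10.0, 40.0, 200.0, 500.0, 1000.0)

_ZONE_ORDER = ("A", "B", "ignorance", "C", "D")


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p (exact t transform).

    Requires equal lengths >= 3.  Zero variance in either vector is
    flagged by returning ``(nan, nan)`` rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def classify_depth_zone(
    depth: float, bounds: tuple[float, ...] = DEFAULT_ZONE_BOUNDS
) -> str:
    """Map a depth (m) to its zone label.

    Intervals are half-open with inclusive lower bound; the deepest zone
    includes its upper cap.  Depths beyond the cap return
    ``"out-of-range"``.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    b_a, b_b, b_ign, b_c, b_d = bounds
    if depth < b_a:
        return "A"
    if depth < b_b:
        return "B"
    if depth < b_ign:
        return "ignorance"
    if depth < b_c:
        return "C"
    if depth <= b_d:
        return "D"
    return "out-of-range"


@dataclass(frozen=True)
class ZoneResult:
    """Correlation outcome for one depth zone."""

    zone: str
    depth_min: float
    depth_max: float
    n: int
    r: float
    p: float
    sign: str  # positive | none | negative | insufficient

    def to_dict(self) -> dict:
        return {
            "zone": self.zone, "depth_min": self.depth_min,
            "depth_max": self.depth_max, "n": self.n,
            "r": self.r, "p": self.p, "sign": self.sign,
        }


def zone_correlations(
    samples: pd.DataFrame,
    alpha: float = 0.05,
    min_n: int = 3,
    bounds: tuple[float, ...] = DEFAULT_ZONE_BOUNDS,
) -> list[ZoneResult]:
    """Per-zone Pearson correlation of blue carbon on sea-ice duration.

    *samples* needs columns ``depth``, ``seaice_duration``,
    ``blue_carbon``.  The sign class is ``positive``/``negative`` when
    p < alpha, ``none`` when not, and ``insufficient`` for the zone of
    ignorance (never analysed), for zones with fewer than *min_n*
    samples, or when the correlation is undefined (constant values).

    No multiple-testing correction is applied across the zones; the four
    analysable zones are reported at the stated per-zone alpha.
    """
    if samples.empty:
        raise ValueError("samples must be non-empty")
    required = {"depth", "seaice_duration", "blue_carbon"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"samples missing columns: {sorted(missing)}")

    lows = (0.0,) + tuple(bounds[:-1])
    highs = bounds
    zone_bounds = dict(zip(_ZONE_ORDER, zip(lows, highs)))
    labels = samples["depth"].map(lambda d: classify_depth_zone(d, bounds))

    results: list[ZoneResult] = []
    for zone in _ZONE_ORDER:
        lo, hi = zone_bounds[zone]
        sub = samples[labels == zone]
        n = len(sub)
        if zone == "ignorance" or n < min_n:
            results.append(ZoneResult(zone, lo, hi, n, math.nan, math.nan, "insufficient"))
            continue
        r, p = pearson(sub["seaice_duration"], sub["blue_carbon"])
        if math.isnan(r):
            sign = "insufficient"
        elif p < alpha:
            sign = "positive" if r > 0 else "negative"
        else:
            sign = "none"
        results.append(ZoneResult(zone, lo, hi, n, r, p, sign))
    return results


@dataclass(frozen=True)
class FastIceScourFit:
    """Fast-ice duration vs scoured-proportion relationship."""

    n: int
    r: float
    p: float
    slope: float
    intercept: float


def fastice_scour_fit(series: pd.DataFrame) -> FastIceScourFit:
    """Correlate annual fast-ice duration with scoured seabed proportion.

    *series* needs columns ``fastice_duration`` (days) and
    ``scoured_proportion`` (fraction in [0, 1]); at least 3 years.
    Returns the Pearson r and p plus the least-squares slope and
    intercept of scoured_proportion on fastice_duration.  Undefined
    correlations (constant series) return nan fields.
    """
    required = {"fastice_duration", "scoured_proportion"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"series missing columns: {sorted(missing)}")
    x = series["fastice_duration"].to_numpy(dtype=float)
    y = series["scoured_proportion"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 years of monitoring")
    r, p = pearson(x, y)
    if math.isnan(r):
        return FastIceScourFit(len(x), math.nan, math.nan, math.nan, math.nan)
    fit = stats.linregress(x, y)
    return FastIceScourFit(len(x), r, p, float(fit.slope), float(fit.intercept))
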