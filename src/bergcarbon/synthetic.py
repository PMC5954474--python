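"""Synthetic inputs with the statistical structure the analyses assume.

The raw monitoring and survey data behind the published relationships are
not deposited anywhere, so the package ships generators that emulate
their structure: a negative fast-ice/scour relationship in the shallows,
depth-zoned sea-ice/blue-carbon correlation signs (+ / 0 / - / 0 for
zones A/B/C/D), and the March-2017 giant-iceberg census (47 giants, 6
over 1000 km2, 4 aground, most between 100 and 500 km2).  Every
generator is deterministic given its seed, and census constraints are
hard (satisfied exactly, not in expectation).

Effect sizes and noise levels are synthetic calibration choices — the
originals are unknowable from the published record — sized so that the
analyses recover the built-in ground truth with high power at realistic
sample sizes (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MonitoringSpec",
    "BenthicSpec",
    "CensusSpec",
    "gen_monitoring_series",
    "gen_benthic_samples",
    "gen_iceberg_registry",
]

_STATUSES = ("fasted", "roaming-shelf", "roaming-deep")
_REGIONS = (
    "Weddell Sea", "Ross Sea", "Amundsen Sea", "Bellingshausen Sea",
    "Lazarev Sea", "Cosmonauts Sea", "Davis Sea",
)


@dataclass(frozen=True)
class MonitoringSpec:
    """Shallow-water scour-monitoring generator settings.

    scoured_proportion = clip(intercept - slope * fastice_days + noise, 0, 1).
    Defaults put the noiseless line at 0.9 scoured for an ice-free year
    and 0.05 at 300 fast-ice days.
    """

    intercept: float = 0.9
    slope: float = 0.85 / 300.0        # per fast-ice day
    noise_sd: float = 0.08
    fastice_range: tuple[float, float] = (50.0, 300.0)
    station: str = "SYN-ROTHERA"
    depth_band: str = "5-25"
    start_year: int = 2003

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_monitoring_series(
    n_years: int = 14, seed: int = 0, spec: MonitoringSpec = MonitoringSpec()
) -> pd.DataFrame:
    """Generate an annual fast-ice / scoured-proportion monitoring record.

    Columns: year, fastice_duration (days), scoured_proportion (fraction),
    station, depth_band.  Default length 14 years matches a 2003-onward
    annual monitoring record.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    fastice = rng.uniform(*spec.fastice_range, size=n_years)
    noise = rng.normal(0.0, spec.noise_sd, size=n_years) if spec.noise_sd > 0 else 0.0
    scoured = np.clip(spec.intercept - spec.slope * fastice + noise, 0.0, 1.0)
    return pd.DataFrame(
        {
            "year": np.arange(spec.start_year, spec.start_year + n_years),
            "fastice_duration": fastice,
            "scoured_proportion": scoured,
            "station": spec.station,
            "depth_band": spec.depth_band,
        }
    )


@dataclass(frozen=True)
class BenthicSpec:
    """Depth-zoned benthic-sample generator settings.

    blue_carbon = baseline(depth) + zone_slope * seaice_duration + noise,
    clipped at zero.  Zone slopes default to the built-in ground truth
    (+ in the scour-protected shallows, 0 where effects balance, - at
    shelf depths, 0 in the deepest zone); baseline declines smoothly with
    depth and is large enough that the negative zone-C slope cannot push
    stocks below zero in practice.
    """

    zone_slopes: dict = field(
        default_factory=lambda: {"A": 0.02, "B": 0.0, "C": -0.02, "D": 0.0}
    )
    zone_depths: dict = field(
        default_factory=lambda: {
            "A": (0.0, 10.0), "B": (10.0, 40.0),
            "C": (200.0, 500.0), "D": (500.0, 1000.0),
        }
    )
    noise_sd: float = 0.5
    seaice_range: tuple[float, float] = (50.0, 300.0)
    baseline_scale: float = 25.0
    baseline_efold_m: float = 300.0
    baseline_floor: float = 5.0

    def baseline(self, depth) -> np.ndarray:
        return self.baseline_scale * np.exp(-np.asarray(depth) / self.baseline_efold_m) \
            + self.baseline_floor


def gen_benthic_samples(
    n_per_zone: int = 50, seed: int = 0, spec: BenthicSpec = BenthicSpec()
) -> pd.DataFrame:
    """Generate benthic samples across the depth zones.

    Columns: depth (m), seaice_duration (days yr-1), blue_carbon
    (t C km-2), site.  ``n_per_zone = 0`` returns an empty frame with the
    schema intact.
    """
    if n_per_zone < 0:
        raise ValueError("n_per_zone must be >= 0")
    rng = np.random.default_rng(seed)
    frames = []
    for zone, (lo, hi) in spec.zone_depths.items():
        depth = rng.uniform(lo, hi, size=n_per_zone)
        seaice = rng.uniform(*spec.seaice_range, size=n_per_zone)
        noise = rng.normal(0.0, spec.noise_sd, size=n_per_zone) if spec.noise_sd > 0 else 0.0
        carbon = np.clip(
            spec.baseline(depth) + spec.zone_slopes[zone] * seaice + noise, 0.0, None
        )
        frames.append(
            pd.DataFrame(
                {
                    "depth": depth,
                    "seaice_duration": seaice,
                    "blue_carbon": carbon,
                    "site": [f"SYN-{zone}-{i:03d}" for i in range(n_per_zone)],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out


@dataclass(frozen=True)
class CensusSpec:
    """Giant-iceberg census constraints (March-2017 defaults: 47 / 6 / 4).

    ``mid_band_fraction`` sets how many of the non-large bergs fall in
    the dominant 100-500 km2 band; the generator raises it if needed so
    at least half of ALL bergs land in that band (a hard constraint).
    """

    total: int = 47
    n_large: int = 6           # > 1000 km2
    n_grounded: int = 4
    mid_band_fraction: float = 0.7
    large_range: tuple[float, float] = (1000.0, 5000.0)
    mid_range: tuple[float, float] = (100.0, 500.0)
    small_range: tuple[float, float] = (31.0, 100.0)

    def __post_init__(self) -> None:
        if min(self.total, self.n_large, self.n_grounded) < 0:
            raise ValueError("census counts must be >= 0")
        if self.n_large > self.total or self.n_grounded > self.total:
            raise ValueError(
                "inconsistent census: grounded and large counts cannot exceed total"
            )


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    # iceberg areas are heavy-tailed; log-uniform within each band
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))


def gen_iceberg_registry(
    census: CensusSpec = CensusSpec(), seed: int = 0
) -> pd.DataFrame:
    """Generate a giant-iceberg registry honouring the census exactly.

    Columns: id, area (km2, all > 30), status (fasted | grounded |
    roaming-shelf | roaming-deep), region.  Exactly ``n_large`` areas
    exceed 1000 km2, exactly ``n_grounded`` records are grounded, and at
    least half of all areas fall in the 100-500 km2 band.
    """
    rng = np.random.default_rng(seed)
    if census.total == 0:
        return pd.DataFrame(columns=["id", "area", "status", "region"])

    n_small_total = census.total - census.n_large
    n_mid = max(
        int(round(census.mid_band_fraction * n_small_total)),
        math.ceil(census.total / 2),
    )
    if n_mid > n_small_total:
        raise ValueError(
            "census infeasible: cannot place at least half of all icebergs in "
            "the 100-500 km2 band with the requested large count"
        )
    n_small = n_small_total - n_mid

    areas = np.concatenate(
        [
            _log_uniform(rng, *census.large_range, census.n_large),
            _log_uniform(rng, *census.mid_range, n_mid),
            _log_uniform(rng, *census.small_range, n_small),
        ]
    )
    order = rng.permutation(census.total)
    areas = areas[order]

    status = rng.choice(_STATUSES, size=census.total).astype(object)
    grounded_idx = rng.choice(census.total, size=census.n_grounded, replace=False)
    status[grounded_idx] = "grounded"
    region = rng.choice(_REGIONS, size=census.total)

    return pd.DataFrame(
        {
            "id": [f"SYN-{i + 1:02d}" for i in range(census.total)],
            "area": areas,
            "status": status,
            "region": region,
        }
    )
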