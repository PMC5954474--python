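"""Parameter registry for the iceberg blue-carbon budget.

Every numeric constant used by the budget, scaling, Monte-Carlo and
simulator modules lives here as a :class:`ParamValue` with a point value,
a [low, high] range, units, and a citation anchor recording where the
number comes from.  Downstream modules never hard-code these numbers;
they resolve them through a :class:`ParamSet`, so a user override in a
config file reaches every calculation.

Parameters with no published range carry a degenerate range
(low == point == high); under Monte-Carlo sampling they stay fixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Union

import yaml

__all__ = ["ParamValue", "ParamSet", "load_params", "DEFAULT_PARAMS"]


@dataclass(frozen=True)
class ParamValue:
    """A named constant with its uncertainty range and provenance.

    Attributes
    ----------
    name : str
        Registry key, also the key accepted in config overrides.
    point : float
        Best/point value used in deterministic calculations.
    low, high : float
        Range bounds used by Monte-Carlo sampling; ``low <= point <= high``.
    units : str
        Physical units (e.g. ``"t C yr-1"``); never empty.
    anchor : str
        Short citation string naming where the value comes from.
    provenance : str
        ``"default"`` or ``"overridden"`` (or ``"overridden-out-of-range"``
        for lenient-mode overrides outside the default range).
    """

    name: str
    point: float
    low: float
    high: float
    units: str
    anchor: str
    provenance: str = "default"

    def __post_init__(self) -> None:
        if not (self.low <= self.point <= self.high):
            raise ValueError(
                f"parameter {self.name!r}: require low <= point <= high, "
                f"got low={self.low}, point={self.point}, high={self.high}"
            )
        if not self.units:
            raise ValueError(f"parameter {self.name!r}: units must be non-empty")


def _p(name: str, point: float, units: str, anchor: str,
       low: float | None = None, high: float | None = None) -> ParamValue:
    if low is None:
        low = point
    if high is None:
        high = point
    return ParamValue(name, float(point), float(low), float(high), units, anchor)


#: Default registry.  Point values and ranges follow the published
#: budget; degenerate ranges mean no range was published.
DEFAULT_PARAMS: tuple[ParamValue, ...] = (
    _p("G0", 7e4, "t C yr-1",
       "per new 5000 km2 of open shelf: 'could generate 7 x 10^4 tonnes of "
       "C immobilized per year'"),
    _p("area_ref", 5000.0, "km2",
       "reference giant-iceberg area: 'for each 5000 km^2 iceberg'"),
    _p("g", 2.5, "dimensionless",
       "post-collapse benthic growth multiplier: 'two- to threefold "
       "increases' in sponge density and biomass", low=2.0, high=3.0),
    _p("f", 5.0, "dimensionless",
       "giant-iceberg fertilization multiplier: 'x5-10 for giant iceberg "
       "fertilization'", low=5.0, high=10.0),
    _p("s", 2.0, "dimensionless",
       "sea-ice-loss production multiplier: 'x2 for sea-ice losses'"),
    _p("q", 0.25, "fraction",
       "'up to a quarter of the area of each grounded iceberg scours'; "
       "0.25 used as the maximum proportion grounded"),
    _p("A_g", 10000.0, "km2",
       "total estimated area of grounded giant icebergs (10 000 km2)"),
    _p("n_ground", 8.0, "yr-1",
       "'eight giant icebergs ground per year' (tracking-based estimate)"),
    _p("rho", 16.0, "t C km-2",
       "benthic standing stock near grounded giants: 'hold 8-16 tonnes of "
       "standing stock of carbon per square kilometre'; 16 (the climax "
       "maximum) used for scour cost", low=8.0, high=16.0),
    _p("T_rec", 5.0, "yr",
       "shallow-water recovery time: 'recovery took 4-6 years in the "
       "shallows'; midpoint 5 used", low=4.0, high=6.0),
    _p("p_o", 3.0, "g C m-2 yr-1",
       "approximate mean organic zoobenthic production, 'organic carbon of "
       "3 g C m^-2 yr^-1'"),
    _p("c", 0.12, "fraction",
       "carbon fraction of carbonate production: 'of which only 12% is "
       "carbon'"),
    _p("p_shallow", 13.0, "g C m-2 yr-1",
       "shallow-water production band: 'approximately 13 g C m^-2 yr^-1 in "
       "the shallows'"),
    _p("p_mid", 5.0, "g C m-2 yr-1",
       "mid-shelf production band: 'approximately 5 g C m^-2 yr^-1 at "
       "100-300 m'"),
    _p("p_deep", 1.5, "g C m-2 yr-1",
       "deep-shelf production band: 'approximately 1.5 g C m^-2 yr^-1 "
       "below 300 m depth'"),
    _p("shallow_factor", 2.0, "dimensionless",
       "upper-100 m production 'estimated as equalling the total "
       "(continental shelf) below it': doubling factor"),
    _p("A_s", 4.4e6, "km2",
       "area of Antarctica's continental shelf (4.4 x 10^6 km^2)"),
    _p("I", 10.0, "Mt C yr-1",
       "new production from ice-shelf losses, 'as much as 10 Mt C yr^-1'"),
    _p("g_new", 2.0, "dimensionless",
       "newly ice-shelf-free areas 'two to three times more productive'",
       low=2.0, high=3.0),
    _p("subant", 2.0, "dimensionless",
       "'Doubling our estimate' to cover sub-Antarctic shelf areas"),
    _p("wap_recycle", 8e4, "t C yr-1",
       "WAP shallow scour recycling context: 'an estimated 8 x 10^4 tonnes "
       "of carbon per year'"),
    _p("census_total", 47, "count",
       "giant icebergs 'currently numbering 47 larger than 30 km^2 in "
       "March 2017'"),
    _p("census_large", 6, "count",
       "'including six that exceeded 1000 km^2 in area'"),
    _p("census_grounded", 4, "count",
       "'in early 2017 there were four icebergs (8.5%) larger than "
       "30 km^2 in area grounded'"),
)

_DEFAULTS_BY_NAME = {p.name: p for p in DEFAULT_PARAMS}

ConfigLike = Union[None, str, Path, Mapping[str, object]]


@dataclass
class ParamSet:
    """Immutable-by-convention registry of :class:`ParamValue` by name."""

    params: dict[str, ParamValue] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, p in self.params.items():
            if key != p.name:
                raise ValueError(f"key {key!r} does not match parameter name {p.name!r}")

    def __getitem__(self, name: str) -> ParamValue:
        try:
            return self.params[name]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.params

    def __iter__(self):
        return iter(self.params.values())

    def __len__(self) -> int:
        return len(self.params)

    def point(self, name: str) -> float:
        """Point value of parameter *name*."""
        return self[name].point

    def cite(self, name: str) -> str:
        """Return the stored citation anchor for *name* verbatim."""
        return self[name].anchor

    def overridden(self) -> list[str]:
        """Names whose values differ from the shipped defaults."""
        return [p.name for p in self if p.provenance != "default"]

    def to_dict(self) -> dict[str, dict[str, object]]:
        return {
            p.name: {
                "point": p.point, "low": p.low, "high": p.high,
                "units": p.units, "anchor": p.anchor,
                "provenance": p.provenance,
            }
            for p in self
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Mapping[str, object]]) -> "ParamSet":
        params = {
            name: ParamValue(
                name=name,
                point=float(rec["point"]),
                low=float(rec["low"]),
                high=float(rec["high"]),
                units=str(rec["units"]),
                anchor=str(rec["anchor"]),
                provenance=str(rec.get("provenance", "default")),
            )
            for name, rec in d.items()
        }
        return cls(params)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ParamSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _read_config(config: ConfigLike) -> Mapping[str, object]:
    if config is None:
        return {}
    if isinstance(config, Mapping):
        return config
    text = Path(config).read_text()
    loaded = yaml.safe_load(text)  # YAML superset also parses JSON
    if loaded is None:
        return {}
    if not isinstance(loaded, Mapping):
        raise ValueError(f"config {config} must be a flat key -> value mapping")
    return loaded


def load_params(config: ConfigLike = None, strict: bool = True) -> ParamSet:
    """Load the default registry, applying overrides from *config*.

    Parameters
    ----------
    config : mapping or path, optional
        Flat mapping from parameter name to either a number (overrides the
        point value) or a ``{point, low, high}`` mapping (overrides the
        range too).  A path is read as YAML/JSON.
    strict : bool
        In strict mode an override outside the default [low, high] range is
        rejected; in lenient mode it is accepted and flagged via
        ``provenance = "overridden-out-of-range"``.

    Raises
    ------
    KeyError
        On an override key not present in the default registry.
    ValueError
        On a non-numeric override value, or an out-of-range override in
        strict mode.
    """
    overrides = _read_config(config)
    params = dict(_DEFAULTS_BY_NAME)
    for name, value in overrides.items():
        if name not in params:
            raise KeyError(f"unknown parameter {name!r} in config")
        default = params[name]
        if isinstance(value, Mapping):
            try:
                point = float(value["point"])
            except (KeyError, TypeError, ValueError):
                raise ValueError(
                    f"override for {name!r} must give a numeric 'point'"
                ) from None
            low = float(value.get("low", point))
            high = float(value.get("high", point))
        else:
            try:
                point = float(value)  # type: ignore[arg-type]
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric override for parameter {name!r}: {value!r}"
                ) from None
            low = high = point
        in_range = default.low <= point <= default.high
        if strict and not in_range:
            raise ValueError(
                f"override for {name!r} ({point}) outside default range "
                f"[{default.low}, {default.high}] (strict mode)"
            )
        provenance = "overridden" if in_range else "overridden-out-of-range"
        params[name] = replace(
            default, point=point, low=low, high=high, provenance=provenance
        )
    return ParamSet(params)
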