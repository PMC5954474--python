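"""Circumpolar zoobenthic production scaling: per-area rate to Mt C yr-1.

Scales a mean per-area zoobenthic production rate up to a circumpolar
total through an explicit, replayable ladder of multiplications:

    3 g C m-2 yr-1 organic x (1 + 0.12 carbonate-carbon) -> 3.4 t C km-2 yr-1
    x 2 (shallows estimated to equal the shelf below)     -> 6.8
    x 4.4e6 km2 continental shelf                          -> 30 Mt C yr-1
    x 2 (sea-ice-loss production increases)                -> 60
    + 10 Mt x 2 (new ice-shelf-loss areas, growth-corrected) -> 80
    x 2 (sub-Antarctic shelves)                            -> 160 Mt C yr-1

The unit identity 1 g C m-2 yr-1 == 1 t C km-2 yr-1 is exact (1 g/m2 =
1e6 g/km2 = 1 t/km2) and applied silently.  The reported branch rounds
each rung to two significant figures before it feeds the next, matching
how the published chain is printed; the raw branch keeps exact values.

Also houses the giant-iceberg census fraction statistic (4 of 47
grounded -> 8.5%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .budget import report_round
from .params import ParamSet, load_params

__all__ = [
    "ScalingLadder",
    "areal_rate",
    "include_shallows",
    "shelf_total",
    "scenario_ladder",
    "full_ladder",
    "grounded_fraction",
]

_OPS = {
    "areal_rate": lambda p_o, c: p_o * (1.0 + c),
    "multiply": lambda rate, factor: rate * factor,
    "shelf_total": lambda rate, area: rate * area / 1e6,
    "add_scaled": lambda base, inc, factor: base + inc * factor,
}


@dataclass
class ScalingLadder:
    """Ordered, replayable record of the scaling chain.

    Each rung is ``(label, inputs, op, result)`` where ``op`` names one of
    the primitive operations and ``result`` is what the rung reported.
    ``replay()`` recomputes every rung from its stored inputs and checks
    it reproduces the stored results.
    """

    rungs: list[tuple[str, dict, str, float]] = field(default_factory=list)

    @property
    def final_total(self) -> float:
        if not self.rungs:
            raise ValueError("empty ladder")
        return self.rungs[-1][3]

    def add(self, label: str, inputs: dict, op: str, result: float) -> None:
        if op not in _OPS:
            raise ValueError(f"unknown ladder operation {op!r}")
        self.rungs.append((label, dict(inputs), op, result))

    def replay(self) -> float:
        """Recompute the ladder from stored rung inputs; raises on mismatch."""
        for label, inputs, op, result in self.rungs:
            recomputed = _OPS[op](**{k: v for k, v in inputs.items() if k != "round"})
            if inputs.get("round"):
                recomputed = report_round(recomputed, inputs["round"])
            if recomputed != result:
                raise AssertionError(
                    f"ladder rung {label!r} does not replay: "
                    f"stored {result}, recomputed {recomputed}"
                )
        return self.final_total

    def to_rows(self) -> list[dict]:
        return [
            {"label": label, "op": op, "result": result, **{f"in_{k}": v for k, v in inputs.items()}}
            for label, inputs, op, result in self.rungs
        ]


def areal_rate(p_o: float, c: float) -> tuple[float, float]:
    """Total per-area zoobenthic carbon production, organic plus carbonate.

    Organic production ``p_o`` (g C m-2 yr-1, numerically equal to
    t C km-2 yr-1) is accompanied by an equal mass of carbonate of which
    a fraction ``c`` is carbon, so total = p_o * (1 + c).

    Returns ``(raw, reported)`` with the reported value rounded to two
    significant figures (3 * 1.12 = 3.36 -> 3.4).
    """
    if p_o < 0:
        raise ValueError("p_o must be >= 0")
    if not 0.0 <= c <= 1.0:
        raise ValueError("carbonate carbon fraction c must be in [0, 1]")
    raw = _OPS["areal_rate"](p_o, c)
    return raw, report_round(raw, "nearest-2sf")


def include_shallows(rate: float, factor: float) -> float:
    """Add the under-sampled shallows, estimated as *factor* x the deeper shelf."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return _OPS["multiply"](rate, factor)


def shelf_total(rate: float, area_km2: float) -> tuple[float, float]:
    """Scale a per-km2 rate to a shelf-wide total in Mt C yr-1.

    Returns ``(raw, reported)``; 6.8 t C km-2 yr-1 x 4.4e6 km2 =
    29.92 Mt -> reported 30.
    """
    if rate < 0 or area_km2 < 0:
        raise ValueError("rate and area must be >= 0")
    raw = _OPS["shelf_total"](rate, area_km2)
    return raw, report_round(raw, "nearest-2sf")


def scenario_ladder(
    base: float, s: float, I: float, g_new: float, subant: float
) -> ScalingLadder:
    """Extend a base shelf total (Mt C yr-1) with the scenario multipliers.

    rung 1: base x s (sea-ice-loss production increases)
    rung 2: rung1 + I x g_new (new ice-shelf-loss areas, growth-corrected)
    rung 3: rung2 x subant (sub-Antarctic shelves)
    """
    if min(base, s, I, g_new, subant) < 0:
        raise ValueError("all scenario inputs must be >= 0")
    ladder = ScalingLadder()
    r1 = _OPS["multiply"](base, s)
    ladder.add("x sea-ice losses", {"rate": base, "factor": s}, "multiply", r1)
    r2 = _OPS["add_scaled"](r1, I, g_new)
    ladder.add(
        "+ ice-shelf-loss production x new-area growth",
        {"base": r1, "inc": I, "factor": g_new},
        "add_scaled",
        r2,
    )
    r3 = _OPS["multiply"](r2, subant)
    ladder.add("x sub-Antarctic shelves", {"rate": r2, "factor": subant}, "multiply", r3)
    return ladder


def full_ladder(params: ParamSet | None = None, reported: bool = True) -> ScalingLadder:
    """Assemble the whole chain from registry parameters.

    With ``reported=True`` (default) each rung feeds the next its
    two-significant-figure value, reproducing the printed chain
    3.4 -> 6.8 -> 30 -> 60 -> 80 -> 160; with ``reported=False`` the raw
    branch is propagated instead (3.36 -> ... -> 159.68).
    """
    if params is None:
        params = load_params()
    mode = "nearest-2sf" if reported else None
    ladder = ScalingLadder()

    def push(label: str, inputs: dict, op: str) -> float:
        result = _OPS[op](**inputs)
        if mode:
            result = report_round(result, mode)
        ladder.add(label, {**inputs, "round": mode}, op, result)
        return result

    r = push(
        "organic + carbonate carbon (t C km-2 yr-1)",
        {"p_o": params.point("p_o"), "c": params.point("c")},
        "areal_rate",
    )
    r = push(
        "x shallows (= shelf below)",
        {"rate": r, "factor": params.point("shallow_factor")},
        "multiply",
    )
    r = push(
        "x shelf area (Mt C yr-1)",
        {"rate": r, "area": params.point("A_s")},
        "shelf_total",
    )
    r = push("x sea-ice losses", {"rate": r, "factor": params.point("s")}, "multiply")
    r = push(
        "+ ice-shelf-loss production x new-area growth",
        {"base": r, "inc": params.point("I"), "factor": params.point("g_new")},
        "add_scaled",
    )
    push("x sub-Antarctic shelves", {"rate": r, "factor": params.point("subant")}, "multiply")
    return ladder


def grounded_fraction(n_grounded: int, n_total: int) -> float:
    """Percentage of censused giants aground, to one decimal (4/47 -> 8.5)."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_grounded <= n_total:
        raise ValueError("require 0 <= n_grounded <= n_total")
    return round(100.0 * n_grounded / n_total, 1)
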