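"""Uncertainty propagation over the registry's parameter ranges.

Parameters are sampled independently (no correlation structure is
published) from either a uniform distribution over [low, high] or a
triangular distribution peaking at the point value.  Models are
evaluated on the raw (unrounded) arithmetic branch per draw, and
summarised as median / central 95% interval / min / max envelopes.

Because every model here is monotone in each parameter separately, the
exact extrema over the parameter box sit at corners of the box;
:func:`propagate` evaluates all corners of the non-degenerate parameters
and attaches the resulting exact bounds alongside the sampled envelope.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .params import ParamSet, load_params

__all__ = ["DrawMatrix", "EnvelopeSummary", "sample_params", "propagate", "MODELS"]


@dataclass
class DrawMatrix:
    """Per-parameter sampled vectors, reproducible from (seed, n, distribution)."""

    n_draws: int
    seed: int
    distribution: str
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.values:
            raise KeyError(f"draw matrix is missing parameter {name!r}")
        return self.values[name]


@dataclass(frozen=True)
class EnvelopeSummary:
    """Sampled envelope of one output quantity, plus exact corner bounds."""

    name: str
    median: float
    q025: float
    q975: float
    vmin: float
    vmax: float
    corner_low: float
    corner_high: float

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "median": self.median,
            "q025": self.q025,
            "q975": self.q975,
            "min": self.vmin,
            "max": self.vmax,
            "corner_low": self.corner_low,
            "corner_high": self.corner_high,
        }


def sample_params(
    params: ParamSet | None = None,
    n: int = 10_000,
    seed: int = 0,
    distribution: str = "uniform",
) -> DrawMatrix:
    """Draw *n* independent samples of every registry parameter.

    Degenerate ranges (low == high) yield constant vectors, so parameters
    without a published range stay fixed at their point value.
    Triangular draws peak at the point value.
    """
    if params is None:
        params = load_params()
    if n < 1:
        raise ValueError(f"need at least one draw, got n={n}")
    if distribution not in ("uniform", "triangular"):
        raise ValueError(f"unknown distribution {distribution!r}")
    rng = np.random.default_rng(seed)
    values: dict[str, np.ndarray] = {}
    for p in params:
        if p.low == p.high:
            values[p.name] = np.full(n, p.point)
        elif distribution == "uniform":
            values[p.name] = rng.uniform(p.low, p.high, size=n)
        else:
            values[p.name] = rng.triangular(p.low, p.point, p.high, size=n)
    return DrawMatrix(n_draws=n, seed=seed, distribution=distribution, values=values)


# ---------------------------------------------------------------------------
# Models: mapping from a parameter lookup to named raw output quantities.
# Each model is monotone in every parameter it reads, which is what makes
# the corner-bound computation exact.

def _budget_outputs(v: Mapping[str, object]) -> dict[str, object]:
    """Raw two-iceberg budget: generation, cost, net (t C yr-1)."""
    generation = 2.0 * np.asarray(v["G0"]) * np.asarray(v["g"]) * np.asarray(v["f"])
    cost = np.asarray(v["q"]) * np.asarray(v["A_g"]) * np.asarray(v["rho"])
    return {
        "generation_raw": generation,
        "cost_raw": cost,
        "net_raw": generation - cost,
    }


def _ladder_outputs(v: Mapping[str, object]) -> dict[str, object]:
    """Raw circumpolar ladder final total (Mt C yr-1)."""
    rate = np.asarray(v["p_o"]) * (1.0 + np.asarray(v["c"]))
    rate = rate * np.asarray(v["shallow_factor"])
    base = rate * np.asarray(v["A_s"]) / 1e6
    total = (base * np.asarray(v["s"]) + np.asarray(v["I"]) * np.asarray(v["g_new"])) \
        * np.asarray(v["subant"])
    return {"circumpolar_total_raw": total}


MODELS: dict[str, tuple[Callable, tuple[str, ...]]] = {
    "budget": (_budget_outputs, ("G0", "g", "f", "q", "A_g", "rho")),
    "ladder": (
        _ladder_outputs,
        ("p_o", "c", "shallow_factor", "A_s", "s", "I", "g_new", "subant"),
    ),
}


def _corner_bounds(
    fn: Callable, names: tuple[str, ...], params: ParamSet
) -> dict[str, tuple[float, float]]:
    """Exact output bounds by evaluating all corners of the parameter box.

    Only parameters with non-degenerate ranges contribute corners.
    Valid for coordinate-wise monotone models (all models here).
    """
    varying = [n for n in names if params[n].low < params[n].high]
    if len(varying) > 16:
        raise ValueError("too many varying parameters for corner enumeration")
    fixed = {n: params[n].point for n in names if n not in varying}
    outputs: dict[str, list[float]] = {}
    for corner in itertools.product(*[(params[n].low, params[n].high) for n in varying]) or [()]:
        point = {**fixed, **dict(zip(varying, corner))}
        for key, val in fn(point).items():
            outputs.setdefault(key, []).append(float(val))
    return {key: (min(vals), max(vals)) for key, vals in outputs.items()}


def propagate(
    model: str, draws: DrawMatrix, params: ParamSet | None = None
) -> dict[str, EnvelopeSummary]:
    """Push a draw matrix through a model; envelope per output quantity.

    ``model`` is ``"budget"`` (two-iceberg generation/cost/net) or
    ``"ladder"`` (circumpolar total).  Raises ``KeyError`` naming any
    parameter the model reads that the draw matrix lacks.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {sorted(MODELS)}")
    if params is None:
        params = load_params()
    fn, names = MODELS[model]
    vectors = {name: draws[name] for name in names}  # KeyError if missing
    raw_outputs = fn(vectors)
    bounds = _corner_bounds(fn, names, params)
    summaries: dict[str, EnvelopeSummary] = {}
    for key, vec in raw_outputs.items():
        vec = np.asarray(vec, dtype=float)
        lo, hi = bounds[key]
        summaries[key] = EnvelopeSummary(
            name=key,
            median=float(np.median(vec)),
            q025=float(np.quantile(vec, 0.025)),
            q975=float(np.quantile(vec, 0.975)),
            vmin=float(vec.min()),
            vmax=float(vec.max()),
            corner_low=lo,
            corner_high=hi,
        )
    return summaries
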