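"""Budget model: significant-figure reporting, generation chain, cost, net."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bergcarbon import (
    IcebergScenario,
    generation_per_iceberg,
    net_budget,
    report_round,
    scour_cost,
)


@pytest.mark.parametrize("value, mode, expected", [
    (1.75e5, "nearest-1sf", 2e5),
    (8.75e5, "nearest-1sf", 9e5),     # single-pass rounding differs from chain
    (1.96e6, "truncate-2sf", 1.9e6),
    (29.92, "nearest-2sf", 30.0),
    (3.36, "nearest-2sf", 3.4),
    (0.0, "nearest-1sf", 0.0),
    (0.0, "truncate-2sf", 0.0),
    (0.0, "nearest-2sf", 0.0),
])
def test_report_round_examples(value, mode, expected):
    assert report_round(value, mode) == pytest.approx(expected)


def test_report_round_rejects_negative_and_unknown_mode():
    with pytest.raises(ValueError, match="non-negative"):
        report_round(-1.0, "nearest-1sf")
    with pytest.raises(ValueError, match="unknown rounding mode"):
        report_round(1.0, "nearest-3sf")


@settings(max_examples=200, deadline=None)
@given(
    value=st.floats(min_value=1e-6, max_value=1e12, allow_nan=False),
    mode=st.sampled_from(["nearest-1sf", "truncate-2sf", "nearest-2sf"]),
)
def test_report_round_idempotent(value, mode):
    once = report_round(value, mode)
    assert report_round(once, mode) == once


def test_generation_chain_sequential_rounding(params):
    one = IcebergScenario(n_icebergs=1)
    raw, reported, steps = generation_per_iceberg(one, params)
    assert raw == pytest.approx(8.75e5)
    assert reported == pytest.approx(1e6)
    # the intermediate reported value is 2e5, not round(raw)
    assert steps[1][2] == pytest.approx(2e5)


def test_generation_growth_only(params):
    sc = IcebergScenario(n_icebergs=1, apply_fertilization=False)
    raw, reported, _ = generation_per_iceberg(sc, params)
    assert raw == pytest.approx(1.75e5)
    assert reported == pytest.approx(2e5)


def test_generation_zero_area(params):
    raw, reported, _ = generation_per_iceberg(
        IcebergScenario(n_icebergs=1, area_km2=0.0), params
    )
    assert raw == 0.0 and reported == 0.0


def test_generation_linear_in_area_and_count(params):
    raw1, _, _ = generation_per_iceberg(IcebergScenario(n_icebergs=1), params)
    raw2, _, _ = generation_per_iceberg(
        IcebergScenario(n_icebergs=1, area_km2=10000), params
    )
    assert raw2 == pytest.approx(2 * raw1)
    b2 = net_budget(IcebergScenario(n_icebergs=2), params)
    b1 = net_budget(IcebergScenario(n_icebergs=1), params)
    assert b2.generation_raw == pytest.approx(2 * b1.generation_raw)


@pytest.mark.parametrize("q, area, rho, expected", [
    (0.25, 10_000, 16, 4e4),
    (0.25, 2816, 16, 11_264),   # A23A (1760) + B22A (1056) km2 footprint
    (0.25, 5000, 0, 0.0),
])
def test_scour_cost_examples(q, area, rho, expected):
    assert scour_cost(q, area, rho) == pytest.approx(expected)


def test_scour_cost_rejects_bad_fraction():
    with pytest.raises(ValueError, match="q must be in"):
        scour_cost(1.5, 1000, 16)


def test_net_budget_two_icebergs_defaults(params):
    result = net_budget(params=params)
    assert result.generation_reported == pytest.approx(2e6)
    assert result.cost_reported == pytest.approx(4e4)
    assert result.net_reported == pytest.approx(1.9e6)
    assert result.net_raw == result.generation_raw - result.cost_raw


def test_net_budget_one_iceberg_raw_difference(params):
    result = net_budget(IcebergScenario(n_icebergs=1), params)
    assert result.net_raw == pytest.approx(8.75e5 - 4e4)


def test_net_budget_zero_cost_equals_generation():
    from bergcarbon import load_params
    ps = load_params({"q": {"point": 0.0, "low": 0.0, "high": 0.0}}, strict=False)
    result = net_budget(params=ps)
    assert result.cost_raw == 0.0
    assert result.net_reported == result.generation_reported


def test_ledger_replay_reproduces_reported_generation(params):
    result = net_budget(params=params)
    # per-iceberg chain: re-apply nearest-1sf to each step's raw input chain
    per_steps = [s for s in result.steps if s[0].startswith("per-iceberg")]
    reported = report_round(per_steps[0][1], "nearest-1sf")
    g = params.point("g")
    f = params.point("f")
    reported = report_round(reported * g, "nearest-1sf")
    reported = report_round(reported * f, "nearest-1sf")
    n = 2
    assert n * reported == result.generation_reported


@settings(max_examples=100, deadline=None)
@given(
    g=st.floats(min_value=1.0, max_value=5.0),
    f=st.floats(min_value=1.0, max_value=20.0),
    area=st.floats(min_value=0.0, max_value=50_000.0),
)
def test_generation_raw_monotone_in_inputs(g, f, area):
    from bergcarbon import load_params
    base_ps = load_params(
        {"g": {"point": g, "low": g, "high": g},
         "f": {"point": f, "low": f, "high": f}},
        strict=False,
    )
    more_ps = load_params(
        {"g": {"point": g + 0.5, "low": g + 0.5, "high": g + 0.5},
         "f": {"point": f, "low": f, "high": f}},
        strict=False,
    )
    sc = IcebergScenario(n_icebergs=1, area_km2=area)
    raw_base, _, _ = generation_per_iceberg(sc, base_ps)
    raw_more, _, _ = generation_per_iceberg(sc, more_ps)
    assert raw_more >= raw_base
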