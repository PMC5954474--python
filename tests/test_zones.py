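"""Depth-zoned correlation analysis and fast-ice/scour fit."""

import math

import numpy as np
import pandas as pd
import pytest

from bergcarbon import (
    classify_depth_zone,
    fastice_scour_fit,
    gen_benthic_samples,
    gen_monitoring_series,
    pearson,
    zone_correlations,
)
from bergcarbon.synthetic import MonitoringSpec


class TestPearson:
    def test_perfect_positive_linear(self):
        x = np.arange(5.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_negative_linear(self):
        x = np.arange(5.0)
        r, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_product_moment(self):
        r, _ = pearson([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)

    def test_zero_variance_flagged_not_raised(self):
        r, p = pearson([1, 2, 3], [5, 5, 5])
        assert math.isnan(r) and math.isnan(p)

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson([1, 2], [3, 4])

    def test_matches_product_moment_formula_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            r, _ = pearson(x, y)
            xc, yc = x - x.mean(), y - y.mean()
            direct = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            assert r == pytest.approx(direct, abs=1e-12)


class TestDepthZones:
    @pytest.mark.parametrize("depth, zone", [
        (0.0, "A"), (5.0, "A"), (9.999, "A"),
        (10.0, "B"), (39.9, "B"),
        (40.0, "ignorance"), (100.0, "ignorance"), (199.9, "ignorance"),
        (200.0, "C"), (300.0, "C"), (499.9, "C"),
        (500.0, "D"), (1000.0, "D"),
        (1000.1, "out-of-range"),
    ])
    def test_boundaries_half_open_lower_inclusive(self, depth, zone):
        assert classify_depth_zone(depth) == zone

    def test_partition_of_depth_axis(self):
        # every depth in [0, 1000] maps to exactly one zone
        for depth in np.linspace(0, 1000, 2001):
            assert classify_depth_zone(float(depth)) in (
                "A", "B", "ignorance", "C", "D")

    def test_negative_depth_raises(self):
        with pytest.raises(ValueError):
            classify_depth_zone(-1.0)

    def test_custom_bounds(self):
        assert classify_depth_zone(45.0, bounds=(10, 50, 200, 500, 1000)) == "B"


class TestZoneCorrelations:
    def test_generator_ground_truth_recovered(self):
        df = gen_benthic_samples(n_per_zone=50, seed=0)
        signs = {z.zone: z.sign for z in zone_correlations(df)}
        assert signs["A"] == "positive"
        assert signs["B"] == "none"
        assert signs["C"] == "negative"
        assert signs["D"] == "none"
        assert signs["ignorance"] == "insufficient"

    def test_constant_carbon_in_zone_flagged_insufficient(self):
        df = pd.DataFrame({
            "depth": [5.0] * 10,
            "seaice_duration": np.linspace(50, 300, 10),
            "blue_carbon": [7.0] * 10,
        })
        (result,) = [z for z in zone_correlations(df) if z.zone == "A"]
        assert result.sign == "insufficient"

    def test_mirrored_pattern_cancels_to_none(self):
        # an A-like positive trend concatenated with its mirror image
        ice = np.linspace(50, 300, 40)
        up = 5 + 0.02 * ice
        down = 5 + 0.02 * (350 - ice)
        df = pd.DataFrame({
            "depth": [5.0] * 80,
            "seaice_duration": np.concatenate([ice, ice]),
            "blue_carbon": np.concatenate([up, down]),
        })
        (result,) = [z for z in zone_correlations(df) if z.zone == "A"]
        assert result.sign == "none"
        assert result.r == pytest.approx(0.0, abs=1e-12)

    def test_small_zones_insufficient(self):
        df = pd.DataFrame({
            "depth": [5.0, 6.0],
            "seaice_duration": [100.0, 200.0],
            "blue_carbon": [5.0, 6.0],
        })
        (result,) = [z for z in zone_correlations(df) if z.zone == "A"]
        assert result.sign == "insufficient" and result.n == 2

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            zone_correlations(pd.DataFrame(
                columns=["depth", "seaice_duration", "blue_carbon"]))


class TestFastIceScourFit:
    def test_noiseless_generator_gives_exact_negative_line(self):
        spec = MonitoringSpec(noise_sd=0.0)
        df = gen_monitoring_series(n_years=10, seed=0, spec=spec)
        fit = fastice_scour_fit(df)
        assert fit.r == pytest.approx(-1.0)
        assert fit.slope == pytest.approx(-spec.slope)
        assert fit.intercept == pytest.approx(spec.intercept)

    def test_default_generator_strongly_negative(self):
        fit = fastice_scour_fit(gen_monitoring_series(n_years=14, seed=0))
        assert fit.r < -0.7
        assert fit.p < 0.05

    def test_constant_proportion_flagged_undefined(self):
        df = pd.DataFrame({
            "fastice_duration": [100.0, 200.0, 300.0],
            "scoured_proportion": [0.2, 0.2, 0.2],
        })
        fit = fastice_scour_fit(df)
        assert math.isnan(fit.r)

    def test_single_year_refused(self):
        df = gen_monitoring_series(n_years=1, seed=0)
        with pytest.raises(ValueError, match="at least 3"):
            fastice_scour_fit(df)
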