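"""Synthetic-section generator: exact ground truth, pipeline closure, BGM validation."""

import math

import numpy as np
import pytest

from barkcarbon import (
    BarkDomainError,
    MORPHOLOGY_PRESETS,
    SyntheticSectionSpec,
    bfi_dm,
    make_section,
    simulate_gauge,
    to_profile,
    validate_bgm,
)
from barkcarbon.simulate import _breakpoints


def piecewise_trapezoid(section, func, panels_per_degree=728):
    """Independent trapezoid oracle aligned to fissure edges, ~2x truth resolution."""
    pts = _breakpoints(section.fissures)
    total = 0.0
    eps = 1e-9  # keep evaluation strictly inside each smooth piece
    for a, b in zip(pts[:-1], pts[1:]):
        if b - a <= 2 * eps:
            continue
        m = max(8, int(round((b - a) * panels_per_degree)))
        grid = np.linspace(a + eps, b - eps, m + 1)
        total += float(np.trapezoid(func(grid), grid))
    return total


def rect_spec(wood_radius=10.0, bt_max=2.0, depth=1.2, halfwidth=15.0, n=3, seed=42,
              shape="rectangular"):
    return SyntheticSectionSpec(
        wood_radius=wood_radius, bt_max=bt_max, n_fissures=n,
        fissure_depth_range=(depth, depth), fissure_halfwidth_range=(halfwidth, halfwidth),
        fissure_shape=shape, seed=seed,
    )


class TestMakeSection:
    def test_unfissured_section(self):
        spec = SyntheticSectionSpec(
            wood_radius=10.0, bt_max=2.0, n_fissures=0,
            fissure_depth_range=(0.0, 0.0), fissure_halfwidth_range=(1.0, 1.0), seed=1,
        )
        section = make_section(spec)
        assert section.true_bfi_area == pytest.approx(1.0, abs=1e-12)
        assert section.true_bfi_thickness == pytest.approx(1.0, abs=1e-12)
        assert np.all(section.thickness(np.linspace(0, 360, 100)) == 2.0)

    def test_rectangular_closed_form_mean(self):
        """Mean thickness of a step profile: bt_max - depth * angular fraction."""
        spec = rect_spec(depth=1.2, halfwidth=15.0, n=3)
        section = make_section(spec)
        frac = 3 * 30.0 / 360.0
        assert section.true_bfi_thickness == pytest.approx(
            (2.0 - 1.2 * frac) / 2.0, rel=1e-12
        )
        var = frac * (1 - frac) * 1.2**2
        assert section.sd_bt == pytest.approx(math.sqrt(var), rel=1e-9)

    def test_triangular_closed_form_mean(self):
        """Triangular notches remove half the rectangular deficit."""
        spec = rect_spec(depth=1.2, halfwidth=15.0, n=3, shape="triangular")
        section = make_section(spec)
        frac = 3 * 30.0 / 360.0
        assert section.true_bfi_thickness == pytest.approx(
            (2.0 - 0.5 * 1.2 * frac) / 2.0, rel=1e-12
        )

    def test_solid_area_closed_form_rectangular(self):
        """Polar solid area: annulus minus per-fissure deficit, in closed form."""
        rw, b, d, w_deg = 10.0, 2.0, 1.2, 15.0
        section = make_section(rect_spec(rw, b, d, w_deg, n=3))
        w = math.radians(2 * w_deg)
        deficit = 3 * w * (rw * d + d * (2 * b - d) / 2.0)
        annulus = math.pi * ((rw + b) ** 2 - rw**2)
        assert section.true_solid_area == pytest.approx(annulus - deficit, rel=1e-12)

    @pytest.mark.parametrize("shape", ["rectangular", "triangular"])
    def test_truth_matches_trapezoid_oracle(self, shape):
        section = make_section(rect_spec(shape=shape, seed=11))
        rw = section.wood_radius
        solid = math.radians(1.0) * piecewise_trapezoid(
            section, lambda t: rw * section.thickness(t) + 0.5 * section.thickness(t) ** 2
        )
        assert section.true_bfi_area == pytest.approx(
            solid / section.annulus, abs=1e-6
        )
        mean = piecewise_trapezoid(section, section.thickness) / 360.0
        assert section.true_bfi_thickness == pytest.approx(mean / section.bt_max, abs=1e-6)

    def test_bit_identical_reproducibility(self):
        a, b = make_section(rect_spec(seed=9)), make_section(rect_spec(seed=9))
        assert a.fissures == b.fissures
        assert a.true_solid_area == b.true_solid_area
        grid = np.linspace(0, 360, 1000)
        assert np.array_equal(a.thickness(grid), b.thickness(grid))

    def test_unsatisfiable_placement_fails_naming_seed(self):
        spec = SyntheticSectionSpec(
            wood_radius=10.0, bt_max=2.0, n_fissures=8,
            fissure_depth_range=(1.0, 1.0), fissure_halfwidth_range=(22.0, 22.0), seed=5,
        )
        with pytest.raises(BarkDomainError, match="seed 5"):
            make_section(spec)

    def test_invalid_specs_rejected(self):
        with pytest.raises(BarkDomainError):
            rect_spec(depth=3.0)  # deeper than the bark
        with pytest.raises(BarkDomainError):
            rect_spec(halfwidth=70.0)  # fissures cannot cover the circumference


class TestThicknessVsAreaBfi:
    def test_thickness_bfi_bounds_area_bfi(self, sections):
        """Radius weighting makes the area ratio the smaller of the two truths."""
        for section in sections.values():
            assert section.true_bfi_thickness >= section.true_bfi_area

    def test_gap_shrinks_for_thin_bark(self):
        thick = make_section(rect_spec(wood_radius=10.0, bt_max=2.0, depth=1.5))
        thin = make_section(rect_spec(wood_radius=40.0, bt_max=2.0, depth=1.5))
        gap_thick = thick.true_bfi_thickness - thick.true_bfi_area
        gap_thin = thin.true_bfi_thickness - thin.true_bfi_area
        assert 0 <= gap_thin < gap_thick

    def test_thin_bark_gap_below_one_percent(self):
        section = make_section(
            rect_spec(wood_radius=30.0, bt_max=1.5, depth=1.0, halfwidth=20.0)
        )
        assert section.bt_max <= section.wood_radius / 20.0
        assert section.true_bfi_thickness - section.true_bfi_area < 0.01


class TestToProfile:
    def test_unfissured_profile_closes_to_one(self):
        spec = SyntheticSectionSpec(
            wood_radius=10.0, bt_max=2.0, n_fissures=0,
            fissure_depth_range=(0.0, 0.0), fissure_halfwidth_range=(1.0, 1.0), seed=1,
        )
        value = bfi_dm(to_profile(make_section(spec), 10)).value
        assert value == pytest.approx(1.0, abs=1e-4)

    def test_digitized_bfi_near_truth(self, sections):
        for section in sections.values():
            value = bfi_dm(to_profile(section, 10)).value
            assert abs(value - section.true_bfi_area) < 0.005

    def test_refinement_improves_accuracy(self, deep_section):
        errs = [
            abs(bfi_dm(to_profile(deep_section, v)).value - deep_section.true_bfi_area)
            for v in (2, 4, 8)
        ]
        assert errs[2] < errs[0]


class TestSimulateGauge:
    def test_unfissured_readings_constant(self):
        spec = SyntheticSectionSpec(
            wood_radius=10.0, bt_max=2.0, n_fissures=0,
            fissure_depth_range=(0.0, 0.0), fissure_halfwidth_range=(1.0, 1.0), seed=1,
        )
        section = make_section(spec)
        rs = simulate_gauge(section, 20, seed=3)
        assert np.all(rs.readings == 2.0)
        biased = simulate_gauge(section, 20, seed=3, bias_cm=0.05)
        assert biased.readings == pytest.approx(rs.readings + 0.05)

    def test_law_of_large_numbers(self, deep_section):
        rs = simulate_gauge(deep_section, 100_000, seed=77)
        expected = deep_section.true_bfi_thickness * deep_section.bt_max
        se = deep_section.sd_bt / math.sqrt(rs.n)
        assert abs(rs.readings.mean() - expected) < 4 * se

    def test_deterministic_given_seed(self, deep_section):
        a = simulate_gauge(deep_section, 50, seed=123)
        b = simulate_gauge(deep_section, 50, seed=123)
        assert np.array_equal(a.readings, b.readings)
        assert np.array_equal(a.positions, b.positions)

    def test_systematic_spacing(self, deep_section):
        rs = simulate_gauge(deep_section, 36, seed=0, scheme="systematic", start_deg=5.0)
        assert rs.positions == pytest.approx((5.0 + np.arange(36) * 10.0) % 360.0)


class TestValidateBgm:
    def test_unfissured_estimates_are_exact(self):
        spec = SyntheticSectionSpec(
            wood_radius=10.0, bt_max=2.0, n_fissures=0,
            fissure_depth_range=(0.0, 0.0), fissure_halfwidth_range=(1.0, 1.0), seed=1,
        )
        df = validate_bgm(spec, [5, 10], replicates=20, seed=8)
        assert df["mean_bfi"].to_numpy() == pytest.approx([1.0, 1.0])
        assert df["sd_bfi"].to_numpy() == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_mean_estimate_matches_truth(self):
        """Random-angle BGM is unbiased for the thickness-ratio BFI."""
        spec = MORPHOLOGY_PRESETS["deep_fissured"]
        section = make_section(spec)
        df = validate_bgm(spec, [10], replicates=200, seed=20210114)
        row = df.iloc[0]
        mc_se = row["sd_bfi"] / math.sqrt(200)
        assert abs(row["mean_bfi"] - section.true_bfi_thickness) < 2 * mc_se

    def test_error_prediction_tracks_simulation(self):
        df = validate_bgm(
            MORPHOLOGY_PRESETS["deep_fissured"], [5, 15, 30],
            replicates=300, seed=20210114,
        )
        rel = df["rel_error_pct"].to_numpy()
        assert rel[0] > rel[1] > rel[2]
        ratio = rel / df["predicted_error_pct"].to_numpy()
        assert np.all((ratio > 1 / 1.5) & (ratio < 1.5))


class TestMorphologyPresets:
    def test_targets_hit_within_band(self, sections):
        """Fixture parameters land on the intended BFI / CV morphology targets."""
        t = {n: s.true_bfi_thickness for n, s in sections.items()}
        cv = {n: s.cv_bt for n, s in sections.items()}
        assert t["deep_fissured"] == pytest.approx(0.67, abs=0.05)
        assert t["smooth"] == pytest.approx(0.95, abs=0.05)
        assert t["scaly_shallow"] == pytest.approx(0.90, abs=0.05)
        assert cv["deep_fissured"] == pytest.approx(36.0, abs=2.0)
        assert cv["fibrous_fissured"] == pytest.approx(38.0, abs=2.0)
        assert cv["smooth"] == pytest.approx(16.0, abs=2.0)
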