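"""Thickness maps, fovea localization, and windowed averaging."""

import numpy as np
import pytest

from octlayers import (
    SurfaceSet,
    average_window,
    composite_layers,
    find_fovea,
    measure_eye,
    simulate_surfaces,
    surfaces_to_thickness,
)
from octlayers.exceptions import FoveaOutOfToleranceError
from octlayers.layers import BASE_LAYERS


def flat_surfaces(profile, gaps_px):
    """Stacked flat surfaces separated by the given pixel gaps."""
    ny, nx = profile.n_bscans, profile.n_ascans_per_bscan
    depths = np.zeros((9, ny, nx))
    depths[0] = 40.0
    for k, g in enumerate(gaps_px):
        depths[k + 1] = depths[k] + g
    return SurfaceSet(depths, profile)


class TestSurfacesToThickness:
    def test_pixel_gap_times_axial_spacing(self, profile):
        two_um = profile.with_overrides(axial_um_per_px=2.0, name="2um")
        surf = flat_surfaces(two_um, [50] + [5] * 7)
        maps = surfaces_to_thickness(surf, two_um)
        assert maps.layers["RNFL"].flat[0] == pytest.approx(100.0)

    def test_identical_surfaces_give_zero_layer(self, profile):
        surf = flat_surfaces(profile, [0, 10, 10, 10, 10, 10, 10, 10])
        maps = surfaces_to_thickness(surf, profile)
        assert (maps.layers["RNFL"] == 0).all()

    def test_total_equals_sum_of_base_layers(self, phantom_spec, profile):
        truth = simulate_surfaces(phantom_spec, profile, seed=8)
        maps = surfaces_to_thickness(truth, profile)
        total = sum(maps.layers[l] for l in BASE_LAYERS)
        np.testing.assert_allclose(total, maps.total, atol=1e-6)

    def test_phantom_gcip_map_matches_generative_field(self, phantom_spec,
                                                       profile):
        truth = simulate_surfaces(phantom_spec, profile, seed=8)
        maps = surfaces_to_thickness(truth, profile)
        # at the grid periphery the pit has no effect: base thickness
        corner = maps.layers["GCIP"][0, 0]
        assert corner == pytest.approx(phantom_spec.thickness_um["GCIP"],
                                       abs=2 * profile.axial_um_per_px)


class TestFindFovea:
    def test_centred_pit_found_at_origin(self, phantom_spec, profile):
        truth = simulate_surfaces(phantom_spec.with_overrides(undulation_um=0.0),
                                  profile, seed=0)
        maps = surfaces_to_thickness(truth, profile)
        fx, fy = find_fovea(maps.total, profile)
        dx, dy, _ = profile.spacing
        assert abs(fx) <= dx * (profile.n_ascans_per_bscan /
                                (profile.n_ascans_per_bscan - 1))
        assert abs(fy) <= dy * (profile.n_bscans / (profile.n_bscans - 1))

    def test_displaced_pit_found_at_displacement(self, profile):
        ny, nx = profile.n_bscans, profile.n_ascans_per_bscan
        x = np.linspace(-3, 3, nx)
        y = np.linspace(-3, 3, ny)
        xx, yy = np.meshgrid(x, y)
        total = 300.0 - 120.0 * np.exp(-(((xx - 0.8) ** 2) + yy**2) / 0.5)
        fx, fy = find_fovea(total, profile)
        assert fx == pytest.approx(0.8, abs=6.0 / (nx - 1) + 1e-9)
        assert fy == pytest.approx(0.0, abs=6.0 / (ny - 1) + 1e-9)

    def test_search_restricted_to_central_2x2mm(self, profile):
        """A deeper minimum at 2.5 mm loses to a pit at 0.5 mm."""
        ny, nx = profile.n_bscans, profile.n_ascans_per_bscan
        x = np.linspace(-3, 3, nx)
        y = np.linspace(-3, 3, ny)
        xx, yy = np.meshgrid(x, y)
        total = (300.0
                 - 100.0 * np.exp(-(((xx - 0.5) ** 2) + yy**2) / 0.05)
                 - 200.0 * np.exp(-(((xx - 2.5) ** 2) + yy**2) / 0.05))
        fx, fy = find_fovea(total, profile)
        dy = 6.0 / (ny - 1)
        assert abs(fx - 0.5) < 0.2 and abs(fy) <= dy / 2 + 1e-9


class TestAverageWindow:
    def test_constant_layer_mean_is_invariant_to_fovea(self, profile):
        gaps = [65.59 / profile.axial_um_per_px] + [4] * 7
        surf = flat_surfaces(profile, gaps)
        maps = surfaces_to_thickness(surf, profile)
        for fovea in [(0.0, 0.0), (0.9, -0.4), (1.0, 1.0)]:
            means = average_window(maps, fovea)
            assert means["RNFL"] == pytest.approx(65.59, abs=1e-9)

    def test_window_membership_enumeration_at_1mm_offset(self, profile, rng):
        """Fovea at (1, 0): mean over exactly the A-scans in x in [-1.5, 3.5]."""
        surf = flat_surfaces(profile, [10] * 8)
        maps = surfaces_to_thickness(surf, profile)
        field = rng.random((profile.n_bscans, profile.n_ascans_per_bscan)) * 50 + 20
        maps.layers["RNFL"] = field
        maps.total = sum(maps.layers[l] for l in BASE_LAYERS)
        x = np.linspace(-3, 3, profile.n_ascans_per_bscan)
        y = np.linspace(-3, 3, profile.n_bscans)
        xx, yy = np.meshgrid(x, y)
        inside = (xx >= -1.5) & (xx <= 3.5) & (np.abs(yy) <= 2.5)
        expected = field[inside].mean()
        got = average_window(maps, (1.0, 0.0))["RNFL"]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_fovea_beyond_tolerance_is_flagged_not_clamped(self, profile):
        surf = flat_surfaces(profile, [10] * 8)
        maps = surfaces_to_thickness(surf, profile)
        with pytest.raises(FoveaOutOfToleranceError):
            average_window(maps, (1.2, 0.0))


class TestComposites:
    def test_arithmetic_of_composites(self):
        base = {l: 10.0 for l in BASE_LAYERS}
        out = composite_layers(base)
        assert out["INL+OPL"] == 20.0
        assert out["ONL+PR"] == 30.0
        assert out["total"] == 80.0

    def test_onlpr_minus_onl_is_photoreceptor_segments(self, rng):
        base = {l: float(rng.uniform(5, 80)) for l in BASE_LAYERS}
        out = composite_layers(base)
        assert out["ONL+PR"] - out["ONL"] == pytest.approx(
            base["IS"] + base["OS"])
        assert out["INL+OPL"] == pytest.approx(base["INL"] + base["OPL"])
        assert out["total"] == pytest.approx(sum(base.values()))

    def test_missing_base_layer_rejected(self):
        base = {l: 10.0 for l in BASE_LAYERS if l != "OPL"}
        with pytest.raises(KeyError):
            composite_layers(base)


class TestTranslationEquivariance:
    def test_shifting_pit_shifts_fovea_same_offset(self, profile):
        ny, nx = profile.n_bscans, profile.n_ascans_per_bscan
        x = np.linspace(-3, 3, nx)
        y = np.linspace(-3, 3, ny)
        xx, yy = np.meshgrid(x, y)
        step = 6.0 / (nx - 1)
        locs = []
        for cx in (0.0, 0.75):
            total = 300.0 - 120.0 * np.exp(-(((xx - cx) ** 2) + yy**2) / 0.5)
            locs.append(find_fovea(total, profile))
        assert locs[1][0] - locs[0][0] == pytest.approx(0.75, abs=2 * step)
        assert locs[1][1] == pytest.approx(locs[0][1], abs=2 * step)

    def test_measure_eye_returns_reported_set(self, phantom_spec, profile):
        truth = simulate_surfaces(phantom_spec, profile, seed=9)
        out = measure_eye(truth, profile)
        assert set(out) == {"mRNFL", "GCIP", "INL", "OPL", "INL+OPL", "ONL",
                            "ONL+PR", "RPE", "total"}
        assert out["INL+OPL"] == pytest.approx(out["INL"] + out["OPL"])
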