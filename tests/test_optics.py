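"""Thin-film optics and the CIE colour chain against closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from noscolor import color as ncolor
from noscolor.dispersion import (DispersionTable, constant_index,
                                 load_dispersion_csv, silicon,
                                 silicon_nitride)
from noscolor.errors import (InputError, ThresholdNotReachedError,
                             UndefinedChromaticityError,
                             WavelengthRangeError)
from noscolor.slide import (CAVITY_PRESETS_NM, SlideConfig, jnd_fraction_scan,
                            simulate_slide_color, sweep_cavity_thickness,
                            sweep_tissue_index)
from noscolor.tmm import Layer, LayerStack, Spectrum, default_grid, tmm_reflectance


# ---------------------------------------------------------------- dispersion

class TestDispersion:
    def test_constant_table_is_constant_everywhere(self):
        table = constant_index(2.0)
        idx = table.complex_index(np.array([400.0, 555.5, 800.0]))
        assert np.allclose(idx, 2.0 - 0.0j)

    def test_linear_midpoint(self):
        table = DispersionTable("m", [500.0, 600.0], [3.0, 4.0], [0.0, 0.2])
        assert table.complex_index(550.0) == pytest.approx(3.5 - 0.1j)

    def test_query_outside_span_raises(self):
        table = DispersionTable("m", [360.0, 830.0], [2.0, 2.0])
        with pytest.raises(WavelengthRangeError):
            table.complex_index(359.0)

    def test_sign_convention_negative_imaginary(self):
        table = constant_index(4.0, k=0.5)
        assert table.complex_index(500.0)[0].imag == pytest.approx(-0.5)

    def test_bundled_tables_cover_visible_grid(self):
        grid = default_grid()
        for table in (silicon(), silicon_nitride()):
            idx = table.complex_index(grid)
            assert np.all(idx.real > 0) and np.all(idx.imag <= 0)

    def test_csv_roundtrip(self, tmp_path):
        path = tmp_path / "disp.csv"
        path.write_text("wavelength_nm,n,k\n400,1.5,0\n800,1.6,0.1\n")
        table = load_dispersion_csv(path, material_id="x")
        assert table.complex_index(600.0)[0] == pytest.approx(1.55 - 0.05j)


# ----------------------------------------------------------------------- TMM

def fresnel_normal(n0, ns):
    return abs((n0 - ns) / (n0 + ns)) ** 2


def airy_reflectance(lam, n0, n1, d, ns):
    """Two-interface closed form for a single lossless layer."""
    r01 = (n0 - n1) / (n0 + n1)
    r12 = (n1 - ns) / (n1 + ns)
    phase = np.exp(-2j * (2 * np.pi * n1 * d / lam))
    r = (r01 + r12 * phase) / (1 + r01 * r12 * phase)
    return np.abs(r) ** 2


class TestTmm:
    def test_index_matched_interface_reflects_nothing(self):
        stack = LayerStack(substrate=constant_index(1.0))
        spec = tmm_reflectance(stack, np.array([500.0, 600.0]))
        assert np.allclose(spec.values, 0.0, atol=1e-14)

    def test_bare_interface_matches_fresnel(self):
        stack = LayerStack(substrate=constant_index(3.0))
        spec = tmm_reflectance(stack, np.array([550.0]))
        assert spec.values[0] == pytest.approx(0.25, abs=1e-12)

    def test_single_layer_matches_airy_closed_form(self):
        lam = np.linspace(400.0, 800.0, 81)
        d = 550.0 / (4 * 2.0)  # quarter-wave at 550 nm for n=2
        stack = LayerStack(substrate=constant_index(3.0),
                           layers=(Layer(constant_index(2.0), d),))
        spec = tmm_reflectance(stack, lam)
        assert np.allclose(spec.values, airy_reflectance(lam, 1.0, 2.0, d, 3.0),
                           atol=1e-9)
        # quarter-wave extremum: R = ((n0 ns - n1^2)/(n0 ns + n1^2))^2
        at_550 = tmm_reflectance(stack, np.array([550.0])).values[0]
        assert at_550 == pytest.approx(((3 - 4) / (3 + 4)) ** 2, abs=1e-12)

    @pytest.mark.parametrize("pol", ["s", "p"])
    def test_oblique_bare_interface_matches_fresnel(self, pol):
        n0, ns, theta0 = 1.0, 1.5, np.deg2rad(30.0)
        theta_s = np.arcsin(n0 * np.sin(theta0) / ns)
        if pol == "s":
            r = (n0 * np.cos(theta0) - ns * np.cos(theta_s)) / (
                n0 * np.cos(theta0) + ns * np.cos(theta_s))
        else:
            r = (ns * np.cos(theta0) - n0 * np.cos(theta_s)) / (
                ns * np.cos(theta0) + n0 * np.cos(theta_s))
        stack = LayerStack(substrate=constant_index(1.5))
        spec = tmm_reflectance(stack, np.array([550.0]), angle_deg=30.0,
                               polarization=pol)
        assert spec.values[0] == pytest.approx(abs(r) ** 2, abs=1e-12)

    def test_zero_thickness_layer_is_identity(self):
        lam = default_grid()
        bare = tmm_reflectance(LayerStack(substrate=silicon()), lam)
        padded = tmm_reflectance(
            LayerStack(substrate=silicon(),
                       layers=(Layer(constant_index(1.8), 0.0),)), lam)
        assert np.allclose(bare.values, padded.values, atol=1e-12)

    @given(st.lists(st.tuples(st.floats(1.1, 4.0), st.floats(0.0, 1.0),
                              st.floats(1.0, 500.0)),
                    min_size=0, max_size=4),
           st.floats(0.0, 75.0))
    def test_energy_bound_for_random_passive_stacks(self, layer_params, angle):
        layers = tuple(Layer(constant_index(n, k), d)
                       for n, k, d in layer_params)
        stack = LayerStack(substrate=silicon(), layers=layers)
        spec = tmm_reflectance(stack, np.linspace(400, 800, 21),
                               angle_deg=angle)
        assert np.all(spec.values >= -1e-12)
        assert np.all(spec.values <= 1 + 1e-9)

    def test_empty_grid_rejected(self):
        with pytest.raises(InputError):
            tmm_reflectance(LayerStack(substrate=silicon()), np.array([]))

    def test_nonfinite_thickness_rejected(self):
        with pytest.raises(InputError):
            Layer(constant_index(2.0), np.inf)


# -------------------------------------------------------------- colour chain

class TestColorChain:
    def test_null_reflectance_gives_zero_xyz(self, slide_config):
        spec = Spectrum(slide_config.wavelengths_nm,
                        np.zeros_like(slide_config.wavelengths_nm))
        t = ncolor.spectrum_to_tristimulus(spec, slide_config.illuminant_spd,
                                           slide_config.cmf)
        assert (t.X, t.Y, t.Z) == (0.0, 0.0, 0.0)

    def test_equal_energy_white_lands_on_neutral_point(self):
        lam = default_grid()
        cmf = ncolor.cie1931_observer().resampled(lam)
        spd = ncolor.illuminant("E", lam)
        t = ncolor.spectrum_to_tristimulus(Spectrum(lam, np.ones_like(lam)),
                                           spd, cmf)
        x, y = t.xy
        assert x == pytest.approx(1 / 3, abs=1e-3)
        assert y == pytest.approx(1 / 3, abs=1e-3)
        assert t.Y == pytest.approx(100.0, abs=1e-9)

    def test_tristimulus_is_linear_in_reflectance(self, slide_config, rng):
        vals = rng.uniform(0, 1, slide_config.wavelengths_nm.size)
        spec = Spectrum(slide_config.wavelengths_nm, vals)
        t1 = ncolor.spectrum_to_tristimulus(spec, slide_config.illuminant_spd,
                                            slide_config.cmf)
        t2 = ncolor.spectrum_to_tristimulus(spec.scaled(0.5),
                                            slide_config.illuminant_spd,
                                            slide_config.cmf)
        assert np.allclose(t2.as_array(), 0.5 * t1.as_array(), rtol=1e-12)

    def test_chromaticity_examples(self):
        assert ncolor.tristimulus_to_xy(ncolor.Tristimulus(1, 1, 1)) == (
            pytest.approx(1 / 3), pytest.approx(1 / 3))
        assert (ncolor.tristimulus_to_xy(ncolor.Tristimulus(2, 2, 2))
                == ncolor.tristimulus_to_xy(ncolor.Tristimulus(1, 1, 1)))
        with pytest.raises(UndefinedChromaticityError):
            ncolor.tristimulus_to_xy(ncolor.Tristimulus(0, 0, 0))

    def test_lab_white_and_black(self):
        white = ncolor.Tristimulus(95.0, 100.0, 108.0)
        wp = ncolor.xyz_to_lab(white, white)
        assert (wp.L, wp.a, wp.b) == (pytest.approx(100.0),
                                      pytest.approx(0.0), pytest.approx(0.0))
        black = ncolor.xyz_to_lab(ncolor.Tristimulus(0, 0, 0), white)
        assert (black.L, black.a, black.b) == (pytest.approx(0.0),
                                               pytest.approx(0.0),
                                               pytest.approx(0.0))

    def test_lab_matches_independent_textbook_formula(self, rng):
        # independent oracle: the rational-constant CIELAB formulation
        def lab_oracle(xyz, white):
            eps, kap = 216.0 / 24389.0, 24389.0 / 27.0
            r = np.asarray(xyz) / np.asarray(white)
            f = np.where(r > eps, np.cbrt(r), (kap * r + 16.0) / 116.0)
            return np.array([116 * f[1] - 16, 500 * (f[0] - f[1]),
                             200 * (f[1] - f[2])])

        white = ncolor.Tristimulus(95.047, 100.0, 108.883)
        for _ in range(50):
            xyz = rng.uniform(0, 110, size=3)
            ours = ncolor.xyz_to_lab(ncolor.Tristimulus(*xyz), white)
            expected = lab_oracle(xyz, white.as_array())
            assert np.allclose(ours.as_array(), expected, atol=1e-9)

    @given(st.tuples(*[st.floats(0, 100) for _ in range(3)]),
           st.tuples(*[st.floats(-60, 60) for _ in range(6)]))
    def test_delta_e_is_a_metric(self, lvals, abvals):
        p = ncolor.LabPoint(lvals[0], abvals[0], abvals[1])
        q = ncolor.LabPoint(lvals[1], abvals[2], abvals[3])
        r = ncolor.LabPoint(lvals[2], abvals[4], abvals[5])
        assert ncolor.delta_e(p, p) == 0.0
        assert ncolor.delta_e(p, q) == ncolor.delta_e(q, p) >= 0.0
        assert (ncolor.delta_e(p, r)
                <= ncolor.delta_e(p, q) + ncolor.delta_e(q, r) + 1e-9)

    def test_delta_e_unit_offset(self):
        p = ncolor.LabPoint(50, 0, 0)
        assert ncolor.delta_e(p, ncolor.LabPoint(51, 0, 0)) == pytest.approx(1.0)

    def test_srgb_white_and_black(self):
        white = ncolor.srgb_to_xyz(ncolor.SRGBColor(1, 1, 1))
        rgb = ncolor.xyz_to_srgb(white)
        assert np.allclose(rgb.as_array(), 1.0, atol=1e-3)
        assert np.allclose(
            ncolor.xyz_to_srgb(ncolor.Tristimulus(0, 0, 0)).as_array(), 0.0)

    def test_srgb_roundtrip_in_gamut(self, rng):
        for _ in range(50):
            rgb = rng.uniform(0.05, 0.95, size=3)
            c = ncolor.SRGBColor(*rgb)
            back = ncolor.xyz_to_srgb(ncolor.srgb_to_xyz(c))
            assert np.allclose(back.as_array(), rgb, atol=1e-6)
            assert not back.clipped


# ------------------------------------------------------------ slide + JND

class TestSlideModel:
    def test_zero_tissue_reproduces_bare_slide(self, slide_config):
        bare = simulate_slide_color(slide_config, 1.0, 0.0)
        also_bare = simulate_slide_color(slide_config, 1.45, 0.0)
        assert np.allclose(bare.spectrum.values, also_bare.spectrum.values)

    def test_index_sweep_moves_the_colour(self, slide_config):
        colors = sweep_tissue_index(slide_config, np.linspace(1.22, 1.47, 6),
                                    tissue_thickness_nm=500.0)
        first, last = colors[0], colors[-1]
        assert ncolor.delta_e(first.lab, last.lab) > 0
        assert first.xy != last.xy

    def test_cavity_presets_give_distinct_colours(self, slide_config):
        colors = sweep_cavity_thickness(slide_config, CAVITY_PRESETS_NM)
        labs = [c.lab for c in colors]
        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                assert ncolor.delta_e(labs[i], labs[j]) > 0

    def test_jnd_zero_threshold_is_zero(self, slide_config):
        res = jnd_fraction_scan(slide_config, 1.37, 500.0, threshold=0.0)
        assert res.delta_min == 0.0

    def test_jnd_bracketing_property(self, slide_config):
        from noscolor.slide import _perturbed_lab

        res = jnd_fraction_scan(slide_config, 1.37, 500.0,
                                parameter="tissue_n", rtol=1e-3)
        base = simulate_slide_color(slide_config, 1.37, 500.0).lab
        for sign, delta in ((+1, res.delta_plus), (-1, res.delta_minus)):
            at = ncolor.delta_e(base, _perturbed_lab(
                slide_config, 1.37, 500.0, "tissue_n", sign * delta))
            below = ncolor.delta_e(base, _perturbed_lab(
                slide_config, 1.37, 500.0, "tissue_n",
                sign * delta * (1 - 5e-3)))
            assert at >= slide_config.jnd_threshold
            assert below < slide_config.jnd_threshold

    def test_jnd_monotone_in_threshold(self, slide_config):
        deltas = [jnd_fraction_scan(slide_config, 1.37, 500.0,
                                    threshold=t).delta_min
                  for t in (1.0, 2.3, 5.0)]
        assert deltas == sorted(deltas)

    def test_jnd_unreachable_threshold_raises(self, slide_config):
        with pytest.raises(ThresholdNotReachedError):
            jnd_fraction_scan(slide_config, 1.37, 500.0, threshold=500.0)
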