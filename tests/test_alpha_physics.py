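"""Alpha range–energy interpolation, material equivalence, gap transmission,
and lineal-energy conversion."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.integrate import solve_ivp

from pbct_microdose import (PMMA_ALPHA_RANGES, Q_VALUE_MEV, AlphaSpectrumModel,
                            DetectorModel, GapGeometry, RangeTable,
                            alpha_event_lineal_energy, equivalent_thickness,
                            interpolate_range, invert_range, residual_energy,
                            sample_alpha_energies, transmission_fraction)
from pbct_microdose.alpha_physics import SILICON_DENSITY


class TestRangeInterpolation:
    @pytest.mark.parametrize("energy, expected", [
        (5.0, 33.0), (6.0, 45.0), (7.0, 58.0), (8.0, 73.0),  # anchors
        (6.5, 51.5),  # midway between the 45 and 58 um anchors
    ])
    def test_anchors_and_linear_interpolation(self, energy, expected):
        assert interpolate_range(energy) == pytest.approx(expected)

    @pytest.mark.parametrize("range_um, expected", [
        (33.0, 5.0), (73.0, 8.0),
        (37.0, 5.0 + 4.0 / 12.0),  # linear inversion between the 33 and 45 um anchors
    ])
    def test_inverse(self, range_um, expected):
        assert invert_range(range_um) == pytest.approx(expected)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            interpolate_range(0.0)
        with pytest.raises(ValueError):
            invert_range(-1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.5, max_value=12.0))
    def test_round_trip_including_extrapolated_region(self, energy):
        r = interpolate_range(energy)
        assert r > 0
        assert invert_range(r) == pytest.approx(energy, rel=1e-9)

    def test_monotone_over_a_fine_grid(self):
        e = np.linspace(0.5, 12.0, 500)
        r = interpolate_range(e)
        assert np.all(np.diff(r) > 0)

    def test_range_table_validation(self):
        with pytest.raises(ValueError):
            RangeTable(anchors=((5.0, 33.0), (6.0, 30.0)))  # range decreases
        with pytest.raises(ValueError):
            RangeTable(density=-1.0)

    def test_range_table_csv_round_trip(self, tmp_path):
        path = tmp_path / "ranges.csv"
        path.write_text("energy_MeV,range_um\n5,33\n6,45\n7,58\n8,73\n")
        table = RangeTable.from_csv(path)
        assert interpolate_range(6.0, table) == pytest.approx(45.0)


class TestEquivalentThickness:
    @pytest.mark.parametrize("args, expected", [
        ((40.0, 0.92, 1.18), 31.0),  # LDPE window expressed in PMMA
        ((40.0, 0.92, 1.00), 37.0),  # ... and in water
    ])
    def test_published_window_equivalences(self, args, expected):
        assert round(equivalent_thickness(*args)) == expected

    def test_identity_for_equal_densities(self):
        assert equivalent_thickness(12.3, 1.18, 1.18) == pytest.approx(12.3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=500.0),
           st.floats(min_value=0.1, max_value=5.0),
           st.floats(min_value=0.1, max_value=5.0))
    def test_round_trip_is_identity(self, t, rho_a, rho_b):
        back = equivalent_thickness(equivalent_thickness(t, rho_a, rho_b), rho_b, rho_a)
        assert back == pytest.approx(t, rel=1e-12)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            equivalent_thickness(-1.0, 1.0, 1.0)


class TestAlphaSpectrumSampling:
    def test_uniform_mean_matches_analytic(self):
        model = AlphaSpectrumModel()
        e = sample_alpha_energies(model, 1_000_000, seed=0)
        se = Q_VALUE_MEV / np.sqrt(12 * e.size)
        assert abs(e.mean() - Q_VALUE_MEV / 2) < 3 * se
        assert np.all(e > 0) and np.all(e <= Q_VALUE_MEV)

    def test_three_body_matches_beta_shape(self):
        model = AlphaSpectrumModel(kind="three_body")
        e = sample_alpha_energies(model, 200_000, seed=1)
        # dN/dE ∝ sqrt(E)·sqrt(e_max − E) is a Beta(1.5, 1.5) on [0, e_max]
        _, p = sps.kstest(e / Q_VALUE_MEV, sps.beta(1.5, 1.5).cdf)
        assert p > 0.01

    def test_empty_deterministic_and_invalid(self):
        model = AlphaSpectrumModel()
        assert sample_alpha_energies(model, 0, seed=0).size == 0
        a = sample_alpha_energies(model, 100, seed=42)
        b = sample_alpha_energies(model, 100, seed=42)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            sample_alpha_energies(model, -1)

    def test_custom_tabulated_respects_support(self):
        grid = np.linspace(0.0, 6.0, 50)
        model = AlphaSpectrumModel(kind="custom_tabulated", e_max=Q_VALUE_MEV,
                                   tabulated=(grid, np.exp(-grid)))
        e = sample_alpha_energies(model, 10_000, seed=2)
        assert np.all(e > 0) and np.all(e <= 6.0)


class TestGapTransmission:
    def test_zero_gap_full_transmission(self):
        assert transmission_fraction(AlphaSpectrumModel(), GapGeometry(0.0)) == 1.0

    def test_uniform_closed_form_at_anchor(self):
        # threshold 5 MeV at the 33 um anchor -> (8.68 - 5)/8.68
        frac = transmission_fraction(AlphaSpectrumModel(), GapGeometry(33.0))
        assert frac == pytest.approx((Q_VALUE_MEV - 5.0) / Q_VALUE_MEV, abs=1e-9)

    def test_blocked_beyond_endpoint_range(self):
        r_max = interpolate_range(Q_VALUE_MEV)
        assert transmission_fraction(AlphaSpectrumModel(), GapGeometry(r_max + 1)) == 0.0

    def test_monotone_non_increasing_in_gap(self):
        gaps = np.linspace(0, 100, 40)
        for model in (AlphaSpectrumModel(), AlphaSpectrumModel(kind="three_body")):
            fracs = [transmission_fraction(model, GapGeometry(g)) for g in gaps]
            assert np.all(np.diff(fracs) <= 1e-12)

    def test_uniform_agrees_with_closed_form_everywhere(self):
        model = AlphaSpectrumModel()
        for gap in np.linspace(1.0, 80.0, 25):
            expected = max(0.0, (Q_VALUE_MEV - invert_range(gap)) / Q_VALUE_MEV)
            assert transmission_fraction(model, GapGeometry(gap)) == pytest.approx(expected, abs=1e-6)

    def test_three_body_agrees_with_monte_carlo(self):
        model = AlphaSpectrumModel(kind="three_body")
        gap = GapGeometry(40.0)
        e = sample_alpha_energies(model, 200_000, seed=3)
        mc = np.mean(interpolate_range(e) > gap.effective_thickness(PMMA_ALPHA_RANGES))
        frac = transmission_fraction(model, gap)
        assert frac == pytest.approx(mc, abs=3 * np.sqrt(frac * (1 - frac) / e.size))

    def test_window_layers_add_mass_thickness(self):
        # a 40 um LDPE window alone is ~31.2 um PMMA-equivalent
        gap = GapGeometry(0.0, window_layers=((40.0, 0.92),))
        assert gap.effective_thickness(PMMA_ALPHA_RANGES) == pytest.approx(31.186, abs=1e-2)


class TestResidualEnergy:
    def test_range_subtraction_at_anchors(self):
        # 73 um range minus a 40 um gap leaves the 33 um / 5 MeV anchor
        assert residual_energy(8.0, GapGeometry(40.0)) == pytest.approx(5.0)

    def test_zero_gap_identity(self):
        assert residual_energy(6.3, GapGeometry(0.0)) == pytest.approx(6.3)

    def test_absorbed_below_threshold(self):
        assert residual_energy(5.0, GapGeometry(50.0)) is None

    def test_range_conservation(self):
        gap = GapGeometry(25.0)
        for e_in in np.linspace(4.0, 8.5, 20):
            e_out = residual_energy(e_in, gap)
            if e_out is None:
                assert interpolate_range(e_in) <= gap.effective_thickness(PMMA_ALPHA_RANGES)
            else:
                assert interpolate_range(e_out) + 25.0 == pytest.approx(
                    interpolate_range(e_in), abs=1e-6)


class TestAlphaLinealEnergy:
    def test_empirical_mode_respects_bounds(self):
        res = alpha_event_lineal_energy(np.full(5000, 6.0), seed=0)
        assert np.all(res.y >= 8.0) and np.all(res.y <= 20.0)

    def test_empirical_invalid_bounds(self):
        with pytest.raises(ValueError):
            alpha_event_lineal_energy(np.array([5.0]), params={"y_lo": 9, "y_hi": 3})

    def test_physics_stopper_definition(self):
        # an alpha stopping inside the SV deposits E over its residual range
        det = DetectorModel()
        e = 2.0
        r_si = interpolate_range(e) * (PMMA_ALPHA_RANGES.density / SILICON_DENSITY)
        assert r_si < det.sv_thickness
        res = alpha_event_lineal_energy(np.array([e]), det, mode="physics")
        assert res.y[0] == pytest.approx(1e3 * e / r_si)

    def test_physics_crosser_matches_slowing_down_integration(self):
        """Energy lost by a crossing alpha must match an independent numeric
        integration of dE/dz = -1/R'(E) through the sensitive volume."""
        det = DetectorModel()
        scale = PMMA_ALPHA_RANGES.density / SILICON_DENSITY

        def dEdz(_, e):
            h = 1e-5
            dr = (interpolate_range(e[0] + h) - interpolate_range(e[0] - h)) / (2 * h)
            return [-1.0 / (dr * scale)]

        for e_in in (6.0, 7.5, 8.5):
            r_si = interpolate_range(e_in) * scale
            assert r_si > det.sv_thickness
            sol = solve_ivp(dEdz, (0.0, det.sv_thickness), [e_in],
                            rtol=1e-10, atol=1e-12, max_step=0.05)
            de_oracle = e_in - sol.y[0, -1]
            res = alpha_event_lineal_energy(np.array([e_in]), det, mode="physics")
            de_impl = res.y[0] * det.mean_chord_length / 1e3
            assert de_impl == pytest.approx(de_oracle, rel=1e-5)

    def test_clipping_flags_events(self):
        res = alpha_event_lineal_energy(np.full(1000, 6.0), mode="empirical",
                                        params={"y_lo": 8, "y_hi": 20, "y_max": 15.0},
                                        seed=1)
        assert res.clipped_count > 0
        assert np.all(res.y <= 15.0)

    def test_detector_validation(self):
        with pytest.raises(ValueError):
            DetectorModel(sv_thickness=-1)
        with pytest.raises(ValueError):
            DetectorModel(mean_chord_length=11.0)
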