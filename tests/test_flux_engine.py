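"""Diffusivities, gradients, fluxes, reaction rates and the ratio summary."""

import numpy as np
import pytest
from scipy import stats

import poreflux as pf
from poreflux.errors import (
    ConfigurationError,
    FluxError,
    GradientError,
    SummaryError,
)
from poreflux.flux_engine import SECONDS_PER_YEAR, seawater_viscosity

from conftest import make_profile

CM2_S = 1e-4 * SECONDS_PER_YEAR  # m2/yr per 1 cm2/s


def d0_table_units(spec, t, s=0.0, p=1.013):
    """d0_infinite_dilution expressed in 1e-6 cm²/s (the table's units)."""
    return pf.d0_infinite_dilution(spec, t, s, p) / CM2_S * 1e6


class TestD0:
    def test_degenerate_slope_gives_temperature_independence(self):
        spec = pf.SoluteSpec("x", 10.0, 0.0, 0.1)
        assert d0_table_units(spec, 0.0) == pytest.approx(10.0)
        assert d0_table_units(spec, 25.0) == pytest.approx(10.0)

    @pytest.mark.parametrize("name", ["nitrate", "nitrite", "ammonium", "oxygen"])
    def test_monotonically_increasing_in_temperature(self, solutes, name):
        spec = solutes[name]
        grid = np.linspace(0, 28, 15)
        vals = [pf.d0_infinite_dilution(spec, t) for t in grid]
        assert np.all(np.diff(vals) > 0)

    def test_nernst_einstein_anchor_at_25C(self, solutes):
        """Independent closed-form oracle: D = R*T*lambda / (z^2 F^2) with the
        limiting equivalent conductivities of NO3- (71.42) and NO2- (71.8)
        S cm^2/mol in water at 25 degC."""
        rt = 8.314462 * 298.15
        f2 = 96485.332**2
        for name, lam in (("nitrate", 71.42), ("nitrite", 71.8)):
            expected = rt * lam / f2 * 1e6  # 1e-6 cm2/s
            got = d0_table_units(solutes[name], 25.0)
            assert got == pytest.approx(expected, rel=0.01)

    @pytest.mark.parametrize(
        "name,temp,expected",
        [
            # published linear-fit table values, 1e-6 cm2/s, pure water
            ("nitrate", 0.0, 9.50),
            ("nitrate", 10.0, 13.38),
            ("nitrate", 25.0, 19.20),
            ("nitrite", 0.0, 9.55),
            ("nitrite", 10.0, 13.45),
            ("nitrite", 25.0, 19.30),
        ],
    )
    def test_matches_published_table_within_one_percent(self, solutes, name, temp, expected):
        assert d0_table_units(solutes[name], temp) == pytest.approx(expected, rel=0.01)

    def test_salinity_and_pressure_reduce_d0(self, solutes):
        fresh = pf.d0_infinite_dilution(solutes["nitrate"], 2.0, 0.0, 1.013)
        marine = pf.d0_infinite_dilution(solutes["nitrate"], 2.0, 35.0, 101.0)
        assert marine < fresh
        assert marine / fresh > 0.85  # viscosity correction is a small effect

    def test_out_of_range_temperature_warns(self, solutes):
        with pytest.warns(UserWarning):
            pf.d0_infinite_dilution(solutes["nitrate"], 35.0)

    def test_viscosity_correlation_pure_water_25C(self):
        # handbook value: 0.8902 cP for pure water at 25 degC
        assert seawater_viscosity(0.0, 25.0, 1.013) == pytest.approx(0.8902, rel=0.01)


class TestSedimentDiffusivity:
    def test_identity_at_unit_porosity(self):
        assert pf.sediment_diffusivity(0.03, 1.0) == pytest.approx(0.03)

    def test_direct_substitution(self):
        # phi = 0.6: Ds = D0 / (1 - ln(0.36))
        assert pf.sediment_diffusivity(1.0, 0.6) == pytest.approx(
            1.0 / (1.0 - np.log(0.36))
        )

    def test_strictly_increasing_in_porosity(self):
        grid = np.linspace(0.05, 1.0, 200)
        vals = [pf.sediment_diffusivity(1.0, p) for p in grid]
        assert np.all(np.diff(vals) > 0)
        assert all(v <= 1.0 for v in vals)

    def test_power_model_alternative(self):
        assert pf.sediment_diffusivity(1.0, 0.7, model="power", m_exponent=3.0) == (
            pytest.approx(0.49)
        )

    def test_invalid_porosity_raises(self):
        with pytest.raises(ConfigurationError):
            pf.sediment_diffusivity(1.0, 0.0)


class TestLocalGradient:
    def test_flat_profile_has_zero_slope(self):
        prof = make_profile([0, 1, 2], nitrate=[5.0, 5.0, 5.0])
        g = pf.local_gradient(prof, "nitrate", [0, 1, 2])
        assert g.slope == pytest.approx(0.0)

    def test_exact_line_with_unit_conversion(self):
        # (0 cm, 0 µM), (1 cm, 1 µM), (2 cm, 2 µM): 1 µM/cm = 100 mmol m-4
        # (the 0 µM point is below detection and enters the fit as 0)
        prof = make_profile([0, 1, 2], nitrate=[0.0, 1.0, 2.0])
        g = pf.local_gradient(prof, "nitrate", [0, 1, 2])
        assert g.slope == pytest.approx(100.0)
        assert g.n_censored == 1

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        depths = np.array([10.0, 13.0, 17.0])
        conc = np.array([4.1, 2.9, 2.2]) + rng.normal(0, 0.1, 3)
        prof = make_profile(depths, nitrate=conc)
        g = pf.local_gradient(prof, "nitrate", [0, 1, 2])
        z = depths / 100.0
        a = np.vstack([np.ones(3), z]).T
        beta = np.linalg.solve(a.T @ a, a.T @ conc)
        assert g.slope == pytest.approx(beta[1], rel=1e-10)

    def test_window_must_be_three_consecutive(self):
        prof = make_profile([0, 1, 2, 3], nitrate=[1, 2, 3, 4])
        with pytest.raises(GradientError):
            pf.local_gradient(prof, "nitrate", [0, 2, 3])
        with pytest.raises(GradientError):
            pf.local_gradient(prof, "nitrate", [0, 1])


class TestBoundaryFlux:
    def test_zero_gradient_zero_flux(self):
        f = pf.boundary_flux(0.0, 0.8, 0.01)
        assert f.signed == 0.0 and f.direction == "none"

    def test_direct_substitution(self):
        f = pf.boundary_flux(100.0, 0.8, 0.01)
        assert f.magnitude == pytest.approx(0.8)
        assert f.direction == "upward"

    def test_negative_gradient_is_downward(self):
        assert pf.boundary_flux(-50.0, 0.7, 0.01).direction == "downward"

    def test_linearity_in_concentration(self):
        f1 = pf.boundary_flux(42.0, 0.7, 0.02)
        f2 = pf.boundary_flux(84.0, 0.7, 0.02)
        assert f2.magnitude == pytest.approx(2 * f1.magnitude)


class TestNetReactionRate:
    def test_linear_profile_has_zero_rate(self, solutes):
        prof = make_profile([0, 10, 20, 30], nitrite=[1.0, 2.0, 3.0, 4.0])
        transport = pf.build_transport(prof, solutes)
        r = pf.net_reaction_rate(prof, "nitrite", transport)
        assert np.isnan(r[0]) and np.isnan(r[-1])
        np.testing.assert_allclose(r[1:-1], 0.0, atol=1e-9)

    def test_quadratic_profile_analytic_oracle(self, solutes):
        # C(z) = a z^2 (z in m) => R = -2 a phi Ds at all interior points,
        # including on a non-uniform grid
        a = 30.0
        depths = np.array([0.0, 7.0, 15.0, 26.0, 40.0])
        conc = a * (depths / 100.0) ** 2 + 1.0
        prof = make_profile(depths, nitrite=conc)
        transport = pf.build_transport(prof, solutes)
        r = pf.net_reaction_rate(prof, "nitrite", transport)
        expected = -2 * a * 0.7 * transport.ds["nitrite"][1:-1]
        np.testing.assert_allclose(r[1:-1], expected, rtol=1e-9)

    def test_sign_pattern_reproduces_prescribed_zones(self, gs14, solutes):
        scenario, profile, _, _ = gs14
        transport = pf.build_transport(profile, solutes)
        r = pf.net_reaction_rate(profile, "nitrite", transport)
        z = profile.depth_cm
        inside = lambda lo, hi: (z > lo + 2) & (z < hi - 2)
        assert np.all(r[inside(50, 85)] < 0)  # upper sink
        assert np.all(r[inside(85, 120)] > 0)  # production zone
        assert np.all(r[inside(120, 160)] < 0)  # lower sink


class TestSiteFluxes:
    def test_all_censored_nitrite_gives_zero_ratio(self, solutes):
        prof = make_profile(
            [0, 50, 100, 150, 200],
            nitrate=[20, 10, 5, np.nan, np.nan],
            nitrite=[np.nan] * 5,
        )
        zones = pf.derive_zones(prof, solutes=solutes)
        fx = pf.site_fluxes(prof, zones, solutes)
        assert fx.j_no2_up == 0.0 and fx.j_no2_down == 0.0 and fx.ratio == 0.0
        assert fx.j_no3_in > 0

    def test_missing_window_error_names_the_window(self, solutes):
        prof = make_profile(
            [0, 100, 200],
            nitrate=[20, 10, np.nan],
            nitrite=[0.5, 0.6, 0.7],
        )
        zones = pf.derive_zones(prof, solutes=solutes)
        with pytest.raises(FluxError, match="nitrate window"):
            pf.site_fluxes(prof, zones, solutes)

    def test_ratio_invariant_under_concentration_rescaling(self, gs14, solutes):
        _, profile, _, zones = gs14
        fx = pf.site_fluxes(profile, zones, solutes)
        scale = 7.0
        scaled_series = {
            name: pf.profile_io.SoluteSeries(s.values * scale, s.censored)
            for name, s in profile.solutes.items()
        }
        scaled = pf.DepthProfile(
            site=profile.site,
            depth_cm=profile.depth_cm,
            solutes=scaled_series,
            porosity=profile.porosity,
            detection_limits={k: v * scale for k, v in profile.detection_limits.items()},
        )
        z2 = pf.derive_zones(scaled)
        fx2 = pf.site_fluxes(scaled, z2, solutes)
        assert fx2.ratio == pytest.approx(fx.ratio, rel=1e-9)
        assert fx2.j_no3_in == pytest.approx(scale * fx.j_no3_in, rel=1e-9)

    def test_window_anchor_option_moves_windows_inward(self, gs14, solutes):
        _, profile, _, zones = gs14
        edge = pf.site_fluxes(profile, zones, solutes, window_anchor="edge")
        inner = pf.site_fluxes(profile, zones, solutes, window_anchor="offset1")
        pts_edge = edge.gradient_windows["no2_up"].points
        pts_inner = inner.gradient_windows["no2_up"].points
        assert pts_inner[0][0] > pts_edge[0][0]

    def test_tortuosity_option_scales_fluxes_not_ratio(self, gs14, solutes):
        _, profile, _, zones = gs14
        log_fx = pf.site_fluxes(profile, zones, solutes, tortuosity="log")
        pow_fx = pf.site_fluxes(profile, zones, solutes, tortuosity="power")
        assert pow_fx.j_no3_in != pytest.approx(log_fx.j_no3_in)
        # a single multiplicative Ds change per solute almost cancels in r
        assert pow_fx.ratio == pytest.approx(log_fx.ratio, rel=1e-6)


class TestRatioSummary:
    def _results(self, ratios):
        return [
            pf.FluxResult(
                site_id=f"s{i}",
                j_no3_in=1.0,
                j_no2_up=r / 2,
                j_no2_down=r / 2,
                ratio=r,
                gradient_windows={},
                ds_used={},
            )
            for i, r in enumerate(ratios)
        ]

    def test_zero_variance_gives_zero_halfwidth(self):
        s = pf.ratio_summary(self._results([0.3, 0.3, 0.3]))
        assert s.mean == pytest.approx(0.3)
        assert s.ci95_halfwidth == pytest.approx(0.0)

    def test_textbook_t_interval_oracle(self):
        ratios = [0.1, 0.2, 0.3, 0.4, 0.5]
        s = pf.ratio_summary(self._results(ratios))
        lo, hi = stats.t.interval(
            0.95, len(ratios) - 1, loc=np.mean(ratios), scale=stats.sem(ratios)
        )
        assert s.mean == pytest.approx(0.3)
        assert s.ci95_halfwidth == pytest.approx((hi - lo) / 2)

    def test_single_site_has_undefined_ci(self):
        s = pf.ratio_summary(self._results([0.4]))
        assert s.mean == pytest.approx(0.4) and s.ci95_halfwidth is None

    def test_empty_list_raises(self):
        with pytest.raises(SummaryError):
            pf.ratio_summary([])

    def test_mean_bounded_by_extremes_and_outliers_flagged(self):
        ratios = [0.1, 0.5, 1.2]
        s = pf.ratio_summary(self._results(ratios))
        assert min(ratios) <= s.mean <= max(ratios)
        assert s.outlier_sites == ("s2",)

    def test_bootstrap_ci_close_to_t(self):
        rng = np.random.default_rng(0)
        ratios = list(rng.normal(0.3, 0.05, size=40))
        t_sum = pf.ratio_summary(self._results(ratios), method="t")
        b_sum = pf.ratio_summary(self._results(ratios), method="bootstrap", seed=1)
        assert b_sum.ci95_halfwidth == pytest.approx(t_sum.ci95_halfwidth, rel=0.2)


class TestSteadyStateConsistency:
    def test_flux_divergence_matches_reaction_rate(self, gs14, solutes):
        """Between adjacent depths, dJ/dz = -phi R on smooth zone interiors."""
        scenario, profile, _, _ = gs14
        transport = pf.build_transport(profile, solutes)
        rate = pf.net_reaction_rate(profile, "nitrite", transport)  # bulk rate
        z_m = profile.depth_m
        phi = 0.7
        ds = transport.ds["nitrite"]
        c = profile.fit_values("nitrite")
        # centred fluxes between samples, interior of the production zone
        idx = np.flatnonzero((profile.depth_cm > 90) & (profile.depth_cm < 115))
        for i in idx:
            j_lo = phi * ds[i] * (c[i] - c[i - 1]) / (z_m[i] - z_m[i - 1])
            j_hi = phi * ds[i] * (c[i + 1] - c[i]) / (z_m[i + 1] - z_m[i])
            div = (j_hi - j_lo) / ((z_m[i + 1] - z_m[i - 1]) / 2)
            assert div == pytest.approx(-rate[i], rel=1e-6)
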