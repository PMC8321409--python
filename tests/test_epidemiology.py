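import numpy as np
import pytest
from scipy.integrate import quad

import abdimer as ab
from abdimer.parameters import DomainError, PRINTED_SCALES
from abdimer.calibration import toxicity_parameters

OMEGA_YR = PRINTED_SCALES["omega_bar_per_year"]  # 9.34e-5 yr^-1


def hazard_with_printed_omega(p, mode="static", **kw):
    """Hazard pinned to the reported omega_bar (rounded at 3 s.f.)."""
    return ab.HazardModel.from_parameters(
        p, mode=mode, U0_per_year=OMEGA_YR / p.gamma, **kw)


class TestXi:
    def test_xi_is_one_at_birth(self, general):
        assert ab.xi(ab.dynamic_schedule(general), 0.0) == 1.0

    def test_xi_at_75(self, general):
        """(1 + 75/154)^2 / (1 - 75/114)^2 = 18.89."""
        assert ab.xi(ab.dynamic_schedule(general), 75.0) == pytest.approx(
            18.89, rel=5e-4)

    def test_static_xi_is_identically_one(self, general):
        sch = ab.static_schedule(general)
        assert np.all(ab.xi(sch, np.array([0.0, 40.0, 80.0])) == 1.0)

    def test_xi_nondecreasing(self, general):
        sch = ab.dynamic_schedule(general)
        t = np.linspace(0, 110, 500)
        assert np.all(np.diff(ab.xi(sch, t)) > 0)

    def test_domain_error_beyond_validity(self, general):
        with pytest.raises(DomainError):
            ab.xi(ab.dynamic_schedule(general), 114.0)


class TestXiIntegral:
    def test_zero_width(self, general):
        assert ab.xi_integral(ab.dynamic_schedule(general), 50.0, 50.0) == 0.0

    def test_static_integral_is_interval_length(self, general):
        assert ab.xi_integral(ab.static_schedule(general), 12.0, 30.5) == \
            pytest.approx(18.5, rel=1e-12)

    def test_late_life_window(self, general):
        val = ab.xi_integral(ab.dynamic_schedule(general), 60.0, 78.5)
        oracle = quad(lambda s: ab.xi(ab.dynamic_schedule(general), s),
                      60.0, 78.5)[0]
        assert val == pytest.approx(oracle, rel=1e-11)
        assert val == pytest.approx(266.7, rel=5e-4)

    @pytest.mark.parametrize("with_toxicity", [False, True])
    def test_closed_form_matches_quadrature(self, general, with_toxicity):
        """The antiderivative agrees with adaptive quadrature to 1e-9
        relative over random windows spanning the validity range."""
        p = toxicity_parameters(general) if with_toxicity else general
        sch = ab.dynamic_schedule(p)
        rng = np.random.default_rng(42)
        pairs = np.sort(rng.uniform(0.0, 110.0, size=(2000, 2)), axis=1)
        for t1, t2 in pairs:
            closed = ab.xi_integral(sch, t1, t2)
            num, _ = quad(lambda s: ab.xi(sch, s), t1, t2, epsrel=1e-12, limit=200)
            assert closed == pytest.approx(num, rel=1e-9, abs=1e-12)


class TestStaticClosedForms:
    def test_constant_incidence(self, general, static_general):
        ages = np.array([10.0, 40.0, 70.0])
        I = static_general.incidence(ages)
        assert np.all(I == I[0])
        assert I[0] == pytest.approx(OMEGA_YR, rel=0.01)

    def test_prevalence_plateau(self, general):
        """P = 1 - e^{-omega T_D} ~ omega T_D = 0.0663% beyond T_D."""
        h = hazard_with_printed_omega(general)
        for age in (7.1, 30.0, 70.0):
            assert 100 * h.prevalence(age, 7.1) == pytest.approx(0.0663, rel=2e-3)

    def test_lifetime_risk_60_to_life_expectancy(self, general):
        h = hazard_with_printed_omega(general)
        risk = h.lifetime_risk(60.0, general.T_L)
        assert 100 * risk == pytest.approx(0.17, rel=2e-2)

    def test_static_solutions_exact(self, general, static_general):
        """V = e^{-U t}, H = e^{-omega t}, Y = 1 - e^{-omega dt} exactly."""
        h = static_general
        t = 48.0
        assert h.viability(t) == pytest.approx(np.exp(-h.U0 * t), rel=1e-12)
        assert h.survivorship(t) == pytest.approx(
            np.exp(-h.omega0 * t), rel=1e-12)
        assert h.lifetime_risk(20.0, 60.0) == pytest.approx(
            1 - np.exp(-40.0 * h.omega0), rel=1e-12)

    def test_viability_and_prevalence_at_birth(self, static_general, dynamic_general):
        for h in (static_general, dynamic_general):
            assert h.viability(0.0) == 1.0
            assert h.prevalence(0.0, 7.1) == 0.0


class TestDynamicCurves:
    def test_incidence_equals_hazard_of_survivorship(self, dynamic_general):
        """I(t) = gamma sigma D = -(d/dt) ln H(t)."""
        h = dynamic_general
        t = np.linspace(5.0, 100.0, 400)
        dt = 1e-4
        lnH = lambda x: -h.gamma * h.cumulative_damage(x)
        numeric = -(lnH(t + dt) - lnH(t - dt)) / (2 * dt)
        assert np.allclose(numeric, h.incidence(t), rtol=1e-6)

    def test_incidence_and_prevalence_strictly_increase(self, dynamic_general):
        t = np.linspace(1.0, 110.0, 300)
        assert np.all(np.diff(dynamic_general.incidence(t)) > 0)
        assert np.all(np.diff(dynamic_general.prevalence(t, 7.1)) > 0)

    def test_hv_annual_change_at_75(self, dynamic_general):
        assert 100 * dynamic_general.hv_annual_change(75.0) == pytest.approx(
            0.29, abs=0.005)

    def test_within_model_hv_ratio(self, dynamic_general):
        ratio = dynamic_general.viability(71.6) / dynamic_general.viability(63.4)
        assert ratio == pytest.approx(0.984, abs=5e-4)

    def test_dynamic_lifetime_risk(self, general, dynamic_general):
        risk = dynamic_general.lifetime_risk(60.0, general.T_L)
        assert 0.024 <= risk <= 0.025

    def test_epi_curves_frame(self, general, dynamic_general):
        curves = ab.epi_curves(dynamic_general, np.arange(0.0, 95.0))
        frame = curves.to_frame()
        assert frame["viability"].iloc[0] == 1.0
        assert np.all(frame["prevalence"].to_numpy() < 1.0)
        assert np.allclose(frame["survivorship"],
                           frame["viability"] ** general.gamma)


class TestDoublingTimes:
    def test_exact_exponential(self):
        ages = np.arange(60.0, 91.0)
        assert ab.doubling_time(ages, 2 ** (ages / 8.0)) == pytest.approx(8.0)

    def test_incidence_doubling_time(self, dynamic_general):
        assert ab.incidence_doubling_time(dynamic_general) == pytest.approx(
            11.0, rel=0.05)

    def test_prevalence_doubling_time(self, dynamic_general):
        assert ab.prevalence_doubling_time(dynamic_general, 7.1) == pytest.approx(
            12.0, rel=0.05)

    def test_flat_curve_returns_infinity(self):
        ages = np.arange(60.0, 91.0)
        assert ab.doubling_time(ages, np.ones_like(ages)) == np.inf

    def test_nonpositive_curve_rejected(self):
        ages = np.arange(60.0, 91.0)
        with pytest.raises(ValueError):
            ab.doubling_time(ages, np.zeros_like(ages))


class TestScenarioRatios:
    def test_identical_scenarios_ratio_one(self, dynamic_general):
        assert ab.scenario_ratio(dynamic_general, dynamic_general,
                                 "prevalence", 70.0, T_D=7.1) == 1.0

    def test_down_general_static_ratio(self, general, down):
        """With the seconds-denominated T_D the static prevalence ratio at
        70 is 2.24 (driven by the squared production ratio 2.25)."""
        omega = PRINTED_SCALES["omega_bar"] * ab.YEAR_SECONDS
        hg = ab.HazardModel.from_parameters(general, mode="static",
                                            U0_per_year=omega / general.gamma)
        hd = ab.HazardModel.from_parameters(
            down, mode="static",
            U0_per_year=omega / general.gamma * (5.45 / 3.63) ** 2)
        T_D = ab.T_D_in_years(general, "seconds")
        assert ab.scenario_ratio(hd, hg, "prevalence", 70.0, T_D=T_D) == \
            pytest.approx(2.24, abs=5e-3)

    def test_down_general_dynamic_ratio_at_80(self, general, down):
        hg = ab.dynamic_hazard(general)
        hd = ab.dynamic_hazard(down)
        T_D = ab.T_D_in_years(general, "seconds")
        ratio = ab.scenario_ratio(hd, hg, "prevalence", 80.0, T_D=T_D)
        assert ratio == pytest.approx(3.15, rel=0.01)

    def test_gene_dosage_lower_bound(self, general, down):
        """Production scaled by Omega multiplies omega0 by Omega^2 exactly;
        with the faster Down production drift the dynamic prevalence ratio
        exceeds Omega^2 = 2.25 at every age."""
        omega2 = (down.S_bar / general.S_bar) ** 2
        hg = ab.dynamic_hazard(general)
        hd = ab.dynamic_hazard(down)
        assert hd.omega0 / hg.omega0 == pytest.approx(omega2, rel=1e-12)
        for age in (40.0, 60.0, 80.0, 100.0):
            r = ab.scenario_ratio(hd, hg, "prevalence", age, T_D=7.1)
            assert r >= omega2

    def test_ad_pathology_cross_model_hv_ratio(self, general):
        """Damage scaled by F = 3.63 at 71.6 vs the unscaled model at 63.4."""
        U0 = PRINTED_SCALES["U_bar"] * ab.YEAR_SECONDS
        base = ab.HazardModel.from_parameters(general, U0_per_year=U0)
        scaled = ab.HazardModel.from_parameters(general, U0_per_year=U0, F=3.63)
        ratio = ab.scenario_ratio(scaled, base, "viability", 71.6, 63.4)
        assert ratio == pytest.approx(0.859, abs=1e-3)
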