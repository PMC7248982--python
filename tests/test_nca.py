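"""NCA checks: terminal-slope selection, trapezoidal areas, full parameter
blocks, extraction ratio and crossover bioavailability."""

import math

import numpy as np
import pytest

from flunipk.nca import (
    LambdaZError,
    NCAResult,
    Route,
    auc_aumc,
    bioavailability,
    cardiac_output,
    extraction_ratio,
    nca_single_profile,
    select_lambda_z,
)
from flunipk.simulate import (
    PLASMA_SCHEDULE_H,
    ConcentrationSeries,
    TruePKParameters,
    simulate_plasma_profile,
    single_dose_regimen,
)
from scipy import stats


def series(times, concs, **kw):
    return ConcentrationSeries("a", "FLU", "plasma", np.asarray(times, float),
                               np.asarray(concs, float), **kw)


class TestLambdaZ:
    def test_exact_monoexponential_recovered(self):
        t = np.array([6.0, 8.0, 12.0, 18.0, 24.0])
        fit = select_lambda_z(series(t, np.exp(-0.2 * t)), Route.IV)
        assert fit.lambda_z == pytest.approx(0.2, rel=1e-12)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-12)

    def test_flat_series_fails_with_diagnostics(self):
        with pytest.raises(LambdaZError):
            select_lambda_z(series([1, 2, 4, 8, 12], [5, 5, 5, 5, 5]), Route.IV)

    def test_biexponential_terminal_slope_near_slow_phase(self):
        # 10 e^{-0.5 t} + 2 e^{-0.1 t} on the IV sampling schedule; oracle =
        # regression on the three latest times where the fast phase is < 0.1%
        t = np.asarray(PLASMA_SCHEDULE_H[1:])  # skip t=0
        c = 10 * np.exp(-0.5 * t) + 2 * np.exp(-0.1 * t)
        fit = select_lambda_z(series(t, c), Route.IV)
        late = t >= 36.0
        oracle = -stats.linregress(t[late][-3:], np.log(c[late][-3:])).slope
        assert fit.lambda_z == pytest.approx(0.1, rel=0.05)
        assert abs(fit.lambda_z - oracle) < 0.05 * oracle + 1e-3

    def test_sc_window_excludes_tmax(self):
        t = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0])
        c = np.array([3.0, 6.0, 5.0, 3.2, 1.4, 0.6, 0.05])
        fit = select_lambda_z(series(t, c), Route.SC)
        assert fit.t_first > 1.0  # strictly after Tmax


class TestAUC:
    def test_flat_interval_uses_linear_trapezoid(self):
        auc, _ = auc_aumc([0.0, 2.0], [1.0, 1.0])
        assert auc == pytest.approx(2.0)

    def test_log_trapezoid_closed_form(self):
        # C 10 -> 5 over 1 h: dAUC = 5/ln 2
        auc, aumc = auc_aumc([0.0, 1.0], [10.0, 5.0])
        k = math.log(2.0)
        assert auc == pytest.approx(5.0 / k, rel=1e-12)
        # first-moment log rule vs adaptive quadrature of the interpolant
        from scipy.integrate import quad
        num, _ = quad(lambda x: x * 10.0 * 2.0 ** -x, 0.0, 1.0, epsabs=1e-12)
        assert aumc == pytest.approx(num, rel=1e-10)

    def test_dense_biexponential_auc_inf_within_half_percent(self):
        t = np.arange(0.0, 60.0, 0.01)
        c = 10 * np.exp(-0.5 * t) + 2 * np.exp(-0.1 * t)
        auc, _ = auc_aumc(t, c)
        auc += c[-1] / 0.1  # analytic tail at the slow rate
        assert auc == pytest.approx(40.0, rel=5e-3)

    def test_negative_concentration_rejected_by_name(self):
        with pytest.raises(ValueError, match="t=2"):
            auc_aumc([0.0, 1.0, 2.0], [3.0, 2.0, -0.1])

    def test_log_down_never_exceeds_linear_trapezoid(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            t = np.sort(rng.uniform(0, 24, size=8))
            t += np.arange(8) * 1e-3  # ensure strictly increasing
            c = np.sort(rng.lognormal(1.0, 1.0, size=8))[::-1]
            auc_ld, _ = auc_aumc(t, c)
            auc_lin = np.trapezoid(c, t)
            assert auc_ld <= auc_lin + 1e-12


class TestFullProfile:
    def test_cmax_tmax_argmax(self):
        res = nca_single_profile(series([1, 2, 4, 8], [5, 9, 6, 2]), 1.1,
                                 Route.SC)
        assert res.cmax_obs * 1000 == pytest.approx(9.0)  # reported in ug/ml
        assert res.tmax_obs == 2.0

    def test_half_life_formula(self):
        assert math.log(2) / 0.21 == pytest.approx(3.3007, abs=1e-4)
        params = TruePKParameters(CL=210.0, V=1000.0)  # k = 0.21
        parent, _ = simulate_plasma_profile(
            params, single_dose_regimen(1.1, "IV"), PLASMA_SCHEDULE_H)
        res = nca_single_profile(parent, 1.1, Route.IV)
        assert res.t_half_z == pytest.approx(3.3007, abs=1e-4)
        assert res.t_half_z * res.lambda_fit.lambda_z == pytest.approx(
            math.log(2), rel=1e-12)

    @pytest.mark.parametrize("cl,v", [(114.0, 444.0), (182.0, 903.0),
                                      (265.0, 1945.0)])
    def test_iv_parameter_recovery_on_study_schedule(self, cl, v):
        params = TruePKParameters(CL=cl, V=v)
        parent, _ = simulate_plasma_profile(
            params, single_dose_regimen(1.1, "IV"), PLASMA_SCHEDULE_H)
        res = nca_single_profile(parent, 1.1, Route.IV)
        assert res.cl_or_clf == pytest.approx(cl, rel=0.05)
        assert res.vz_or_vzf == pytest.approx(v, rel=0.08)
        assert res.t_half_z == pytest.approx(math.log(2) / params.k, rel=0.05)
        assert res.mrt_inf * res.auc_inf == pytest.approx(res.aumc_inf,
                                                          rel=1e-12)

    def test_rich_sampling_recovery_within_two_percent(self, lactating_params):
        k = lactating_params.k
        t = np.arange(0.0, 10 * math.log(2) / k, 0.25)
        parent, _ = simulate_plasma_profile(
            lactating_params, single_dose_regimen(1.1, "IV"), t)
        res = nca_single_profile(parent, 1.1, Route.IV)
        assert res.cl_or_clf == pytest.approx(lactating_params.CL, rel=0.02)
        assert res.vz_or_vzf == pytest.approx(lactating_params.V, rel=0.02)
        assert res.mrt_inf == pytest.approx(1.0 / k, rel=0.02)

    def test_partial_result_when_terminal_fit_fails(self):
        res = nca_single_profile(series([1, 2, 4], [5, 5, 5]), 1.1, Route.IV)
        assert res.lambda_fit is None
        assert math.isnan(res.cl_or_clf)
        assert res.cmax_obs * 1000 == pytest.approx(5.0)
        assert res.warnings

    def test_vss_reported_for_iv_only(self, lactating_params):
        parent, _ = simulate_plasma_profile(
            lactating_params, single_dose_regimen(1.1, "SC"), PLASMA_SCHEDULE_H)
        res = nca_single_profile(parent, 1.1, Route.SC)
        assert math.isnan(res.vss) and math.isnan(res.e_body)


class TestExtractionRatio:
    def test_unit_body_weight(self):
        assert cardiac_output(1.0) == pytest.approx(180.0)

    def test_allometric_value_at_76_kg(self):
        assert cardiac_output(76.0) == pytest.approx(79.05, abs=0.01)

    def test_identity_when_cl_equals_cardiac_output(self):
        bw = 85.0
        cl = 60.0 * cardiac_output(bw)  # same units, ml/kg/h
        assert extraction_ratio(cl, bw) == pytest.approx(1.0, rel=1e-12)

    def test_sc_clearance_rejected(self):
        with pytest.raises(ValueError, match="systemic"):
            extraction_ratio(200.0, 85.0, route=Route.SC)

    def test_dimensionless_in_dose_mass_unit(self, lactating_params):
        # doubling the dose scales AUC and leaves CL, hence E_body, unchanged
        parent, _ = simulate_plasma_profile(
            lactating_params, single_dose_regimen(1.1, "IV"), PLASMA_SCHEDULE_H)
        r1 = nca_single_profile(parent, 1.1, Route.IV, body_weight=85.0)
        doubled = ConcentrationSeries("a", "FLU", "plasma", parent.times,
                                      2 * parent.concs)
        r2 = nca_single_profile(doubled, 2.2, Route.IV, body_weight=85.0)
        assert r1.e_body == pytest.approx(r2.e_body, rel=1e-9)


class TestBioavailability:
    @staticmethod
    def result(animal, route, auc_inf):
        return NCAResult(animal_id=animal, route=route, dose_mg_kg=1.1,
                         cmax_obs=1.0, tmax_obs=1.0, clast_obs=0.1,
                         tlast_obs=48.0, auc_last=auc_inf * 0.99,
                         auc_inf=auc_inf)

    def test_identical_aucs_give_unity(self):
        pair = bioavailability(self.result("g1", Route.SC, 5.0),
                               self.result("g1", Route.IV, 5.0))
        assert pair.f == pytest.approx(1.0)

    def test_mean_auc_ratio_differs_from_mean_of_ratios(self):
        # ratio of group-mean AUCs: 8.806/9.880 = 0.8913, which is not the
        # mean of per-animal ratios in general
        pair = bioavailability(self.result("g1", Route.SC, 8.806),
                               self.result("g1", Route.IV, 9.880))
        assert pair.f == pytest.approx(0.8913, abs=1e-4)

    def test_mismatched_animals_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            bioavailability(self.result("g1", Route.SC, 5.0),
                            self.result("g2", Route.IV, 5.0))

    def test_crossover_recovery_with_noise(self):
        # full-cohort version lives in the acceptance suite; here one animal
        from flunipk.simulate import AssayNoiseModel, apply_assay_noise
        params = TruePKParameters(CL=265.0, V=1400.0, F=0.9)
        noise = AssayNoiseModel(0.05, 0.0, lod=0.1, loq=0.5)
        rng = np.random.default_rng(2)
        fs = []
        for _ in range(10):
            piv, _ = simulate_plasma_profile(
                params, single_dose_regimen(1.1, "IV"), PLASMA_SCHEDULE_H)
            psc, _ = simulate_plasma_profile(
                params, single_dose_regimen(1.1, "SC"), PLASMA_SCHEDULE_H)
            riv = nca_single_profile(apply_assay_noise(piv, noise, rng), 1.1,
                                     Route.IV)
            rsc = nca_single_profile(apply_assay_noise(psc, noise, rng), 1.1,
                                     Route.SC)
            fs.append(bioavailability(rsc, riv).f)
        assert np.mean(fs) == pytest.approx(0.9, abs=0.04)
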