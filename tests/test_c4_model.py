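"""Forward C4 model: electron transport, limited-rate solvers, curves."""

import numpy as np
import pytest

from c4spectra.c4_model import (
    C4Constants,
    LeafEnvironment,
    LeafPhotoParams,
    electron_transport_rate,
    enzyme_limited_A,
    light_limited_A,
    net_assimilation,
    predict_curve,
)
from c4spectra.curves import ACI_CO2_STEPS, CurveProtocol

from .oracles import enzyme_A_oracle, light_A_oracle


class TestElectronTransport:
    def test_zero_light_gives_zero(self):
        assert electron_transport_rate(0.0, 400.0, 0.3) == 0.0

    def test_saturating_light_approaches_jmax(self):
        assert electron_transport_rate(1e9, 400.0, 0.3) == pytest.approx(400.0, abs=0.1)

    def test_root_satisfies_quadratic_and_bounds(self):
        I2, jmax, theta = 500.0, 400.0, 0.3
        jt = electron_transport_rate(I2, jmax, theta)
        residual = theta * jt**2 - (I2 + jmax) * jt + I2 * jmax
        assert abs(residual) < 1e-9
        assert 0.0 <= jt <= min(I2, jmax)

    def test_small_theta_limit_is_rectangular_hyperbola(self):
        I2, jmax = 300.0, 450.0
        jt = electron_transport_rate(I2, jmax, 1e-6)
        assert jt == pytest.approx(I2 * jmax / (I2 + jmax), rel=1e-3)

    def test_strictly_increasing_in_light(self):
        grid = np.linspace(1.0, 3000.0, 200)
        jts = [electron_transport_rate(i, 400.0, 0.3) for i in grid]
        assert np.all(np.diff(jts) > 0)

    @pytest.mark.parametrize("bad", [dict(I2=-1), dict(Jmax=0), dict(theta=1.0)])
    def test_invalid_inputs_rejected(self, bad):
        kwargs = dict(I2=100.0, Jmax=400.0, theta=0.3)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            electron_transport_rate(**kwargs)


class TestLimitedRates:
    def test_zero_vcmax_collapses_to_respiration(self, consts):
        p = LeafPhotoParams(Vcmax=0.0, Vpmax=400.0, Jmax=400.0, Rd=2.0)
        env = LeafEnvironment(Ca=400.0, I_inc=1800.0, Ci_over_Ca=0.4)
        assert enzyme_limited_A(env, p, consts) == pytest.approx(-2.0, abs=1e-8)

    def test_zero_light_collapses_to_respiration(self, consts, ref_params):
        env = LeafEnvironment(Ca=400.0, I_inc=0.0, Ci_over_Ca=0.4)
        assert light_limited_A(env, ref_params, consts) == -ref_params.Rd

    def test_enzyme_rate_nondecreasing_in_co2(self, consts, ref_params):
        vals = [
            enzyme_limited_A(
                LeafEnvironment(Ca=ca, I_inc=1800.0, Ci_over_Ca=0.4),
                ref_params, consts,
            )
            for ca in np.linspace(50, 1400, 30)
        ]
        assert np.all(np.diff(vals) >= -1e-9)

    def test_light_rate_nondecreasing_in_light(self, consts, ref_params):
        vals = [
            light_limited_A(
                LeafEnvironment(Ca=400.0, I_inc=i, Ci_over_Ca=0.4),
                ref_params, consts,
            )
            for i in np.linspace(0, 2000, 30)
        ]
        assert np.all(np.diff(vals) >= -1e-9)

    def test_enzyme_solver_matches_bisection_oracle(self, consts):
        p = LeafPhotoParams(Vcmax=50.0, Vpmax=400.0, Jmax=400.0, Rd=2.0)
        env = LeafEnvironment(Ca=400.0, I_inc=1800.0, Ci_over_Ca=0.4)
        a = enzyme_limited_A(env, p, consts)
        assert a == pytest.approx(enzyme_A_oracle(env.ci, p, consts), abs=1e-6)

    def test_light_solver_matches_bisection_oracle(self, consts):
        p = LeafPhotoParams(Vcmax=50.0, Vpmax=400.0, Jmax=400.0, Rd=2.0,
                            theta=0.3, PSabs=0.35)
        env = LeafEnvironment(Ca=400.0, I_inc=1800.0, Ci_over_Ca=0.4)
        a = light_limited_A(env, p, consts)
        assert a == pytest.approx(light_A_oracle(env.ci, 1800.0, p, consts), abs=1e-6)

    def test_conservation_at_enzyme_solution(self, consts, ref_params):
        """Cs - Cm - (Vp - A - Rm)/gbs vanishes at the returned solution."""
        env = LeafEnvironment(Ca=650.0, I_inc=1800.0, Ci_over_Ca=0.4)
        a = enzyme_limited_A(env, ref_params, consts)
        cm = env.ci - a / ref_params.gm
        vp = cm * ref_params.Vpmax / (cm + consts.Kp)
        rm = consts.rm_ratio * ref_params.Rd
        cs = cm + (vp - a - rm) / consts.gbs
        # the same Cs must reproduce A through the Rubisco equation
        a_back = ((cs - consts.gamma_star_Os) * ref_params.Vcmax
                  / (cs + consts.Kc_eff) - ref_params.Rd)
        assert a_back == pytest.approx(a, abs=1e-8)
        assert cs - cm - (vp - a - rm) / consts.gbs == pytest.approx(0.0, abs=1e-8)


class TestNetAssimilation:
    def test_min_of_components_and_regime(self, consts, rng):
        for _ in range(200):
            p = LeafPhotoParams(
                Vcmax=rng.uniform(10, 90), Vpmax=rng.uniform(50, 900),
                Jmax=rng.uniform(100, 700), Rd=rng.uniform(0.5, 4),
                theta=rng.uniform(0.1, 0.9), PSabs=rng.uniform(0.2, 0.6),
            )
            env = LeafEnvironment(
                Ca=rng.uniform(60, 1400), I_inc=rng.uniform(50, 2000),
                Ci_over_Ca=rng.uniform(0.2, 0.8),
            )
            res = net_assimilation(env, p, consts)
            assert res.A <= res.Ac + 1e-12 and res.A <= res.Aj + 1e-12
            assert res.A >= -p.Rd - 1e-6
            assert res.regime == ("enzyme" if res.Ac <= res.Aj else "light")

    def test_zero_vcmax_is_enzyme_limited_respiration(self, consts):
        p = LeafPhotoParams(Vcmax=0.0, Vpmax=400.0, Jmax=400.0, Rd=2.0)
        env = LeafEnvironment(Ca=400.0, I_inc=1800.0, Ci_over_Ca=0.4)
        res = net_assimilation(env, p, consts)
        assert res.A == pytest.approx(-2.0, abs=1e-8)
        assert res.regime == "enzyme"


class TestPredictCurve:
    def test_aci_protocol_shape(self, consts, ref_params):
        curve = predict_curve(CurveProtocol.aci(), ref_params, consts)
        assert len(curve) == 10
        assert np.all(curve.I_inc == 1800.0)
        assert list(curve.Ca) == list(ACI_CO2_STEPS)

    def test_ai_dark_step_equals_respiration(self, consts, ref_params):
        curve = predict_curve(CurveProtocol.ai(), ref_params, consts)
        assert len(curve) == 10
        assert curve.A_obs[-1] == pytest.approx(-ref_params.Rd)

    def test_aci_monotone_after_sorting(self, consts, rng):
        for _ in range(10):
            p = LeafPhotoParams(
                Vcmax=rng.uniform(20, 70), Vpmax=rng.uniform(100, 700),
                Jmax=rng.uniform(200, 600), Rd=rng.uniform(0.5, 3),
            )
            curve = predict_curve(CurveProtocol.aci(), p, consts)
            order = np.argsort(curve.Ca)
            assert np.all(np.diff(curve.A_obs[order]) >= -1e-8)

    def test_empty_protocol_rejected(self, consts, ref_params):
        with pytest.raises(ValueError):
            predict_curve(CurveProtocol("ACi", ()), ref_params, consts)
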