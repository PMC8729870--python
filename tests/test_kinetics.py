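"""Input-function models, 2TCM tissue curves, Patlak analysis, CMRGlc."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from petmoco import phantom as ph
from petmoco.kinetics import (
    FENG_DEFAULTS,
    KineticParams,
    PatlakConfig,
    cmrglc,
    feng_aif,
    frame_average,
    patlak_fit,
    patlak_points,
    plasma_blood_ratio,
    tissue_tac,
    whole_blood_from_plasma,
)

T = np.arange(0.0, 3601.0)


@pytest.fixture(scope="module")
def aif():
    return feng_aif(T)


@pytest.fixture(scope="module")
def whole_blood(aif):
    return whole_blood_from_plasma(aif)


class TestFengAif:
    def test_zero_amplitudes_zero_curve(self):
        curve = feng_aif(T, (0.0, 0.0, 0.0, 1.6, 0.35, 0.01, 10.0))
        assert np.all(curve.value == 0.0)

    def test_peak_time_physiological(self, aif):
        # bolus peak between 30 s and 120 s after injection
        assert 30.0 <= T[np.argmax(aif.value)] <= 120.0
        assert aif.value[0] == 0.0

    def test_auc_finite_positive(self, aif):
        auc = aif.auc(0, 3600)
        assert np.isfinite(auc) and auc > 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="negative rate"):
            feng_aif(T, (100.0, 1.0, 1.0, -1.0, 0.1, 0.01, 10.0))


class TestPlasmaBloodRatio:
    def test_unit_ratio_identity(self, aif):
        wb = whole_blood_from_plasma(aif, r0=1.0, r_inf=1.0)
        assert np.allclose(wb.value, aif.value)

    def test_monotone_limits(self):
        r = plasma_blood_ratio(T, r0=1.0, r_inf=1.25, tau_r=600.0)
        assert r[0] == pytest.approx(1.0)
        assert r[-1] == pytest.approx(1.25, abs=1e-2)
        assert np.all(np.diff(r) >= 0)

    def test_roundtrip_plasma_blood_plasma(self, aif, whole_blood):
        ratio = plasma_blood_ratio(T)
        back = whole_blood.value * ratio
        assert np.allclose(back, aif.value, rtol=1e-12)

    def test_bad_tau(self):
        with pytest.raises(ValueError):
            plasma_blood_ratio(T, tau_r=-5.0)


class TestTissueTac:
    def test_k1_zero_is_blood_only(self, aif, whole_blood):
        p = KineticParams(K1=0.0, k2=0.0, k3=0.0, Vb=0.1)
        ct = tissue_tac(p, aif, whole_blood, T)
        assert np.allclose(ct, 0.1 * whole_blood(T), rtol=1e-6)

    def test_trapping_limit(self, aif):
        """k3 >> k2: everything delivered is trapped, C_T -> K1 * int Cp."""
        p = KineticParams(K1=0.1, k2=0.01, k3=50.0, Vb=0.0)
        ct = tissue_tac(p, aif, None, T)
        from scipy.integrate import cumulative_trapezoid

        int_cp = cumulative_trapezoid(aif(T), dx=1.0 / 60.0, initial=0.0)
        late = slice(600, None)
        assert np.allclose(ct[late], 0.1 * int_cp[late], rtol=0.01)

    def test_matches_ode_solver(self, aif, whole_blood):
        """Analytic-convolution evaluation vs direct ODE integration."""
        p = KineticParams(K1=0.1, k2=0.15, k3=0.05, Vb=0.05)
        ct = tissue_tac(p, aif, whole_blood, T)

        def rhs(t_min, y):
            cp = np.interp(t_min * 60.0, aif.t, aif.value)
            return [p.K1 * cp - (p.k2 + p.k3) * y[0], p.k3 * y[0]]

        sol = solve_ivp(rhs, [0, 60], [0.0, 0.0], t_eval=T / 60.0,
                        max_step=0.05, rtol=1e-9, atol=1e-9)
        ct_ode = (1 - p.Vb) * (sol.y[0] + sol.y[1]) + p.Vb * whole_blood(T)
        sup = np.max(np.abs(ct - ct_ode)) / np.max(np.abs(ct_ode))
        assert sup < 0.005

    def test_degenerate_rates_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(K1=0.1, k2=0.0, k3=0.0)


class TestPatlak:
    def test_exact_linear_construction(self, aif, schedule37):
        """C_T = 0.02 * intCp + 0.3 * Cp must return slope/intercept exactly."""
        from scipy.integrate import cumulative_trapezoid

        grid = np.arange(0.0, 3601.0)
        cp = aif(grid)
        int_cp = cumulative_trapezoid(cp, dx=1.0 / 60.0, initial=0.0)
        mids = schedule37.mid_times
        tissue = 0.02 * np.interp(mids, grid, int_cp) + 0.3 * np.interp(mids, grid, cp)
        slope, intercept = patlak_fit(tissue, aif, PatlakConfig(), schedule37)
        assert slope == pytest.approx(0.02, rel=1e-6)
        assert intercept == pytest.approx(0.3, rel=1e-4)

    def test_eight_points_on_protocol(self, aif, schedule37):
        x, y, idx = patlak_points(np.ones(37), aif, schedule37, t_star=1500.0)
        assert len(idx) == 8

    def test_slope_recovers_ki_grid(self, aif, whole_blood, schedule37):
        """Noiseless 2TCM across Ki in [0.01, 0.05]: slope within 2% of
        K1*k3/(k2+k3)."""
        grid = [
            (0.05, 0.20, 0.05),
            (0.08, 0.15, 0.04),
            (0.10, 0.15, 0.05),
            (0.12, 0.10, 0.05),
            (0.15, 0.12, 0.06),
        ]
        for K1, k2, k3 in grid:
            p = KineticParams(K1, k2, k3, Vb=0.0)
            ct = tissue_tac(p, aif, whole_blood, T)
            tissue = frame_average(T, ct, schedule37)
            slope, _ = patlak_fit(tissue, aif, PatlakConfig(), schedule37)
            assert abs(slope - p.Ki) / p.Ki < 0.02, (K1, k2, k3)

    def test_noisy_recovery_median(self, aif, whole_blood, schedule37):
        """Single-voxel Poisson noise at the phantom's default count
        sensitivity: median |slope error| < 10% over 50 seeds."""
        p = KineticParams(0.1, 0.15, 0.05, Vb=0.0)
        ct = tissue_tac(p, aif, whole_blood, T)
        tissue = frame_average(T, ct, schedule37)
        sens = ph.PhantomSpec().count_sensitivity
        durations = schedule37.durations
        rng = np.random.default_rng(0)
        errors = []
        for _ in range(50):
            lam = tissue * durations * sens
            noisy = rng.poisson(lam) / (durations * sens)
            slope, _ = patlak_fit(noisy, aif, PatlakConfig(), schedule37)
            errors.append(abs(slope - p.Ki) / p.Ki * 100)
        assert np.median(errors) < 10.0

    def test_scale_invariance(self, aif, whole_blood, schedule37):
        p = KineticParams(0.1, 0.15, 0.05, Vb=0.0)
        ct = tissue_tac(p, aif, whole_blood, T)
        tissue = frame_average(T, ct, schedule37)
        s1, i1 = patlak_fit(tissue, aif, PatlakConfig(), schedule37)
        from petmoco.core import InputFunction

        scaled_aif = InputFunction(aif.t, aif.value * 7.3, "plasma")
        s2, i2 = patlak_fit(tissue * 7.3, scaled_aif, PatlakConfig(), schedule37)
        assert s2 == pytest.approx(s1, rel=1e-9)
        assert i2 == pytest.approx(i1, rel=1e-9)

    def test_insufficient_frames(self, aif):
        sched = ph.make_schedule([(4, 300.0)])
        with pytest.raises(ValueError, match="insufficient late frames"):
            patlak_fit(np.ones(4), aif, PatlakConfig(t_star=1190.0), sched)


class TestCmrglc:
    def test_stated_arithmetic(self):
        cfg = PatlakConfig(plasma_glucose=1000.0, lumped_constant=0.65)
        assert cmrglc(0.0065, cfg) == pytest.approx(1.0)
        assert cmrglc(0.0, cfg) == 0.0

    def test_linearity_in_glucose(self):
        a = cmrglc(0.01, PatlakConfig(plasma_glucose=4000.0))
        b = cmrglc(0.01, PatlakConfig(plasma_glucose=8000.0))
        assert b == pytest.approx(2 * a)

    def test_invalid_lumped_constant(self):
        with pytest.raises(ValueError):
            PatlakConfig(lumped_constant=0.0)


class TestInputFunctionAuc:
    def test_non_negative_and_additive(self, aif):
        a = aif.auc(0, 1800)
        b = aif.auc(1800, 3600)
        assert a >= 0 and b >= 0
        assert a + b == pytest.approx(aif.auc(0, 3600), rel=1e-9)
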