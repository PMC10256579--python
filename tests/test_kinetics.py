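"""Kinetic fitting: closed-form mono-exponential solutions, single-time-point
extrapolation, whole-body retention fits with fallback, and clamping at the
physical half-life."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from iodose import (
    TimeActivitySeries,
    fit_monoexp,
    fit_multiexp_retention,
    tiac_single_timepoint,
)
from iodose.config import I131_PHYSICAL_HALF_LIFE_H
from iodose.kinetics import (
    FLAG_FALLBACK_MONO,
    FLAG_HALF_LIFE_CLAMPED,
    FLAG_UPTAKE_SUSPECTED,
)

LN2 = np.log(2)


def series(times, acts, a0=3700.0, organ="neck_uptake"):
    n = len(times)
    return TimeActivitySeries(
        organ=organ,
        times_h=np.asarray(times, float),
        activities_mbq=np.asarray(acts, float),
        volumes_ml=np.full(n, 10.0),
        masses_g=np.full(n, 10.0),
        a0_mbq=a0,
    )


def quad_tia(fit, t_split=2000.0):
    """Independent TIA oracle: adaptive quadrature plus the analytic tail."""
    val, _ = quad(fit, 0.0, t_split, limit=200)
    tail = sum(
        c.amplitude * np.exp(-c.decay_constant_per_h * t_split) / c.decay_constant_per_h
        for c in fit.components
    )
    return val + tail


class TestFitMonoexp:
    def test_two_point_closed_form(self):
        fit = fit_monoexp(series([24.0, 48.0], [100.0, 50.0]))
        assert fit.t_eff_h == pytest.approx(24.0, rel=1e-12)
        assert fit.components[0].amplitude == pytest.approx(200.0, rel=1e-12)
        assert fit.tia_mbq_h == pytest.approx(200.0 * 24.0 / LN2, rel=1e-12)
        assert fit.tia_mbq_h == pytest.approx(6924.94, abs=0.01)

    def test_three_point_noise_free_recovery(self):
        t = np.array([10.0, 20.0, 30.0])
        fit = fit_monoexp(series(t, 100.0 * 2.0 ** (-t / 10.0)))
        assert fit.components[0].amplitude == pytest.approx(100.0, rel=1e-8)
        assert fit.components[0].decay_constant_per_h == pytest.approx(LN2 / 10.0, rel=1e-8)
        assert fit.tia_mbq_h == pytest.approx(100.0 * 10.0 / LN2, rel=1e-8)

    def test_flat_series_clamps_to_physical_half_life(self):
        fit = fit_monoexp(series([24.0, 25.0], [5.0, 5.0]))
        assert FLAG_HALF_LIFE_CLAMPED in fit.flags
        assert fit.t_eff_h == pytest.approx(I131_PHYSICAL_HALF_LIFE_H)

    def test_rising_series_over_a_day_is_flagged_not_rejected(self):
        fit = fit_monoexp(series([6.0, 24.0, 48.0], [1.0, 2.0, 3.0]))
        assert FLAG_UPTAKE_SUSPECTED in fit.flags

    def test_single_positive_sample_redirects_to_single_time_point(self):
        with pytest.raises(ValueError, match="single"):
            fit_monoexp(series([24.0, 48.0], [5.0, 0.0]))

    def test_tia_matches_quadrature(self):
        fit = fit_monoexp(series([24.0, 48.0, 96.0], [100.0, 52.0, 12.0]))
        assert fit.tia_mbq_h == pytest.approx(quad_tia(fit), rel=1e-6)


class TestSingleTimePoint:
    def test_neck_default_68h(self):
        fit = tiac_single_timepoint(5.0, 96.0, "neck_uptake", a0_mbq=3700.0)
        lam = LN2 / 68.0
        assert fit.components[0].amplitude == pytest.approx(5.0 * np.exp(lam * 96.0), rel=1e-12)
        assert fit.components[0].amplitude == pytest.approx(13.305, abs=2e-3)
        assert fit.tia_mbq_h == pytest.approx(1305.2, abs=0.5)
        assert fit.tiac_h == pytest.approx(0.3528, abs=2e-4)

    def test_parotid_default_9p3h(self):
        fit = tiac_single_timepoint(20.0, 24.0, "parotid", a0_mbq=3700.0)
        assert fit.tia_mbq_h == pytest.approx(1605.0, rel=1e-3)

    def test_zero_activity_gives_zero_tia(self):
        fit = tiac_single_timepoint(0.0, 24.0, "parotid", a0_mbq=3700.0)
        assert fit.tia_mbq_h == 0.0
        assert fit.tiac_h == 0.0

    def test_missing_half_life_names_organ(self):
        with pytest.raises(ValueError, match="liver"):
            tiac_single_timepoint(5.0, 24.0, "liver", a0_mbq=3700.0)

    def test_explicit_half_life_overrides_defaults(self):
        fit = tiac_single_timepoint(5.0, 24.0, "liver", a0_mbq=3700.0, half_life_h=16.0)
        assert fit.t_eff_h == pytest.approx(16.0)

    @given(hl=st.floats(min_value=17.0, max_value=150.0))
    @settings(deadline=None, max_examples=40)
    def test_tia_increases_with_assumed_half_life_past_scan_time(self, hl):
        """TIA = A(t1) T e^{ln2 t1 / T} / ln2 is increasing in T for
        T >= ln2 t1 (~16.6 h for a 24-h scan); below that the t=0
        back-extrapolation dominates and the relation inverts."""
        f1 = tiac_single_timepoint(5.0, 24.0, "x", a0_mbq=1.0, half_life_h=hl)
        f2 = tiac_single_timepoint(5.0, 24.0, "x", a0_mbq=1.0, half_life_h=hl * 1.05)
        assert f2.tia_mbq_h > f1.tia_mbq_h

    def test_consistency_with_two_point_fit(self):
        """On exact mono-exponential data, either point extrapolated with the
        true half-life reproduces the 2-point fit's TIA."""
        t = np.array([24.0, 72.0])
        a = 80.0 * 2.0 ** (-t / 17.0)
        fit2 = fit_monoexp(series(t, a, a0=3700.0))
        for ti, ai in zip(t, a):
            f1 = tiac_single_timepoint(ai, ti, "x", a0_mbq=3700.0, half_life_h=fit2.t_eff_h)
            assert f1.tia_mbq_h == pytest.approx(fit2.tia_mbq_h, rel=1e-12)


class TestRetentionFit:
    def test_noise_free_biexponential_recovery(self):
        t = np.array([2.0, 6.0, 12.0, 24.0, 48.0, 96.0, 144.0, 168.0])
        y = 0.6 * 2.0 ** (-t / 5.0) + 0.4 * 2.0 ** (-t / 24.0)
        fit = fit_multiexp_retention(t, y, a0_mbq=1.0)
        true_tiac = (0.6 * 5 + 0.4 * 24) / LN2
        assert fit.tiac_h == pytest.approx(true_tiac, rel=1e-3)
        # faster component first, amplitudes sum to A0
        assert fit.components[0].decay_constant_per_h > fit.components[1].decay_constant_per_h
        assert sum(c.amplitude for c in fit.components) == pytest.approx(1.0, rel=1e-9)
        assert fit.components[0].half_life_h == pytest.approx(5.0, rel=1e-3)
        assert fit.components[1].half_life_h == pytest.approx(24.0, rel=1e-3)

    def test_mono_exponential_falls_back_to_one_component(self):
        t = np.array([2.0, 6.0, 24.0, 48.0, 96.0])
        y = 2.0 ** (-t / 11.5)
        fit = fit_multiexp_retention(t, y, a0_mbq=1.0)
        assert FLAG_FALLBACK_MONO in fit.flags
        assert len(fit.components) == 1
        assert fit.tiac_h == pytest.approx(11.5 / LN2, rel=1e-6)

    def test_truncated_window_gives_same_tiac(self):
        """Centre schedules differ (last measurement ~44 h vs ~167 h) but the
        noise-free model is identifiable from either window."""
        def make(times):
            t = np.asarray(times, float)
            y = 0.6 * 2.0 ** (-t / 5.0) + 0.4 * 2.0 ** (-t / 24.0)
            return fit_multiexp_retention(t, y, a0_mbq=1.0)

        f_short = make([2.0, 6.0, 12.0, 24.0, 44.0])
        f_long = make([2.0, 6.0, 24.0, 48.0, 96.0, 167.0])
        assert f_short.tiac_h == pytest.approx(f_long.tiac_h, rel=5e-3)

    def test_all_zero_retention_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fit_multiexp_retention([2.0, 24.0, 48.0], [0.0, 0.0, 0.0], a0_mbq=1.0)

    def test_late_first_point_needs_anchor(self):
        with pytest.raises(ValueError, match="anchor"):
            fit_multiexp_retention([24.0, 48.0, 96.0], [0.5, 0.3, 0.1])

    def test_tia_matches_quadrature(self):
        t = np.array([2.0, 6.0, 24.0, 48.0, 96.0, 167.0])
        y = 0.7 * 2.0 ** (-t / 8.0) + 0.3 * 2.0 ** (-t / 30.0)
        fit = fit_multiexp_retention(t, y, a0_mbq=1.0)
        assert fit.tia_mbq_h == pytest.approx(quad_tia(fit), rel=1e-6)
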