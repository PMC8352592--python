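"""Normalization and kinetic fitting: oracles, round trips, properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromokin import (
    AcquisitionSpec,
    AnalysisError,
    KineticParams,
    TimeSeriesCurve,
    TwoCompartmentSpec,
    analyze_flip_frap,
    background_correct,
    compare_t_half,
    fit_biphasic,
    fit_double_exponential,
    full_scale_normalize,
    k_ex_for_half_time,
    percent_recovery_at,
    simulate_biphasic_curve,
    simulate_flip_frap,
    simulate_frap_curve,
    simulate_slow_recovery,
    solve_t_half,
)


def _curve(time, roi, whole=None, background=None, n_pre=2):
    n = len(time)
    return TimeSeriesCurve(
        time=time,
        roi=roi,
        whole=np.ones(n) if whole is None else whole,
        background=np.zeros(n) if background is None else background,
        n_pre=n_pre,
    )


class TestBackgroundCorrect:
    def test_zero_background_is_identity(self):
        c = _curve(np.arange(5.0), np.array([10, 10, 3, 4, 5.0]))
        out = background_correct(c)
        assert np.array_equal(out.roi, c.roi)

    def test_constant_background_subtracted(self):
        c = _curve(
            np.arange(5.0),
            np.full(5, 100.0),
            background=np.full(5, 20.0),
        )
        assert np.allclose(background_correct(c).roi, 80.0)

    def test_oversubtraction_floors_at_zero_and_flags(self):
        c = _curve(
            np.arange(5.0),
            np.full(5, 10.0),
            background=np.full(5, 15.0),
        )
        out = background_correct(c)
        assert np.all(out.roi == 0.0)
        assert out.meta["floored"] is True


class TestFullScaleNormalize:
    def test_arithmetic_oracle(self):
        # Constant whole channel, roi pre-mean 1, roi(t0)=0.3,
        # roi(t)=0.65: F(t) = (0.65 - 0.3) / 0.7 = 0.5.
        c = _curve(np.arange(4.0), np.array([1.0, 1.0, 0.3, 0.65]))
        norm = full_scale_normalize(c)
        assert norm.value[2] == 0.0
        assert norm.value[3] == pytest.approx(0.5, abs=1e-12)

    def test_no_bleach_detected_raises(self):
        c = _curve(np.arange(4.0), np.array([1.0, 1.0, 1.0, 1.0]))
        with pytest.raises(AnalysisError, match="no bleach"):
            full_scale_normalize(c)

    def test_observational_bleaching_corrected_by_whole_channel(self):
        # 20 % linear whole-cell decay over the run: the double
        # normalization cancels it, so the plateau matches the
        # decay-free case within 1 %.
        p = KineticParams(a=0.9, b=0.0, k1=1.0)
        acq = AcquisitionSpec(n_pre=10, n_post=100, interval=0.2, bleach_depth=0.7)
        clean = full_scale_normalize(
            background_correct(simulate_frap_curve(p, acq))
        )
        decay_rate = 0.2 / (acq.n_frames * acq.interval)
        decayed = full_scale_normalize(
            background_correct(
                simulate_frap_curve(p, acq, whole_decay_rate=decay_rate)
            )
        )
        assert abs(decayed.post_value[-1] - clean.post_value[-1]) < 0.01

    @settings(max_examples=30, deadline=None)
    @given(
        bleach=st.floats(0.2, 0.95),
        scale=st.floats(0.1, 1000.0),
        mobile=st.floats(0.1, 1.0),
    )
    def test_invariants_hold_for_any_positive_input(self, bleach, scale, mobile):
        acq = AcquisitionSpec(n_pre=5, n_post=30, interval=0.5, bleach_depth=bleach)
        curve = simulate_frap_curve(KineticParams(a=mobile, k1=0.8), acq)
        scaled = TimeSeriesCurve(
            time=curve.time,
            roi=curve.roi * scale,
            whole=curve.whole * scale,
            background=curve.background,
            n_pre=curve.n_pre,
        )
        norm = full_scale_normalize(scaled)
        assert norm.value[curve.n_pre] == 0.0
        assert norm.value[: curve.n_pre].mean() == pytest.approx(1.0, abs=1e-9)


class TestDoubleExponentialFit:
    def test_noiseless_single_component_closed_form(self, gland_acq):
        curve = simulate_frap_curve(KineticParams(a=0.9, b=0.0, k1=0.5), gland_acq)
        fit = fit_double_exponential(
            full_scale_normalize(background_correct(curve))
        )
        assert fit.mobile_fraction == pytest.approx(0.9, abs=1e-6)
        assert fit.t_half == pytest.approx(math.log(2) / 0.5, abs=1e-6)

    def test_noiseless_two_component_round_trip(self, gland_acq, two_component_params):
        p = two_component_params
        curve = simulate_frap_curve(p, gland_acq)
        fit = fit_double_exponential(
            full_scale_normalize(background_correct(curve))
        )
        for name in ("a", "b", "k1", "k2"):
            assert getattr(fit, name) == pytest.approx(
                getattr(p, name), rel=1e-4
            ), name

    def test_fitted_model_is_monotone(self, gland_acq, two_component_params):
        curve = simulate_frap_curve(two_component_params, gland_acq)
        fit = fit_double_exponential(
            full_scale_normalize(background_correct(curve))
        )
        grid = np.linspace(0.0, 100.0, 2000)
        assert np.all(np.diff(fit.predict(grid)) >= 0)

    def test_noisy_t_half_recovery_within_ten_percent(self):
        # The 3.1 s chromosomal-band regime at 2 % noise.
        p = KineticParams(a=0.65, b=0.35, k1=0.32, k2=0.075)
        truth = solve_t_half(p)
        recovered = []
        for seed in range(50):
            acq = AcquisitionSpec(
                n_pre=10, n_post=250, interval=0.648,
                bleach_depth=0.7, noise_sd=0.02, seed=seed,
            )
            fit = fit_double_exponential(
                full_scale_normalize(
                    background_correct(simulate_frap_curve(p, acq))
                )
            )
            recovered.append(fit.t_half)
        assert np.median(recovered) == pytest.approx(truth, rel=0.10)


class TestSolveTHalf:
    def test_single_exponential_closed_form(self):
        assert solve_t_half(KineticParams(a=0.8, k1=2.0)) == pytest.approx(
            math.log(2) / 2.0
        )

    def test_equal_rates_reduce_to_single_exponential(self):
        p = KineticParams(a=0.5, b=0.5, k1=0.7, k2=0.7)
        assert solve_t_half(p) == pytest.approx(math.log(2) / 0.7)

    def test_matches_dense_bisection(self):
        p = KineticParams(a=0.5, b=0.5, k1=1.0, k2=0.1)
        lo, hi = 0.0, 100.0
        target = (p.a + p.b) / 2.0
        for _ in range(200):
            mid = (lo + hi) / 2.0
            if p.recovery(mid) < target:
                lo = mid
            else:
                hi = mid
        assert solve_t_half(p) == pytest.approx((lo + hi) / 2.0, abs=1e-10)

    def test_zero_mobile_fraction_raises(self):
        with pytest.raises(AnalysisError, match="mobile fraction"):
            solve_t_half(KineticParams(a=0.0, b=0.0, k1=1.0, k2=0.0))


class TestFlipFrapAnalysis:
    def test_symmetric_exchange_balances(self):
        spec = TwoCompartmentSpec(
            v1=1.0, v2=1.0, k_ex=k_ex_for_half_time(20.0), bleach_fraction=0.9
        )
        acq = AcquisitionSpec(n_pre=10, n_post=250, interval=0.648)
        res = analyze_flip_frap(*simulate_flip_frap(spec, acq))
        assert res.gain_loss_balance == pytest.approx(1.0, abs=0.02)

    def test_flat_pair_raises_no_exchange(self):
        spec = TwoCompartmentSpec(v1=1.0, v2=1.0, k_ex=0.0, bleach_fraction=0.9)
        acq = AcquisitionSpec(n_pre=5, n_post=50, interval=1.0)
        with pytest.raises(AnalysisError, match="no exchange"):
            analyze_flip_frap(*simulate_flip_frap(spec, acq))

    def test_histone_like_pool_shows_under_two_percent_recovery(self):
        # Near-zero exchange: the bleached half gains < 2 % of its
        # pre-bleach value over 180 s, the immobile-histone phenotype.
        spec = TwoCompartmentSpec(
            v1=1.0, v2=1.0, k_ex=1e-5, bleach_fraction=0.9
        )
        acq = AcquisitionSpec(n_pre=10, n_post=278, interval=0.648)
        bleached, unbleached = simulate_flip_frap(spec, acq)
        pct = 100.0 * bleached.roi / bleached.roi[:10].mean()
        assert pct[10:].max() - pct[10] < 2.0
        res = analyze_flip_frap(bleached, unbleached)
        assert res.bleached_recovery_percent < 2.0


class TestScalarReadouts:
    def test_percent_recovery_on_plateaued_curve(self):
        acq = AcquisitionSpec(n_pre=2, n_post=100, interval=30.0, bleach_depth=1.0)
        curve = simulate_slow_recovery(0.18, 5.0, acq)  # saturates instantly
        norm = full_scale_normalize(background_correct(curve))
        assert percent_recovery_at(norm, 1500.0) == pytest.approx(0.18, abs=1e-6)
        assert percent_recovery_at(norm, 1500.0, window=120.0) == pytest.approx(
            0.18, abs=1e-6
        )

    def test_slow_recovery_at_forty_minutes(self):
        k = -math.log(0.1) / 2400.0
        acq = AcquisitionSpec(n_pre=5, n_post=120, interval=30.0, bleach_depth=0.8)
        norm = full_scale_normalize(
            background_correct(simulate_slow_recovery(0.2, k, acq))
        )
        assert percent_recovery_at(norm, 2400.0) == pytest.approx(0.18, abs=1e-6)

    def test_out_of_range_query_raises(self):
        acq = AcquisitionSpec(n_pre=2, n_post=20, interval=1.0)
        norm = full_scale_normalize(
            background_correct(
                simulate_frap_curve(KineticParams(a=0.5, k1=1.0), acq)
            )
        )
        with pytest.raises(AnalysisError, match="outside sampled range"):
            percent_recovery_at(norm, 1e6)

    def test_compare_t_half_paper_regimes(self, gland_acq):
        # A slowed variant versus a fast wild type: 1.7 s vs 0.7 s
        # half-times give a ratio of ~2.43.
        fits = []
        for t_half in (1.7, 0.7):
            p = KineticParams(a=1.0, b=0.0, k1=math.log(2) / t_half)
            curve = simulate_frap_curve(p, gland_acq)
            fits.append(
                fit_double_exponential(
                    full_scale_normalize(background_correct(curve))
                )
            )
        cmp = compare_t_half(fits[0], fits[1])
        assert cmp.ratio == pytest.approx(1.7 / 0.7, rel=1e-4)
        assert "2.4" in cmp.description

    def test_compare_identical_fits_is_unity(self, gland_acq):
        curve = simulate_frap_curve(KineticParams(a=0.9, k1=1.0), gland_acq)
        fit = fit_double_exponential(
            full_scale_normalize(background_correct(curve))
        )
        assert compare_t_half(fit, fit).ratio == 1.0


class TestBiphasicFit:
    def test_pure_exponential_gives_zero_slope(self):
        acq = AcquisitionSpec(n_pre=5, n_post=100, interval=0.5, bleach_depth=1.0)
        curve = simulate_biphasic_curve(0.6, 1.0, 0.0, acq)
        fit = fit_biphasic(full_scale_normalize(background_correct(curve)))
        assert fit.slope == pytest.approx(0.0, abs=1e-6)

    def test_pure_ramp_recovers_slope(self):
        acq = AcquisitionSpec(n_pre=5, n_post=100, interval=0.5, bleach_depth=1.0)
        curve = simulate_biphasic_curve(0.0, 1.0, 0.003, acq)
        fit = fit_biphasic(full_scale_normalize(background_correct(curve)))
        assert fit.fast_amp == pytest.approx(0.0, abs=1e-3)
        assert fit.slope == pytest.approx(0.003, abs=1e-3)

    def test_noiseless_round_trip(self):
        acq = AcquisitionSpec(n_pre=5, n_post=200, interval=0.5, bleach_depth=1.0)
        curve = simulate_biphasic_curve(0.4, 1.0, 0.001, acq)
        fit = fit_biphasic(full_scale_normalize(background_correct(curve)))
        assert fit.fast_amp == pytest.approx(0.4, rel=1e-4)
        assert fit.fast_k == pytest.approx(1.0, rel=1e-4)
        assert fit.slope == pytest.approx(0.001, rel=1e-4)


class TestImmobileFraction:
    def test_injected_immobile_fraction_recovered(self):
        # Mobile fraction 0.86 (immobile 0.14, the receptor phenotype).
        p = KineticParams(a=0.56, b=0.30, k1=0.33, k2=0.075)
        immobile = []
        for seed in range(40):
            acq = AcquisitionSpec(
                n_pre=10, n_post=250, interval=0.648,
                bleach_depth=0.7, noise_sd=0.02, seed=seed,
            )
            fit = fit_double_exponential(
                full_scale_normalize(
                    background_correct(simulate_frap_curve(p, acq))
                )
            )
            immobile.append(1.0 - fit.mobile_fraction)
        assert np.mean(immobile) == pytest.approx(0.14, abs=0.03)
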