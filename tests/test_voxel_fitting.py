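import numpy as np
import pytest

from relaxmap.relaxation_models import (
    AcquisitionSchedule,
    BiParams,
    MonoParams,
    bi_decay,
    ir_signal,
    mono_decay,
)
from relaxmap.voxel_fitting import (
    DecayCurve,
    fit_bi,
    fit_mono,
    fit_t1_ir,
    fit_volume,
    mask_volume,
    subtract_background,
)

from conftest import make_bi_curve, make_mono_curve


# --- independent brute-force oracles -------------------------------------

def mono_grid_oracle(curve, t2_lo, t2_hi, n_grid=2000):
    """Profiled grid search: scan T2, solve S0 analytically per grid point."""
    t, y = curve.schedule.times, curve.signal
    best = (np.inf, None, None)
    for t2 in np.linspace(t2_lo, t2_hi, n_grid):
        e = np.exp(-t / t2)
        s0 = max(float(e @ y / (e @ e)), 0.0)
        rss = float(np.sum((s0 * e - y) ** 2))
        if rss < best[0]:
            best = (rss, s0, t2)
    return best  # (rss, s0, t2)


def bi_grid_oracle(curve, tf_range, ts_range, n_grid=60, refine=2):
    """Coarse 2-D grid over (T2_fast, T2_slow) with amplitudes from
    non-negative linear least squares, refined locally."""
    from scipy.optimize import nnls

    t, y = curve.schedule.times, curve.signal
    best = (np.inf, None)
    lo_f, hi_f = tf_range
    lo_s, hi_s = ts_range
    for _ in range(refine + 1):
        tf_grid = np.linspace(lo_f, hi_f, n_grid)
        ts_grid = np.linspace(lo_s, hi_s, n_grid)
        for tf in tf_grid:
            for ts in ts_grid:
                if ts <= tf:
                    continue
                basis = np.column_stack(
                    [np.exp(-t / tf), np.exp(-t / ts)]
                )
                amps, _ = nnls(basis, y)
                rss = float(np.sum((basis @ amps - y) ** 2))
                if rss < best[0]:
                    best = (rss, (amps[0], amps[1], tf, ts))
        _, (a1, a2, tf, ts) = best
        df = (hi_f - lo_f) / n_grid
        ds = (hi_s - lo_s) / n_grid
        lo_f, hi_f = max(tf - 2 * df, 1.0), tf + 2 * df
        lo_s, hi_s = max(ts - 2 * ds, 1.0), ts + 2 * ds
    return best  # (rss, (a1, a2, tf, ts))


# --- DecayCurve ------------------------------------------------------------

class TestDecayCurve:
    def test_length_mismatch_rejected(self, cpmg40):
        with pytest.raises(ValueError, match="length"):
            DecayCurve(cpmg40, np.zeros(39))

    def test_n(self, cpmg40):
        assert make_mono_curve(cpmg40).n == 40


# --- fit_mono --------------------------------------------------------------

class TestFitMono:
    def test_noiseless_round_trip(self, cpmg40):
        fit = fit_mono(make_mono_curve(cpmg40, 100.0, 50.0))
        assert fit.converged
        assert fit.params.S0 == pytest.approx(100.0, rel=1e-6)
        assert fit.params.T == pytest.approx(50.0, rel=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert fit.n == 40

    def test_all_zero_curve_fails_gracefully(self, cpmg40):
        fit = fit_mono(DecayCurve(cpmg40, np.zeros(40)))
        assert not fit.converged
        assert fit.params is None

    def test_non_finite_curve_fails_gracefully(self, cpmg40):
        sig = np.ones(40)
        sig[3] = np.nan
        fit = fit_mono(DecayCurve(cpmg40, sig))
        assert not fit.converged

    def test_too_few_samples_rejected(self):
        sch = AcquisitionSchedule.cpmg(n_echoes=2, first_te=10, last_te=20)
        with pytest.raises(ValueError, match="3 samples"):
            fit_mono(DecayCurve(sch, np.ones(2)))

    def test_noisy_matches_grid_oracle(self, cpmg40):
        curve = make_mono_curve(cpmg40, 100.0, 80.0, noise_sd=1.0, seed=17)
        fit = fit_mono(curve)
        _, _, t2_oracle = mono_grid_oracle(curve, 40.0, 160.0)
        assert fit.params.T == pytest.approx(t2_oracle, rel=0.05)

    @pytest.mark.parametrize("s0,t2", [(10.0, 15.0), (500.0, 120.0), (3.0, 350.0)])
    def test_self_consistency(self, cpmg40, s0, t2):
        fit = fit_mono(make_mono_curve(cpmg40, s0, t2))
        assert fit.params.S0 == pytest.approx(s0, rel=1e-6)
        assert fit.params.T == pytest.approx(t2, rel=1e-6)


# --- fit_bi ----------------------------------------------------------------

class TestFitBi:
    def test_noiseless_round_trip_and_nesting(self, cpmg40):
        curve = make_bi_curve(cpmg40, 50.0, 50.0, 20.0, 200.0)
        fb = fit_bi(curve)
        fm = fit_mono(curve)
        assert fb.converged and not fb.effectively_mono
        assert fb.params.A1 == pytest.approx(50.0, rel=1e-3)
        assert fb.params.A2 == pytest.approx(50.0, rel=1e-3)
        assert fb.params.T2_fast == pytest.approx(20.0, rel=1e-3)
        assert fb.params.T2_slow == pytest.approx(200.0, rel=1e-3)
        assert fb.rss < fm.rss

    def test_ordering_convention(self, cpmg40):
        fb = fit_bi(make_bi_curve(cpmg40, 30.0, 70.0, 15.0, 150.0))
        assert fb.params.T2_fast < fb.params.T2_slow

    def test_mono_curve_flagged_effectively_mono(self, cpmg40):
        fb = fit_bi(make_mono_curve(cpmg40, 100.0, 50.0))
        assert fb.effectively_mono

    def test_too_few_samples_rejected(self):
        sch = AcquisitionSchedule.cpmg(n_echoes=4, first_te=10, last_te=40)
        with pytest.raises(ValueError, match="5 samples"):
            fit_bi(DecayCurve(sch, np.ones(4)))

    def test_noisy_matches_grid_oracle(self, cpmg40):
        curve = make_bi_curve(
            cpmg40, 50.0, 50.0, 20.0, 200.0, noise_sd=0.5, seed=23
        )
        fb = fit_bi(curve)
        _, (a1, a2, tf, ts) = bi_grid_oracle(
            curve, (5.0, 60.0), (80.0, 400.0)
        )
        assert fb.params.T2_fast == pytest.approx(tf, rel=0.10)
        assert fb.params.T2_slow == pytest.approx(ts, rel=0.10)
        assert fb.params.A1 == pytest.approx(a1, rel=0.10)
        assert fb.params.A2 == pytest.approx(a2, rel=0.10)

    def test_nesting_inequality_on_noisy_curves(self, cpmg40, rng):
        for seed in range(5):
            curve = make_bi_curve(
                cpmg40, 60.0, 40.0, 25.0, 180.0, noise_sd=1.0, seed=seed
            )
            assert fit_bi(curve).rss <= fit_mono(curve).rss + 1e-6


# --- fit_t1_ir -------------------------------------------------------------

class TestFitT1IR:
    def test_noiseless_signed_round_trip(self, ir_schedule):
        sig = ir_signal(MonoParams(1.0, 100.0), ir_schedule.times)
        fit = fit_t1_ir(DecayCurve(ir_schedule, sig))
        assert fit.converged
        assert fit.params.T == pytest.approx(100.0, abs=1e-4)
        assert fit.params.S0 == pytest.approx(1.0, rel=1e-6)

    def test_late_sampling_flagged_wide_confidence(self):
        # all TIs beyond 5 T1: recovery is flat, T1 barely identifiable
        sch = AcquisitionSchedule.ir(np.linspace(500.0, 5000.0, 8))
        sig = ir_signal(MonoParams(1.0, 100.0), sch.times) + (
            np.random.default_rng(0).normal(0, 1e-4, 8)
        )
        fit = fit_t1_ir(DecayCurve(sch, sig))
        assert fit.converged
        assert "wide_confidence" in fit.flags

    def test_magnitude_data_with_free_beta(self, ir_schedule):
        true = MonoParams(5.0, 120.0)
        sig = ir_signal(true, ir_schedule.times, beta=1.9, magnitude=True)
        fit = fit_t1_ir(DecayCurve(ir_schedule, sig), fit_beta=True)
        assert fit.params.T == pytest.approx(120.0, rel=0.01)

    def test_requires_ir_schedule(self, cpmg40):
        with pytest.raises(ValueError, match="IR schedule"):
            fit_t1_ir(make_mono_curve(cpmg40))

    def test_all_zero_fails_gracefully(self, ir_schedule):
        fit = fit_t1_ir(DecayCurve(ir_schedule, np.zeros(10)))
        assert not fit.converged


# --- oracle equivalence property ------------------------------------------

def test_lm_matches_grid_oracle_on_random_curves():
    """On 20 random mono curves the optimizer solution agrees with an
    exhaustive profiled grid search to within the grid resolution."""
    rng = np.random.default_rng(99)
    sch = AcquisitionSchedule.cpmg(n_echoes=20, first_te=10, last_te=300)
    for _ in range(20):
        s0 = rng.uniform(20.0, 200.0)
        t2 = rng.uniform(20.0, 150.0)
        sig = mono_decay(MonoParams(s0, t2), sch.times)
        sig = sig + rng.normal(0.0, 0.5, sig.shape)
        curve = DecayCurve(sch, sig)
        fit = fit_mono(curve)
        _, s0_g, t2_g = mono_grid_oracle(curve, 10.0, 200.0, n_grid=4000)
        grid_step = (200.0 - 10.0) / 4000
        assert abs(fit.params.T - t2_g) <= 2 * grid_step
        assert fit.params.S0 == pytest.approx(s0_g, rel=0.01)


def test_permutation_safety(cpmg40):
    """Jointly shuffling the (time, signal) pairs (then restoring time
    order, as the schedule is ordered by contract) leaves the fit
    unchanged bit-for-bit."""
    curve = make_mono_curve(cpmg40, 80.0, 60.0, noise_sd=1.0, seed=4)
    rng = np.random.default_rng(1)
    perm = rng.permutation(curve.n)
    t_sh, y_sh = curve.schedule.times[perm], curve.signal[perm]
    order = np.argsort(t_sh)
    curve2 = DecayCurve(
        AcquisitionSchedule(cpmg40.kind, t_sh[order]), y_sh[order]
    )
    f1, f2 = fit_mono(curve), fit_mono(curve2)
    assert f1.params == f2.params
    assert f1.rss == f2.rss


# --- subtract_background ---------------------------------------------------

class TestSubtractBackground:
    @pytest.mark.parametrize(
        "sample,background,expected",
        [(21.5, 7.0, 14.5), (7.0, 7.0, 0.0), (6.9, 7.0, -0.1)],
    )
    def test_difference(self, sample, background, expected):
        assert subtract_background(sample, background) == pytest.approx(expected)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(np.nan, 7.0)


# --- mask_volume -----------------------------------------------------------

class TestMaskVolume:
    def test_uniform_volume_fully_included(self):
        v = np.ones((4, 4, 2, 5))
        assert mask_volume(v, 0.05).all()

    def test_zero_background_excluded(self):
        v = np.zeros((4, 4, 2, 5))
        v[1, 1, 0, :] = 100.0
        mask = mask_volume(v, 0.05)
        assert mask[1, 1, 0]
        assert mask.sum() == 1

    def test_threshold_one_keeps_only_max(self):
        v = np.zeros((3, 3, 1, 2))
        v[..., 0] = np.arange(9).reshape(3, 3, 1)
        v[..., 1] = 0.0
        mask = mask_volume(v, 1.0)
        assert mask.sum() == 1
        assert mask[2, 2, 0]

    def test_non_4d_rejected(self):
        with pytest.raises(ValueError, match="4-D"):
            mask_volume(np.zeros((4, 4, 2)))


# --- fit_volume ------------------------------------------------------------

class TestFitVolume:
    def test_per_voxel_failures_do_not_abort(self, cpmg40):
        v = np.zeros((2, 2, 1, 40))
        v[0, 0, 0] = mono_decay(MonoParams(100.0, 50.0), cpmg40.times)
        v[1, 1, 0] = np.nan  # poisoned voxel
        mask = np.ones((2, 2, 1), bool)
        fitted = fit_volume(v, cpmg40, mask=mask)
        assert fitted.mono[0, 0, 0].converged
        assert not fitted.mono[1, 1, 0].converged

    def test_schedule_mismatch_rejected(self, cpmg40):
        with pytest.raises(ValueError, match="schedule"):
            fit_volume(np.zeros((2, 2, 1, 39)), cpmg40)
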