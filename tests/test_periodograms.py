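import numpy as np
import pytest
from scipy.signal import lombscargle as scipy_lombscargle

from serialrhythm import (
    SectionSpec,
    ValidationError,
    lomb_scargle,
    lsp_threshold,
    peak_period,
    serial_periodogram,
    sokolove_bushell,
)
from serialrhythm import synth
from serialrhythm.periodograms import Periodogram

TWO_PI = 2 * np.pi


class TestSokoloveBushell:
    def test_hand_computed_square(self):
        # [1,1,0,0] x 2: between-columns sum 1, total sum 2, K = 2 -> Q = 8
        y = np.array([1.0, 1, 0, 0, 1, 1, 0, 0])
        pg = sokolove_bushell(y, [4])
        assert pg.statistic[0] == pytest.approx(8.0)
        assert pg.percent_variance[0] == pytest.approx(100.0)
        assert pg.K[0] == 2

    def test_any_periodic_pattern_is_100pct(self, rng):
        pattern = rng.random(17)
        y = np.tile(pattern, 6)
        pg = sokolove_bushell(y, [17])
        assert pg.percent_variance[0] == pytest.approx(100.0)

    def test_subharmonic_peaks(self):
        ts = synth.square_wave(duration=1200.0, dt=1.0, period=50.0)
        periods = np.arange(30, 160)
        pg = sokolove_bushell(ts.values, periods)
        for P in (50, 100, 150):
            assert pg.percent_variance[periods == P][0] == pytest.approx(100.0)
        med = np.median(pg.percent_variance)
        assert pg.percent_variance[periods == 100][0] >= med

    def test_percent_variance_bounded(self, rng):
        y = rng.normal(0, 1, 400)
        pg = sokolove_bushell(y, np.arange(10, 100))
        assert np.all(pg.percent_variance >= 0) and np.all(pg.percent_variance <= 100)

    def test_constant_series_error(self):
        with pytest.raises(ValidationError):
            sokolove_bushell(np.full(100, 2.0), [10])

    def test_too_few_cycles_error(self):
        with pytest.raises(ValidationError):
            sokolove_bushell(np.arange(30.0), [20])

    def test_df_modes(self, rng):
        y = rng.normal(0, 1, 300)
        a = sokolove_bushell(y, [30], df_mode="cycles")
        b = sokolove_bushell(y, [30], df_mode="period")
        np.testing.assert_allclose(a.statistic, b.statistic)
        assert a.threshold[0] != b.threshold[0]


class TestLombScargle:
    def make_sinusoid(self, n_days=10):
        return synth.sinusoid(duration=n_days * 1440.0, dt=15.0, period=1440.0)

    def test_floating_max_is_one(self):
        ts = self.make_sinusoid()
        periods = np.arange(1200.0, 1700.0, 15.0)
        pg = lomb_scargle(ts.values, periods, dt=15.0, floating=True)
        assert pg.statistic.max() == pytest.approx(1.0, abs=1e-6)
        assert periods[pg.statistic.argmax()] == 1440.0

    def test_standard_max_is_half_n_minus_one(self):
        ts = self.make_sinusoid()
        periods = np.arange(1200.0, 1700.0, 15.0)
        pg = lomb_scargle(ts.values, periods, dt=15.0, floating=False)
        assert pg.statistic.max() == pytest.approx((ts.n - 1) / 2.0, rel=1e-6)

    def test_matches_scipy_oracle(self, rng):
        y = rng.normal(0, 1, 200) + np.sin(TWO_PI * np.arange(200) / 23.7)
        t = np.arange(200.0)
        periods = np.linspace(10, 80, 50)
        ours = lomb_scargle(y, periods, times=t, floating=False)
        ref = scipy_lombscargle(t, y - y.mean(), TWO_PI / periods) / np.var(y, ddof=1)
        np.testing.assert_allclose(ours.statistic, ref, rtol=1e-9, atol=1e-9)

    def test_no_subharmonic_response(self):
        ts = synth.square_wave(duration=1200.0, dt=1.0, period=50.0)
        periods = np.arange(30.0, 160.0)
        pg = lomb_scargle(ts.values, periods, dt=1.0, floating=True)
        for P in (100.0, 150.0):
            idx = np.where(periods == P)[0][0]
            assert not pg.significant[idx]
        assert pg.significant[np.where(periods == 50.0)[0][0]]

    def test_standard_invariant_to_constant(self, rng):
        y = rng.normal(0, 1, 120)
        periods = np.linspace(10, 50, 30)
        a = lomb_scargle(y, periods, dt=1.0).statistic
        b = lomb_scargle(y + 100.0, periods, dt=1.0).statistic
        np.testing.assert_allclose(a, b, rtol=1e-8)

    def test_floating_invariant_to_affine(self, rng):
        y = rng.normal(0, 1, 120)
        periods = np.linspace(10, 50, 30)
        a = lomb_scargle(y, periods, dt=1.0, floating=True).statistic
        b = lomb_scargle(3.5 * y - 7.0, periods, dt=1.0, floating=True).statistic
        np.testing.assert_allclose(a, b, rtol=1e-8)

    def test_nonuniform_times_accepted(self, rng):
        t = np.sort(rng.uniform(0, 500, 300))
        y = np.sin(TWO_PI * t / 50.0) + rng.normal(0, 0.2, 300)
        pg = lomb_scargle(y, np.linspace(20, 100, 81), times=t, floating=True)
        assert abs(pg.tested_periods[pg.statistic.argmax()] - 50.0) <= 2.0

    def test_period_grid_validation(self):
        ts = self.make_sinusoid(2)
        with pytest.raises(ValidationError):
            lomb_scargle(ts.values, [10.0], dt=15.0)  # below 2*dt
        with pytest.raises(ValidationError):
            lomb_scargle(ts.values, [1e9], dt=15.0)

    def test_constant_series_error(self):
        with pytest.raises(ValidationError):
            lomb_scargle(np.full(50, 1.0), [10.0], dt=1.0)


class TestLspThreshold:
    def test_floating_n100(self):
        # direct evaluation of the reconstructed formula
        expected = 1.0 - (1.0 - 0.95 ** (1.0 / 100)) ** (2.0 / 97)
        assert lsp_threshold(100, 0.05, floating=True) == pytest.approx(expected)
        assert expected == pytest.approx(0.1445, abs=5e-4)

    def test_monotone_decreasing_in_p(self):
        ps = [0.001, 0.01, 0.05, 0.2, 0.5]
        for floating in (True, False):
            vals = [lsp_threshold(200, p, floating=floating) for p in ps]
            assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_standard_prefactor(self):
        bracket = lsp_threshold(100, 0.05, floating=True)
        assert lsp_threshold(100, 0.05, floating=False) == pytest.approx(49.0 * bracket)

    def test_validation(self):
        with pytest.raises(ValidationError):
            lsp_threshold(4, 0.05)
        with pytest.raises(ValidationError):
            lsp_threshold(100, 1.5)

    def test_false_alarm_calibration_small(self, rng):
        """Reduced-size Monte-Carlo: the family-wise false-positive rate under
        white noise stays within a binomial band of the nominal level (the
        full 1000-replicate run lives in the acceptance suite)."""
        N, reps = 200, 200
        periods = N / np.arange(1.0, N // 2 + 1)[::-1]
        thr = lsp_threshold(N, 0.05, floating=True)
        count = 0
        for _ in range(reps):
            y = rng.normal(0, 1, N)
            pg = lomb_scargle(y, periods, dt=1.0, floating=True)
            count += pg.statistic.max() > thr
        assert 0.0 <= count / reps <= 0.12


class TestPeakTracking:
    def test_single_peak(self):
        pg = Periodogram(
            tested_periods=np.array([10.0, 20.0, 30.0]),
            statistic=np.array([1.0, 5.0, 2.0]),
            percent_variance=np.zeros(3),
            method="sokolove_bushell",
            threshold=np.full(3, 3.0),
            significant=np.array([False, True, False]),
            N=100,
        )
        track = peak_period(pg)
        assert track.period == 20.0 and track.significant

    def test_flat_ties_to_shortest(self):
        pg = Periodogram(
            tested_periods=np.array([10.0, 20.0, 30.0]),
            statistic=np.ones(3),
            percent_variance=np.zeros(3),
            method="sokolove_bushell",
            threshold=np.full(3, 3.0),
            significant=np.zeros(3, bool),
            N=100,
        )
        track = peak_period(pg)
        assert track.period == 10.0 and not track.significant

    def test_exact_grid_recovery(self):
        ts = synth.sinusoid(duration=2000.0, dt=1.0, period=137.0)
        periods = np.arange(100, 180, dtype=float)
        pg = lomb_scargle(ts.values, periods, dt=1.0, floating=True)
        assert peak_period(pg).period == 137.0


class TestSerialPeriodogram:
    def test_stationary_rows_peak_at_1440(self):
        ts = synth.sinusoid(duration=20 * 1440.0, dt=15.0, period=1440.0)
        spec = SectionSpec(10 * 96, 96, 96.0)
        periods = np.arange(88, 105, dtype=float)  # samples: 1320-1560 min
        sp = serial_periodogram(ts, spec, periods, method="lomb_scargle_floating")
        np.testing.assert_allclose(sp.peak_periods * 15.0, 1440.0)

    def test_period_step_transition_bounded(self, period_step_series):
        spec = SectionSpec(10 * 96, 96, 96.0)
        periods = np.arange(88, 110, dtype=float)
        sp = serial_periodogram(
            period_step_series, spec, periods, method="lomb_scargle_floating"
        )
        minutes = sp.peak_periods * 15.0
        assert minutes[0] == pytest.approx(1440.0, abs=15.0)
        assert minutes[-1] == pytest.approx(1500.0, abs=15.0)
        in_transition = np.sum((minutes > 1440.0) & (minutes < 1500.0))
        assert in_transition <= 10  # at most l/s sections

    def test_two_components_then_merge(self):
        """Two close periods during the first regime, one intermediate
        rhythm afterwards."""
        dt = 15.0
        part1 = synth.two_component(30 * 1440.0, dt, 1380.0, 1440.0)
        part2 = synth.sinusoid(30 * 1440.0, dt, period=1410.0)
        values = np.concatenate([part1.values, part2.values])
        ts = part1.copy_with(values)
        spec = SectionSpec(20 * 96, 5 * 96, 96.0)
        periods = np.arange(85, 105, dtype=float)
        sp = serial_periodogram(ts, spec, periods, method="lomb_scargle_floating")
        first_row, last_row = sp.matrix[0], sp.matrix[-1]
        # first regime: local maxima at both programmed periods
        local_max = [
            i
            for i in range(1, len(periods) - 1)
            if first_row[i] > first_row[i - 1] and first_row[i] > first_row[i + 1]
        ]
        peaks_min = periods[local_max] * dt
        assert any(abs(p - 1380.0) <= 30.0 for p in peaks_min)
        assert any(abs(p - 1440.0) <= 30.0 for p in peaks_min)
        assert periods[np.argmax(last_row)] * dt == pytest.approx(1410.0, abs=15.0)

    def test_sbp_requires_two_cycles(self):
        ts = synth.sinusoid(duration=3 * 1440.0, dt=15.0, period=1440.0)
        with pytest.raises(ValidationError):
            serial_periodogram(
                ts, SectionSpec(96, 96, 96.0), np.array([96.0]), method="sokolove_bushell"
            )
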