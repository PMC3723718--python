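import numpy as np
import pytest

from serialrhythm import (
    Dichotomizer,
    FlankConfig,
    PhaseTrackConfig,
    ValidationError,
    acrophase,
    alpha_duration,
    cog_circular,
    cog_linear,
    flank_heaviside,
    flank_squarewave,
    flank_threshold,
    track_phase,
)
from serialrhythm.phase import FlankEstimate, _square_template

TWO_PI = 2 * np.pi


def grid_search_acrophase(y: np.ndarray, n_grid: int = 20000) -> float:
    """Oracle: phase maximizing the correlation with a cosine template."""
    n = y.size
    i = np.arange(1, n + 1)
    phis = np.linspace(0, TWO_PI, n_grid, endpoint=False)
    best, best_r = 0.0, -np.inf
    yc = y - y.mean()
    for phi in phis:
        t = np.cos(TWO_PI * i / n - phi)
        r = np.dot(yc, t - t.mean())
        denom = np.linalg.norm(t - t.mean())
        r = r / denom if denom else -np.inf
        if r > best_r:
            best, best_r = phi, r
    return best


class TestAcrophase:
    def test_cosine_peak_at_6_of_24(self):
        i = np.arange(1, 25)
        y = 2 + np.cos(TWO_PI * (i - 6) / 24.0)
        est = acrophase(y)
        assert est.angle == pytest.approx(np.pi / 2, abs=1e-9)
        # independent oracle: grid-search correlation with a cosine template
        assert est.angle == pytest.approx(grid_search_acrophase(y), abs=TWO_PI / 20000 + 1e-9)

    @pytest.mark.parametrize("i0", [1, 5, 18, 24])
    def test_single_point_mass(self, i0):
        y = np.zeros(24)
        y[i0 - 1] = 3.0
        diff = (acrophase(y).angle - TWO_PI * i0 / 24) % TWO_PI
        assert min(diff, TWO_PI - diff) < 1e-12

    def test_zero_vector_error(self):
        with pytest.raises(ValidationError, match="undefined phase"):
            acrophase(np.zeros(24))

    def test_identity_with_circular_cog(self, rng):
        for _ in range(100):
            y = rng.random(rng.integers(8, 48))
            assert acrophase(y).angle == pytest.approx(cog_circular(y).angle, abs=1e-9)

    def test_rotation_equivariance(self, rng):
        y = rng.random(24)
        base = acrophase(y).angle
        for r in (1, 5, 11):
            rotated = np.roll(y, r)
            expected = (base + TWO_PI * r / 24) % TWO_PI
            assert acrophase(rotated).angle == pytest.approx(expected, abs=1e-9)


class TestCogLinear:
    def test_single_event(self):
        y = np.zeros(24)
        y[17] = 1.0  # sample i = 18
        assert cog_linear(y).angle == pytest.approx(3 * np.pi / 2)

    def test_symmetric_hump(self):
        n = 24
        i = np.arange(1, n + 1)
        y = np.exp(-((i - n / 2) ** 2) / 4.0)
        assert cog_linear(y).angle == pytest.approx(np.pi, abs=1e-9)

    def test_wrapped_square_artifact(self, wrapped_square):
        """The linear c.o.g. lands in the trough of a boundary-straddling
        wave; the circular one stays at the true center (~midnight)."""
        lin = cog_linear(wrapped_square).time_in_cycle(24.0)
        circ = cog_circular(wrapped_square).time_in_cycle(24.0)
        # true center: activity 20:00-04:00 -> center at 24:00 (= 0 h)
        circ_dist = min(circ, 24 - circ)
        assert circ_dist < 1.0
        assert 8.0 < lin < 16.0  # deep inside the inactive trough

    def test_rotation_equivariance_fails_on_wrap(self, wrapped_square):
        base = cog_linear(wrapped_square).angle
        rolled = cog_linear(np.roll(wrapped_square, 12)).angle
        expected = (base + TWO_PI * 12 / 24) % TWO_PI
        assert abs((rolled - expected + np.pi) % TWO_PI - np.pi) > 0.5

    def test_negative_warning_flag(self):
        y = np.ones(10)
        y[0] = -0.5
        assert "negative_values" in cog_linear(y).flags


class TestCogCircular:
    def test_uniform_undefined(self):
        est = cog_circular(np.ones(24))
        assert est.a == pytest.approx(0.0, abs=1e-12)
        assert est.b == pytest.approx(0.0, abs=1e-12)
        assert "undefined_angle" in est.flags and np.isnan(est.angle)

    def test_rotation_equivariance(self, rng):
        y = rng.random(36)
        base = cog_circular(y).angle
        for r in (2, 9, 30):
            expected = (base + TWO_PI * r / 36) % TWO_PI
            assert cog_circular(np.roll(y, r)).angle == pytest.approx(expected, abs=1e-9)

    def test_zero_sum_error(self):
        with pytest.raises(ValidationError):
            cog_circular(np.zeros(12))


def exhaustive_square_fit(y: np.ndarray) -> tuple[int, int, float]:
    """Oracle: best (c, d) over every circular pair, by direct correlation."""
    n = y.size
    best = None
    best_r = -np.inf
    for c in range(n):
        for d in range(n):
            if (d - c) % n == 0:
                continue
            t = _square_template(n, c, d)
            tc = t - t.mean()
            yc = y - y.mean()
            denom = np.linalg.norm(tc) * np.linalg.norm(yc)
            if denom == 0:
                continue
            r = float(np.dot(tc, yc) / denom)
            if r > best_r + 1e-12:
                best, best_r = (c, d), r
    return best[0], best[1], best_r


class TestFlankHeaviside:
    def test_clean_onset(self):
        y = np.concatenate([np.zeros(12), np.ones(12)])
        est = flank_heaviside(y, sign="+")
        assert est.onset == 13.0 and est.fit_r == pytest.approx(1.0)

    def test_clean_offset(self):
        y = np.concatenate([np.ones(12), np.zeros(12)])
        est = flank_heaviside(y, sign="-")
        assert est.offset == 13.0 and est.fit_r == pytest.approx(1.0)

    def test_constant_error(self):
        with pytest.raises(ValidationError):
            flank_heaviside(np.ones(24), FlankConfig(dichotomize_first=False))

    def test_full_onset_grid_exact(self):
        for onset in range(2, 24):
            y = np.zeros(24)
            y[onset - 1 :] = 1.0
            assert flank_heaviside(y, sign="+").onset == float(onset)

    def test_noisy_recovery_95pct(self, rng):
        true_onset = 9
        hits = 0
        for _ in range(200):
            y = np.zeros(48)
            y[true_onset - 1 : true_onset - 1 + 24] = 1.0
            y = y + rng.normal(0, 0.2, 48)  # SNR 5
            est = flank_heaviside(y, FlankConfig(threshold=Dichotomizer("median")))
            if abs(est.onset - true_onset) <= 2:
                hits += 1
        assert hits >= 0.95 * 200


class TestFlankSquarewave:
    def test_clean_square(self):
        y = np.zeros(24)
        y[6:18] = 1.0  # active samples 7..18, offset at 19
        est = flank_squarewave(y)
        assert (est.onset, est.offset) == (7.0, 19.0)
        assert est.converged and est.iterations == 1
        assert est.fit_r == pytest.approx(1.0)

    def test_wrapping_square_matches_oracle(self, wrapped_square):
        est = flank_squarewave(wrapped_square)
        c, d, r = exhaustive_square_fit(wrapped_square)
        assert (est.onset, est.offset) == (c + 1.0, d + 1.0) == (20.0, 5.0)
        assert est.fit_r == pytest.approx(r)

    def test_full_position_grid_exact(self):
        n = 24
        for onset0 in range(0, n, 3):
            for width in (4, 8, 12, 16):
                y = _square_template(n, onset0, (onset0 + width) % n)
                est = flank_squarewave(y)
                assert est.onset == onset0 + 1.0
                assert est.offset == (onset0 + width) % n + 1.0
                assert est.converged

    def test_noisy_recovery_90pct(self, rng):
        c_true, d_true = 7, 19
        hits = 0
        for _ in range(200):
            y = np.zeros(24)
            y[c_true - 1 : d_true - 1] = 1.0
            y = y + rng.normal(0, 0.2, 24)
            est = flank_squarewave(y)
            if abs(est.onset - c_true) <= 2 and abs(est.offset - d_true) <= 2:
                hits += 1
        assert hits >= 0.90 * 200

    def test_serial_phases_tracked_within_half_cycle(self, rng):
        """Serial flank phases pass through track_phase; deviations from the
        extrapolated expectation stay within T/2."""
        raw = (6.0 + np.cumsum(rng.normal(0, 1.5, 30))) % 24.0
        out = track_phase(raw, PhaseTrackConfig(k=4, period_T=24.0))
        diffs = np.abs(np.diff(out))
        assert np.all(diffs <= 12.0 + 1.5 * 4)  # bounded steps, no 24 h jumps


class TestFlankThreshold:
    def test_sinusoid_mean_crossing(self):
        n = 96
        y = np.cos(TWO_PI * (np.arange(n) - 48) / n)  # minimum at 0, rises later
        idx = flank_threshold(y, cycle_T=n, mode="crossing_up")
        # analytic upward mean-crossing of cos(2*pi*(t-48)/96): t = 24
        assert abs(idx - 25.0) <= 1.0  # 1-based sample, within +/- 1

    def test_max_mode(self):
        y = np.cos(TWO_PI * (np.arange(48) - 20) / 48.0)
        assert flank_threshold(y, 48, mode="max") == 21.0

    def test_never_crossing_flagged(self):
        y = np.linspace(0.2, 0.4, 30)
        assert np.isnan(flank_threshold(y, 30, mode="crossing_down", threshold=5.0))

    def test_unknown_mode(self):
        with pytest.raises(ValidationError):
            flank_threshold(np.arange(10.0), 10, mode="bogus")


class TestAlphaDuration:
    def test_worked_example(self):
        est = FlankEstimate(onset=20.0, offset=4.0)
        assert alpha_duration(est, 24.0) == pytest.approx(8.0)

    def test_equal_flanks_zero(self):
        est = FlankEstimate(onset=5.0, offset=5.0)
        assert alpha_duration(est, 24.0) == 0.0

    def test_half_cycle_square(self):
        y = np.zeros(24)
        y[6:18] = 1.0
        est = flank_squarewave(y)
        out = alpha_duration(est, 24.0, dt_minutes=60.0)
        assert out["samples"] == 12.0
        assert out["hours"] == 12.0
        assert out["percent"] == 50.0

    def test_missing_flank(self):
        assert np.isnan(alpha_duration(FlankEstimate(onset=3.0), 24.0))
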