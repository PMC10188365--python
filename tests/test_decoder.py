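"""Decoder tests: half-splitting, clock integrals, derivative signal,
split-point search, baseline metrics and onset estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tests.conftest import make_profile
from xrikit import decoder as dec
from xrikit.decoder import (
    HalfProfile,
    fraction_grid,
    fraction_integral,
    onset_fraction,
    optimal_split,
    signal_from_half,
    split_at,
    trim_to_support,
)


def symmetric_profile(n_half=30, delta_d=1.0, seed=0):
    """Strictly mirror-symmetric profile with positive H (odd sample count)."""
    rng = np.random.default_rng(seed)
    h_half = rng.uniform(0.5, 2.0, n_half)
    f_half = rng.uniform(0.0, 1.0, n_half)
    h = np.concatenate([h_half[::-1], [1.0], h_half])
    f = np.concatenate([f_half[::-1], [0.5], f_half])
    return make_profile(h, f, delta_d=delta_d)


class TestSplitAt:
    def test_symmetric_split_gives_identical_halves(self):
        prof = symmetric_profile()
        left, right = split_at(prof, prof.length_um / 2)
        np.testing.assert_allclose(left.h, right.h)
        np.testing.assert_allclose(left.f, right.f)

    def test_half_lengths_sum_to_total(self):
        prof = make_profile(np.ones(40), np.zeros(40))
        left, right = split_at(prof, 10.0)
        total = (len(left.h) + len(right.h) + 1) * prof.delta_d_um
        assert abs(total - 40 * prof.delta_d_um) <= prof.delta_d_um

    def test_quarter_split_length_ratio(self):
        prof = make_profile(np.ones(41), np.zeros(41))
        left, right = split_at(prof, 0.25 * prof.length_um)
        assert len(right.h) / len(left.h) == pytest.approx(3.0, rel=0.15)

    def test_split_outside_profile_errors(self):
        prof = make_profile(np.ones(10), np.zeros(10))
        with pytest.raises(ValueError):
            split_at(prof, prof.length_um + 1.0)


class TestFractionIntegral:
    def test_hand_cumulative_sum(self):
        half = HalfProfile(h=[1.0, 1.0, 2.0], f=[0, 0, 0], delta_d=1.0)
        np.testing.assert_allclose(fraction_integral(half), [0.25, 0.5, 1.0])

    def test_constant_h_gives_linear_fraction(self):
        n = 20
        half = HalfProfile(h=np.ones(n), f=np.zeros(n), delta_d=0.5)
        np.testing.assert_allclose(fraction_integral(half), np.arange(1, n + 1) / n)

    def test_all_zero_h_errors(self):
        half = HalfProfile(h=np.zeros(5), f=np.ones(5), delta_d=1.0)
        with pytest.raises(ValueError):
            fraction_integral(half)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_nondecreasing_ends_at_one(self, seed):
        rng = np.random.default_rng(seed)
        half = HalfProfile(h=rng.uniform(0, 2, 25), f=np.zeros(25), delta_d=1.0)
        if half.h_integral[-1] <= 0:
            return
        frac = fraction_integral(half)
        assert np.all(np.diff(frac) >= 0)
        assert frac[-1] == pytest.approx(1.0)


class TestSignalFromHalf:
    def test_proportional_channels_give_constant_signal(self):
        rng = np.random.default_rng(3)
        h = rng.uniform(0.5, 2.0, 50)
        k = 3.7
        half = HalfProfile(h=h, f=k * h, delta_d=0.25)
        sig = signal_from_half(half, fraction_grid())
        expected = k * half.h_integral[-1]
        np.testing.assert_allclose(sig, expected, rtol=1e-9)

    def test_constant_channels_give_f_times_length(self):
        n, dd, f0 = 40, 0.5, 2.0
        half = HalfProfile(h=np.full(n, 1.3), f=np.full(n, f0), delta_d=dd)
        sig = signal_from_half(half, fraction_grid())
        np.testing.assert_allclose(sig, f0 * n * dd, rtol=1e-9)

    def test_hand_difference_quotients(self):
        half = HalfProfile(h=[1, 1, 1, 1], f=[0, 0, 2, 2], delta_d=1.0)
        grid = np.array([0.25, 0.5, 0.75, 1.0])
        np.testing.assert_allclose(
            signal_from_half(half, grid), [0.0, 0.0, 8.0, 8.0]
        )

    def test_zero_increment_merged_with_next(self):
        # middle sample contributes F but no clock advance; its F merges
        # into the next nonzero increment
        half = HalfProfile(h=[1.0, 0.0, 1.0], f=[1.0, 1.0, 1.0], delta_d=1.0)
        grid = np.array([0.5, 1.0])
        np.testing.assert_allclose(signal_from_half(half, grid), [2.0, 4.0])

    def test_too_few_samples_errors(self):
        half = HalfProfile(h=[1.0, 1.0], f=[0.0, 0.0], delta_d=1.0)
        with pytest.raises(ValueError):
            signal_from_half(half, fraction_grid())


def brute_force_split(profile, grid):
    """Independent exhaustive split search (oracle for optimal_split)."""
    h = profile.channel("HA")
    d = profile.d_um
    L = profile.length_um
    center = L / 2.0
    best = None
    for k in range(3, len(h) - 3):
        if not (center - 0.25 * L <= d[k] <= center + 0.25 * L):
            continue
        dd = profile.delta_d_um
        hl, fl = h[k - 1 :: -1], profile.channel("FLAG")[k - 1 :: -1]
        hr, fr = h[k + 1 :], profile.channel("FLAG")[k + 1 :]
        if hl.sum() <= 0 or hr.sum() <= 0:
            continue
        sl = signal_from_half(HalfProfile(h=hl, f=fl, delta_d=dd), grid)
        sr = signal_from_half(HalfProfile(h=hr, f=fr, delta_d=dd), grid)
        ssd = float(np.sum((sl - sr) ** 2))
        key = (ssd, abs(d[k] - center), k)
        if best is None or key < best[0]:
            best = (key, k)
    return best[1]


class TestOptimalSplit:
    def test_symmetric_profile_splits_at_center_with_zero_ssd(self):
        prof = symmetric_profile()
        sig = optimal_split(prof)
        assert sig.split_arc_um == pytest.approx(prof.length_um / 2)
        assert sig.ssd == pytest.approx(0.0, abs=1e-18)

    def test_off_center_mirror_point_is_found(self):
        # profile mirror-symmetric about the 60%-arc point, inside the
        # center +/- 25% search range
        n_half = 20
        rng = np.random.default_rng(5)
        h_half = rng.uniform(0.5, 2.0, n_half)
        f_half = rng.uniform(0.0, 1.0, n_half)
        h = np.concatenate([np.ones(10), h_half[::-1], [1.0], h_half])
        f = np.concatenate([np.zeros(10), f_half[::-1], [0.7], f_half])
        prof = make_profile(h, f)
        mirror_index = 10 + n_half
        sig = optimal_split(prof)
        assert abs(sig.split_index - mirror_index) <= 1

    def test_matches_brute_force_oracle(self):
        grid = fraction_grid()
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(20, 60))
            prof = make_profile(
                rng.uniform(0.2, 2.0, n), rng.uniform(0.0, 1.5, n)
            )
            assert optimal_split(prof, grid=grid).split_index == brute_force_split(
                prof, grid
            )

    def test_too_short_profile_errors(self):
        with pytest.raises(ValueError):
            optimal_split(make_profile(np.ones(5), np.ones(5)))


class TestSignalMetrics:
    def test_baseline_constant_signal(self):
        sig = dec.DecodedSignal(grid=fraction_grid(), f_signal=np.full(201, 4.2))
        assert dec.baseline(sig) == pytest.approx(4.2)

    def test_baseline_hand_window_mean(self):
        grid = fraction_grid()
        vals = np.where(grid <= 0.05, 1.0, 9.0)
        sig = dec.DecodedSignal(grid=grid, f_signal=vals)
        assert dec.baseline(sig) == pytest.approx(1.0)

    def test_end_center_ratio_levels(self):
        grid = fraction_grid()
        sig = dec.DecodedSignal(grid=grid, f_signal=np.full(201, 2.0))
        assert dec.end_center_ratio(sig) == pytest.approx(1.0)
        vals = np.where(grid < 0.5, 1.0, 3.0)
        sig = dec.DecodedSignal(grid=grid, f_signal=vals)
        assert dec.end_center_ratio(sig) == pytest.approx(3.0)

    def test_end_center_ratio_linear_hand_windows(self):
        grid = fraction_grid()
        sig = dec.DecodedSignal(grid=grid, f_signal=1.0 + grid)
        center = np.mean(1.0 + grid[grid <= 0.05])
        end = np.mean(1.0 + grid[grid >= 0.95])
        assert dec.end_center_ratio(sig) == pytest.approx(end / center)

    def test_nonpositive_center_flagged(self):
        sig = dec.DecodedSignal(grid=fraction_grid(), f_signal=np.zeros(201))
        with pytest.raises(ValueError):
            dec.end_center_ratio(sig)

    def test_relative_change(self):
        grid = fraction_grid()
        sig = dec.DecodedSignal(grid=grid, f_signal=np.full(201, 5.0))
        np.testing.assert_allclose(dec.relative_change(sig), 0.0)
        vals = np.where(grid < 0.5, 2.0, 3.0)
        sig = dec.DecodedSignal(grid=grid, f_signal=vals)
        rel = dec.relative_change(sig)
        assert rel[-1] == pytest.approx(0.5)
        sig7 = dec.DecodedSignal(grid=grid, f_signal=7.0 * vals)
        np.testing.assert_allclose(dec.relative_change(sig7), rel)


class TestOnsetFraction:
    def test_piecewise_linear_rise_recovers_breakpoint(self):
        grid = fraction_grid()
        net = np.clip((grid - 0.4) / 0.4, 0.0, 1.0)
        sig = dec.DecodedSignal(grid=grid, f_signal=net)
        est = onset_fraction(sig)
        assert est.ok
        assert est.onset == pytest.approx(0.4, abs=1e-6)

    def test_flat_signal_flags_no_rise(self):
        sig = dec.DecodedSignal(grid=fraction_grid(), f_signal=np.full(201, 3.0))
        est = onset_fraction(sig)
        assert "no-rise" in est.flags

    def test_logistic_rise_matches_independent_refit(self):
        grid = fraction_grid()
        vals = 1.0 / (1.0 + np.exp(-(grid - 0.6) / 0.04))
        sig = dec.DecodedSignal(grid=grid, f_signal=vals)
        est = onset_fraction(sig)
        assert est.ok
        # independent least-squares refit on the same rising set
        base = dec.baseline(sig)
        net = vals - base
        peak = net.max()
        run = np.nonzero((net >= 0.1 * peak) & (net <= 0.5 * peak))[0]
        run = run[run < np.argmax(net)]
        x, y = grid[run], net[run]
        xm, ym = x.mean(), y.mean()
        slope = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
        onset_oracle = xm - ym / slope
        assert est.onset == pytest.approx(onset_oracle, abs=1e-9)

    def test_scale_equivariance_and_invariance(self):
        grid = fraction_grid()
        rng = np.random.default_rng(11)
        h = rng.uniform(0.5, 2.0, 41)
        f = np.concatenate([np.zeros(20), np.linspace(0, 2, 21)])
        prof = make_profile(h, f)
        prof_scaled = make_profile(h, 5.0 * f)
        sig = optimal_split(prof)
        sig_scaled = optimal_split(prof_scaled)
        np.testing.assert_allclose(sig_scaled.f_signal, 5.0 * sig.f_signal, rtol=1e-9)
        est, est_scaled = onset_fraction(sig), onset_fraction(sig_scaled)
        if est.ok:
            assert est_scaled.onset == pytest.approx(est.onset, abs=1e-9)


class TestInvariances:
    def test_arc_reparameterization_invariance(self):
        """Resampling the arc axis (halving the step, duplicating mass into
        finer bins) leaves a half's decoded signal unchanged: the clock
        axis absorbs any smooth reparameterization of arc length."""
        rng = np.random.default_rng(21)
        grid = fraction_grid()
        h = rng.uniform(0.5, 2.0, 30)
        f = rng.uniform(0.0, 1.0, 30)
        coarse = HalfProfile(h=h, f=f, delta_d=1.0)
        fine = HalfProfile(h=np.repeat(h, 2), f=np.repeat(f, 2), delta_d=0.5)
        stretched = HalfProfile(
            h=np.repeat(h, 3), f=np.repeat(f, 3), delta_d=1.0 / 3.0
        )
        # evaluate at the coarse native clock positions, where the
        # difference quotients are shared exactly across discretizations
        native = fraction_integral(coarse)
        ref = signal_from_half(coarse, native)
        for other in (fine, stretched):
            np.testing.assert_allclose(
                signal_from_half(other, native), ref, rtol=1e-9
            )
        # on the full grid the discretizations agree in integral (weak) sense
        a = np.trapezoid(signal_from_half(coarse, grid), grid)
        b = np.trapezoid(signal_from_half(fine, grid), grid)
        assert b == pytest.approx(a, rel=0.05)

    def test_trim_to_support_drops_faint_tails(self):
        h = np.concatenate([np.full(3, 0.01), np.ones(30), np.full(4, 0.01)])
        f = np.ones_like(h)
        prof = make_profile(h, f)
        trimmed = trim_to_support(prof)
        assert trimmed.n_samples == 30
        assert trimmed.channel("HA").min() == pytest.approx(1.0)

    def test_trim_keeps_fully_supported_profile(self):
        prof = make_profile(np.ones(20), np.zeros(20))
        assert trim_to_support(prof).n_samples == 20
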