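"""Channel fusion, gap detection, surrogate and PCHIP imputation."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from physiomot import (
    ChannelWindow,
    TimestampedSeries,
    detect_gaps,
    fuse_channels_by_sqi,
    generate_surrogate_ensemble,
    pchip_impute_hourly,
    simple_bsqi,
    surrogate_impute,
)

from conftest import make_series


def _win(start, ch, sqi, value=1.0):
    t = start + np.arange(10.0)
    return ChannelWindow(start, ch, sqi, t, np.full(10, value))


class TestFuseChannels:
    def test_highest_sqi_channel_kept(self):
        fused, prov = fuse_channels_by_sqi([_win(0, 1, 0.80, 5.0), _win(0, 2, 0.60, 9.0)])
        assert prov[0]["chosen_channel"] == 1
        assert np.all(fused.v == 5.0)

    def test_threshold_is_strict(self):
        fused, prov = fuse_channels_by_sqi([_win(0, 1, 0.75), _win(0, 2, 0.70)])
        assert len(fused) == 0
        assert prov[0]["chosen_channel"] is None

    def test_tie_breaks_to_lowest_channel(self):
        fused, prov = fuse_channels_by_sqi([_win(0, 2, 1.0, 3.0), _win(0, 1, 1.0, 3.0)])
        assert prov[0]["chosen_channel"] == 1
        assert np.all(fused.v == 3.0)

    def test_no_kept_window_at_or_below_threshold(self):
        rng = np.random.default_rng(0)
        windows = [
            _win(60.0 * i, ch, float(rng.uniform(0.5, 1.0)))
            for i in range(20) for ch in (1, 2, 3)
        ]
        _, prov = fuse_channels_by_sqi(windows)
        for rec in prov:
            if rec["chosen_channel"] is not None:
                assert rec["sqi"] > 0.75


class TestSimpleBsqi:
    @staticmethod
    def _pulse_train(fs=125.0, dur=30.0, bpm=60.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(int(dur * fs)) / fs
        x = np.zeros_like(t)
        for beat in np.arange(0.5, dur, 60.0 / bpm):
            x += 1.2 * np.exp(-((t - beat) ** 2) / (2 * 0.008**2))
        return x + noise * rng.standard_normal(len(t))

    def test_clean_pulse_train_scores_one(self):
        assert simple_bsqi(self._pulse_train(), fs=125.0) == pytest.approx(1.0)

    def test_white_noise_scores_low(self):
        rng = np.random.default_rng(1)
        scores = [
            simple_bsqi(rng.standard_normal(int(30 * 125)), fs=125.0)
            for _ in range(30)
        ]
        assert np.median(scores) < 0.5

    def test_monotone_in_noise(self):
        scores = [
            np.mean([simple_bsqi(self._pulse_train(noise=s, seed=k), 125.0) for k in range(5)])
            for s in (0.0, 0.5, 1.5)
        ]
        assert scores[0] >= scores[1] >= scores[2] - 0.05


class TestDetectGaps:
    def test_single_gap(self):
        gaps = detect_gaps(make_series([0, 1, 2, 40, 41]), th_g=30)
        assert len(gaps) == 1
        assert (gaps[0].t_b, gaps[0].t_e, gaps[0].g_l) == (2, 40, 38)

    def test_uniform_series_has_none(self):
        gaps = detect_gaps(make_series(np.arange(100.0)), th_g=2.0)
        assert gaps == []

    def test_sorted_by_increasing_length(self):
        t = np.concatenate([[0], [50], np.arange(51, 60), [95], np.arange(96, 100), [180]])
        gaps = detect_gaps(make_series(np.sort(t)), th_g=30)
        assert [g.g_l for g in gaps] == sorted(g.g_l for g in gaps)

    def test_singleton_series(self):
        assert detect_gaps(make_series([3.0]), th_g=1) == []


class TestSurrogateImpute:
    def test_no_gaps_identity(self):
        s = make_series(np.arange(100.0), np.sin(np.arange(100.0)))
        out = surrogate_impute(s, th_g=5.0, seed=0)
        assert out is s

    def test_constant_series_filled_exactly(self):
        t = np.concatenate([np.arange(0, 50.0), np.arange(80.0, 130.0)])
        s = make_series(t, np.full(len(t), 3.5))
        out = surrogate_impute(s, th_g=10.0, noise_frac=0.0, seed=1)
        assert np.all(out.v == 3.5)
        assert detect_gaps(out, 10.0) == []

    def test_deterministic_and_seed_sensitive(self, gappy_ar1):
        a = surrogate_impute(gappy_ar1, th_g=10.0, seed=5)
        b = surrogate_impute(gappy_ar1, th_g=10.0, seed=5)
        assert np.array_equal(a.t, b.t) and np.array_equal(a.v, b.v)
        outs = {surrogate_impute(gappy_ar1, th_g=10.0, seed=k).v.sum() for k in range(10)}
        assert len(outs) > 1

    def test_original_samples_preserved_and_span_covered(self, gappy_ar1):
        out = surrogate_impute(gappy_ar1, th_g=10.0, seed=2)
        idx = np.searchsorted(out.t, gappy_ar1.t)
        assert np.allclose(out.t[idx], gappy_ar1.t)
        assert np.allclose(out.v[idx], gappy_ar1.v)
        assert out.t[0] == gappy_ar1.t[0] and out.t[-1] == gappy_ar1.t[-1]
        assert np.all(np.diff(out.t) > 0)

    def test_random_gap_configurations_all_closed(self):
        """After imputation no gap above threshold remains (50 configs)."""
        rng = np.random.default_rng(99)
        base_t = np.arange(3000.0)
        base_v = np.sin(base_t / 50.0) + rng.normal(0, 0.2, len(base_t))
        for trial in range(50):
            keep = np.ones(len(base_t), dtype=bool)
            for _ in range(rng.integers(1, 5)):
                lo = int(rng.integers(200, 2500))
                keep[lo : lo + int(rng.integers(15, 120))] = False
            s = TimestampedSeries(base_t[keep], base_v[keep])
            out = surrogate_impute(s, th_g=10.0, seed=trial)
            assert detect_gaps(out, 10.0) == []

    def test_impossible_donor_raises(self):
        # gap longer than all data on either side
        t = np.concatenate([np.arange(0, 20.0), np.arange(500.0, 520.0)])
        s = make_series(t, np.ones(len(t)))
        with pytest.raises(ValueError, match="donor"):
            surrogate_impute(s, th_g=60.0, seed=0)

    def test_mask_and_recover_distribution(self, gappy_ar1):
        """Imputed values are distributed like the donor data (KS test)."""
        pvals = []
        for seed in range(50):
            out = surrogate_impute(gappy_ar1, th_g=10.0, seed=seed)
            new = np.setdiff1d(out.t, gappy_ar1.t)
            imputed = out.v[np.searchsorted(out.t, new)]
            pvals.append(ks_2samp(imputed, gappy_ar1.v).pvalue)
        assert np.median(pvals) > 0.01


class TestSurrogateEnsemble:
    def test_gap_free_members_identical(self):
        s = make_series(np.arange(200.0), np.cos(np.arange(200.0)))
        ens = generate_surrogate_ensemble(s, th_g=5.0, m=10, base_seed=3)
        assert len(ens) == 10
        assert all(np.array_equal(m.v, s.v) for m in ens.members)

    def test_members_differ_on_gappy_input(self, gappy_ar1):
        ens = generate_surrogate_ensemble(gappy_ar1, th_g=10.0, m=5, base_seed=0)
        sums = {m.v.sum() for m in ens.members}
        assert len(sums) == 5
        assert ens.member_seeds == [0, 1, 2, 3, 4]

    def test_ensemble_mean_tracks_donor_level(self, gappy_ar1):
        ens = generate_surrogate_ensemble(gappy_ar1, th_g=10.0, m=100, base_seed=1)
        new_means = []
        for m in ens.members:
            new = np.setdiff1d(m.t, gappy_ar1.t)
            new_means.append(m.v[np.searchsorted(m.t, new)].mean())
        grand = np.mean(new_means)
        mu, sd = gappy_ar1.v.mean(), gappy_ar1.v.std(ddof=1)
        se = sd / np.sqrt(len(new_means))
        # stationary AR(1): imputed-region mean within a few SE of signal mean
        assert abs(grand - mu) < 6 * se


class TestPchipHourly:
    def test_complete_hours_are_exact_sums(self):
        t = np.arange(0, 3 * 3600.0, 60.0)
        v = np.ones(len(t))
        out = pchip_impute_hourly(make_series(t, v))
        assert len(out) == 3
        assert np.allclose(out.v, 60.0)

    def test_interior_hour_no_overshoot(self):
        t = np.array([0.0, 1800.0, 2 * 3600.0 + 100.0])
        v = np.array([4.0, 6.0, 30.0])
        out = pchip_impute_hourly(make_series(t, v), t0=0.0, n_hours=3)
        assert 10.0 <= out.v[1] <= 30.0

    def test_linear_ramp_recovered_exactly(self):
        # hourly sums 10, 20, (missing 30), 40, 50 on a linear ramp
        hours = np.array([0, 1, 3, 4])
        vals = np.array([10.0, 20.0, 40.0, 50.0])
        out = pchip_impute_hourly(make_series(hours * 3600.0 + 1, vals), t0=0.0, n_hours=5)
        assert out.v[2] == pytest.approx(30.0)

    def test_edge_hours_nearest_filled(self):
        hours = np.array([2, 3])
        vals = np.array([7.0, 9.0])
        out = pchip_impute_hourly(make_series(hours * 3600.0, vals), t0=0.0, n_hours=6)
        assert np.allclose(out.v, [7, 7, 7, 9, 9, 9])
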