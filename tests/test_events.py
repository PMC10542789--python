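"""Trial segmentation, GoW/LoW labelling, PSTHs, z-scoring and window logic."""

import numpy as np
import pandas as pd
import pytest

import whiskvr as w
from whiskvr import events as ev
from whiskvr.events import (AlignmentError, PSTH, ResponseWindows, align_and_bin,
                            exclude_contaminated, find_transient_window,
                            label_gow_low, segment_trials, window_rates, zscore_psth)


class TestSegmentTrials:
    def test_recovers_simulator_movement_onsets(self, medium_session):
        cfg = medium_session.config
        got = segment_trials(medium_session.speed, medium_session.surface, cfg)
        truth = medium_session.trial_table
        # center draws produce no surface movement and are invisible in the traces
        moved = truth[(truth["outcome"] != "center") | truth["is_return"]]
        assert len(got) == len(moved)
        assert np.allclose(got["onset_time"].to_numpy(),
                           moved["onset_time"].to_numpy(), atol=2.0 / cfg.frame_rate)
        assert list(got["outcome"]) == list(moved["outcome"])
        assert list(got["is_return"]) == list(moved["is_return"])

    def test_constant_surface_zero_trials(self):
        cfg = w.SessionConfig(duration=10.0)
        n = cfg.n_frames
        out = segment_trials(np.full(n, 20.0), np.zeros(n), cfg)
        assert len(out) == 0

    def test_interonset_interval_from_constant_speed(self):
        cfg = w.SessionConfig(duration=60.0, seed=1, speed_noise_sd=0.0,
                              rest_bout_mean=0.0, mean_run_speed=20.0)
        speed = w.generate_locomotion(cfg)
        surface, _ = w.simulate_surface(speed, cfg)
        got = segment_trials(speed, surface, cfg)
        iois = np.diff(got["onset_time"].to_numpy())
        assert np.allclose(iois, 10.0, atol=0.05)


class TestLabelGowLow:
    def _trials(self, onsets):
        return pd.DataFrame({"onset_time": onsets,
                             "outcome": ["rostral"] * len(onsets),
                             "is_return": [False] * len(onsets),
                             "distance_covered": [200.0] * len(onsets)})

    def _events(self, rows):
        return pd.DataFrame(rows, columns=["time", "whisker_id", "kind", "origin",
                                           "direction", "repetition_index"])

    def test_gain_labels_gow(self):
        cfg = w.SessionConfig()
        out = label_gow_low(self._trials([10.0]),
                            self._events([(10.1, "C1", "GoW", "external", "rostral", 1)]),
                            cfg)
        assert bool(out["gow"][0]) and not bool(out["low"][0])

    def test_movement_without_contact_change_is_neither(self):
        cfg = w.SessionConfig()
        out = label_gow_low(self._trials([10.0]), self._events([]), cfg)
        assert not out["gow"][0] and not out["low"][0]

    def test_simultaneous_gain_and_loss_sets_both(self):
        cfg = w.SessionConfig()
        out = label_gow_low(self._trials([10.0]), self._events([
            (10.1, "C1", "GoW", "external", "rostral", 1),
            (10.15, "R1", "LoW", "external", "rostral", 1)]), cfg)
        assert bool(out["gow"][0]) and bool(out["low"][0])

    def test_agrees_with_ground_truth_on_synthetic_session(self, medium_session):
        cfg = medium_session.config
        trials = segment_trials(medium_session.speed, medium_session.surface, cfg)
        truth = medium_session.ground_truth.contact_events
        out = label_gow_low(trials, truth, cfg)
        ext = truth[truth["origin"] == "external"]
        for _, t in out.iterrows():
            lo, hi = t["onset_time"], t["onset_time"] + cfg.translation_duration + 0.05
            near = ext[(ext["time"] >= lo) & (ext["time"] < hi)]
            assert t["gow"] == bool((near["kind"] == "GoW").any())
            assert t["low"] == bool((near["kind"] == "LoW").any())


class TestPSTH:
    def test_spike_at_event_time_in_first_post_bin(self):
        p = align_and_bin(np.array([10.0]), np.array([10.0]),
                          window=(-0.5, 0.5), bin_width=0.1)
        idx = np.flatnonzero(p.counts[0])
        assert len(idx) == 1
        assert p.bin_edges[idx[0]] == pytest.approx(0.0)

    def test_poisson_rate_recovered(self, rng):
        lam, n_ev = 20.0, 200
        events = 100.0 * np.arange(n_ev)
        spikes = np.sort(np.concatenate(
            [t - 1.0 + np.sort(rng.uniform(0, 3.0, rng.poisson(lam * 3.0)))
             for t in events]))
        p = align_and_bin(spikes, events, window=(-1.0, 2.0), bin_width=0.05)
        se = np.sqrt(lam / (0.05 * n_ev))
        assert np.all(np.abs(p.rate - lam) < 4 * se)

    def test_identical_events_zero_sem(self):
        spikes = np.array([1.05, 1.15])
        p = align_and_bin(spikes, np.array([1.0, 1.0]), window=(-0.5, 0.5),
                          bin_width=0.1)
        assert np.all(p.sem == 0)

    def test_count_conservation(self, medium_session):
        st = next(iter(medium_session.spike_trains.values()))
        trials = medium_session.trial_table
        onsets = trials.loc[~trials["is_return"], "onset_time"].to_numpy()
        onsets = onsets[(onsets > 1.0) & (onsets < medium_session.duration - 2.0)]
        p = align_and_bin(st, onsets)
        total = sum(np.sum((st >= t - 1.0) & (st < t + 2.0)) for t in onsets)
        assert p.counts.sum() == total
        assert p.rate.sum() * p.bin_width * len(onsets) == pytest.approx(total)

    def test_zero_events_rejected(self):
        with pytest.raises(AlignmentError):
            align_and_bin(np.array([1.0]), np.array([]))


class TestZScore:
    def _psth(self, rng, shift=0.0, scale=1.0):
        counts = rng.poisson(5.0, size=(40, 60)).astype(float)
        counts = counts * scale + shift
        return PSTH(bin_edges=-1.0 + 0.05 * np.arange(61), counts=counts)

    def test_baseline_bins_near_standard_normal(self, rng):
        p = zscore_psth(self._psth(rng))
        base = p.z[(p.bin_centers >= -0.3) & (p.bin_centers < 0)]
        assert abs(base.mean()) < 1.0

    def test_location_and_scale_invariance_of_shape(self, rng):
        p0 = zscore_psth(self._psth(rng))
        rng2 = np.random.default_rng(1234)
        p1 = zscore_psth(self._psth(rng2, shift=3.0))
        rng3 = np.random.default_rng(1234)
        p2 = zscore_psth(self._psth(rng3, scale=2.5))
        assert np.allclose(p0.z, p1.z, atol=1e-9)
        assert np.allclose(p0.z, p2.z, atol=1e-9)

    def test_zero_variance_flagged_not_zeroed(self):
        p = PSTH(bin_edges=-1.0 + 0.05 * np.arange(61),
                 counts=np.ones((10, 60)))
        with pytest.raises(AlignmentError):
            zscore_psth(p)


class TestTransientWindow:
    def _psth_from_rate(self, rate_per_bin):
        counts = np.tile(rate_per_bin * 0.05, (50, 1))
        return PSTH(bin_edges=-0.5 + 0.05 * np.arange(len(rate_per_bin) + 1),
                    counts=counts)

    def test_boxcar_response_bracketed(self):
        rate = np.full(50, 10.0)
        lift = (np.arange(50) * 0.05 - 0.5 >= 0.05) & (np.arange(50) * 0.05 - 0.5 < 0.25)
        rate[lift] = 40.0
        win = find_transient_window(self._psth_from_rate(rate))
        assert win[0] <= 0.10 and win[1] >= 0.20
        assert 0.0 <= win[0] < win[1] <= 0.6 + 0.05

    def test_flat_psth_falls_back(self):
        win = find_transient_window(self._psth_from_rate(np.full(50, 10.0)))
        assert win == (0.0, 0.3)

    def test_higher_of_two_peaks_wins(self):
        rate = np.full(50, 10.0)
        centers = -0.5 + 0.05 * np.arange(50) + 0.025
        rate[np.abs(centers - 0.1) < 0.03] = 30.0
        rate[np.abs(centers - 0.4) < 0.03] = 60.0
        win = find_transient_window(self._psth_from_rate(rate))
        assert win[0] <= 0.4 <= win[1]
        assert win[0] > 0.15

    def test_invariant_to_constant_rate_offset(self):
        rate = np.full(50, 10.0)
        centers = -0.5 + 0.05 * np.arange(50) + 0.025
        rate[np.abs(centers - 0.15) < 0.06] = 35.0
        w0 = find_transient_window(self._psth_from_rate(rate))
        w1 = find_transient_window(self._psth_from_rate(rate + 100.0))
        assert w0 == w1


class TestWindowRates:
    def test_single_spike_rate(self):
        rates = window_rates(np.array([10.1]), np.array([10.0]), (0.0, 0.3))
        assert rates[0] == pytest.approx(1 / 0.3)

    def test_empty_train_zero(self):
        rates = window_rates(np.array([]), np.array([5.0, 9.0]), (-0.3, 0.0))
        assert np.all(rates == 0)

    def test_poisson_mean(self, rng):
        spikes = np.sort(rng.uniform(0, 1000.0, 15000))   # lambda = 15
        events = np.arange(10.0, 990.0, 10.0)
        for win in ((-0.3, 0.0), (0.0, 0.3), (1.0, 1.3)):
            r = window_rates(spikes, events, win)
            se = r.std(ddof=1) / np.sqrt(len(r))
            assert r.mean() == pytest.approx(15.0, abs=3 * se)

    def test_out_of_bounds_event_listed(self):
        with pytest.raises(AlignmentError, match="0.1"):
            window_rates(np.array([1.0]), np.array([0.1]), (-0.3, 0.0), duration=100.0)

    def test_contaminated_events_dropped(self):
        times = np.array([10.0, 10.2, 20.0, 20.5])
        kept = exclude_contaminated(times, baseline=(-0.3, 0.0))
        assert list(kept) == [10.0, 20.0, 20.5]


class TestResponseWindows:
    def test_sustained_starts_one_second_after_transient(self):
        rw = ResponseWindows(transient=(0.05, 0.4))
        assert rw.sustained == pytest.approx((1.4, 1.7))
        rw.validate()

    def test_invalid_transient_rejected(self):
        with pytest.raises(AlignmentError):
            ResponseWindows(transient=(0.5, 0.2)).validate()
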