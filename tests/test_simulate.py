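"""Generator behaviour: locomotion, whisking, surface protocol, contact
truth and spiking statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal, stats

import whiskvr as w
from whiskvr.config import ConfigError
from whiskvr.session import EVENT_COLUMNS
from whiskvr.simulate import derive_contact_truth, simulate_spikes, transient_kernel


def events_frame(rows):
    return pd.DataFrame(rows, columns=EVENT_COLUMNS).sort_values("time").reset_index(drop=True)


class TestLocomotion:
    def test_running_mean_near_configured_speed(self):
        cfg = w.SessionConfig(duration=600.0, seed=1)
        speed = w.generate_locomotion(cfg)
        running = speed > 1.0
        assert abs(speed[running].mean() - 23.7) < 2.0

    def test_constant_speed_degenerate_case(self):
        cfg = w.SessionConfig(duration=30.0, seed=3, speed_noise_sd=0.0,
                              rest_bout_mean=0.0)
        speed = w.generate_locomotion(cfg)
        assert np.all(speed == 23.7)

    def test_seeded_determinism(self):
        cfg = w.SessionConfig(duration=60.0, seed=5)
        assert np.array_equal(w.generate_locomotion(cfg), w.generate_locomotion(cfg))

    def test_nonnegative_and_has_rests(self):
        cfg = w.SessionConfig(duration=300.0, seed=9)
        speed = w.generate_locomotion(cfg)
        assert np.all(speed >= 0)
        assert (speed == 0).any() and (speed > 0).any()

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            w.generate_locomotion(w.SessionConfig(duration=-1.0))
        with pytest.raises(ConfigError):
            w.generate_locomotion(w.SessionConfig(mean_run_speed=-5.0))


class TestWhisking:
    def test_spectral_peak_at_whisk_frequency(self):
        cfg = w.SessionConfig(duration=60.0, seed=1, whisk_rest_mean=0.0)
        res = w.generate_whisking(cfg, np.zeros(cfg.n_frames))
        ang = res.angles[:, 0]
        f, p = signal.welch(ang - ang.mean(), fs=cfg.frame_rate, nperseg=2 ** 14)
        band = (f >= 5) & (f <= 30)
        peak = f[band][np.argmax(p[band])]
        assert 18.0 <= peak <= 20.0

    def test_quiescent_bout_flat_at_setpoint(self):
        cfg = w.SessionConfig(duration=30.0, seed=2)
        res = w.generate_whisking(cfg, np.zeros(cfg.n_frames))
        quiet = ~res.whisking_mask
        assert quiet.any()
        for wi, wg in enumerate(cfg.whiskers):
            ang = res.angles[quiet, wi]
            assert ang.std() < 0.5
            assert abs(ang.mean() - wg.setpoint_deg) < 0.5

    def test_setpoint_tracks_surface_offset(self):
        cfg = w.SessionConfig(duration=40.0, seed=3, whisk_setpoint_tracking=10.0,
                              whisk_rest_mean=0.0)
        surface = np.zeros(cfg.n_frames)
        surface[cfg.n_frames // 2:] = 1.0   # rostral step of 1 cm
        res = w.generate_whisking(cfg, surface)
        # skip 2 s after the step for the low-pass setpoint to settle
        settle = cfg.n_frames // 2 + int(2 * cfg.frame_rate)
        before = res.angles[:cfg.n_frames // 2, 0].mean()
        after = res.angles[settle:, 0].mean()
        assert after - before == pytest.approx(10.0, abs=0.5)

    def test_nyquist_guard(self):
        with pytest.raises(ConfigError):
            w.generate_whisking(w.SessionConfig(frame_rate=30.0, whisk_freq=19.0),
                                np.zeros(10))


class TestSurface:
    def test_first_translation_time_from_constant_speed(self):
        cfg = w.SessionConfig(duration=30.0, seed=1, speed_noise_sd=0.0,
                              rest_bout_mean=0.0, mean_run_speed=20.0)
        speed = w.generate_locomotion(cfg)
        _, trials = w.simulate_surface(speed, cfg)
        # 200 cm at 20 cm/s -> 10 s
        assert trials["onset_time"].iloc[0] == pytest.approx(10.0, abs=0.01)

    def test_outcome_frequencies_near_equal_probability(self):
        cfg = w.SessionConfig(duration=35000.0, frame_rate=50.0, seed=1,
                              speed_noise_sd=0.0, rest_bout_mean=0.0,
                              mean_run_speed=30.0)
        speed = w.generate_locomotion(cfg)
        _, trials = w.simulate_surface(speed, cfg)
        draws = trials[~trials["is_return"]].iloc[:3000]
        assert len(draws) == 3000
        freqs = draws["outcome"].value_counts(normalize=True)
        for outcome in ("rostral", "caudal", "center"):
            assert freqs[outcome] == pytest.approx(1 / 3, abs=0.03)
        chi = stats.chisquare(draws["outcome"].value_counts().to_numpy())
        assert chi.pvalue > 0.01

    def test_zero_speed_yields_zero_trials(self):
        cfg = w.SessionConfig(duration=20.0)
        _, trials = w.simulate_surface(np.zeros(cfg.n_frames), cfg)
        assert len(trials) == 0

    def test_distance_conservation(self):
        cfg = w.SessionConfig(duration=400.0, seed=4)
        speed = w.generate_locomotion(cfg)
        _, trials = w.simulate_surface(speed, cfg)
        assert len(trials) > 2
        total = trials["distance_covered"].sum()
        integral = np.cumsum(speed)[int(trials["onset_time"].iloc[-1] * cfg.frame_rate)] \
            / cfg.frame_rate
        assert total == pytest.approx(integral, rel=1e-3)

    def test_rostral_caudal_then_return_protocol(self):
        cfg = w.SessionConfig(duration=300.0, seed=6)
        speed = w.generate_locomotion(cfg)
        _, trials = w.simulate_surface(speed, cfg)
        displaced = False
        for _, t in trials.iterrows():
            if displaced:
                assert t["is_return"] and t["outcome"] == "center"
                displaced = False
            else:
                assert not t["is_return"]
                displaced = t["outcome"] in ("rostral", "caudal", "out")


class TestContactTruth:
    def test_external_gow_at_reach_crossing(self):
        cfg = w.SessionConfig(duration=10.0)
        n = cfg.n_frames
        surface = np.zeros(n)
        f0 = n // 2
        ramp = np.linspace(0, 1.0, 125)
        surface[f0:f0 + 125] = ramp
        surface[f0 + 125:] = 1.0
        events, _ = derive_contact_truth(cfg, surface, np.ones(n, dtype=bool))
        ext = events[events["origin"] == "external"]
        assert list(ext["kind"]) == ["GoW"]
        assert ext["whisker_id"].iloc[0] == "R1"
        assert ext["direction"].iloc[0] == "rostral"
        # R1 reach starts at azimuth 4 deg = 0.4 cm into the 1 cm ramp
        t_cross = (f0 + 0.4 * 125) / cfg.frame_rate
        assert ext["time"].iloc[0] == pytest.approx(t_cross, abs=0.02)

    def test_movement_within_contacted_span_yields_no_events(self):
        cfg = w.SessionConfig(duration=10.0)
        n = cfg.n_frames
        surface = np.full(n, 0.8)       # R1 already in reach
        surface[n // 2:] += np.minimum(
            np.arange(n - n // 2) / 125, 1.0) * 0.3   # move within reach span
        events, _ = derive_contact_truth(cfg, surface, np.ones(n, dtype=bool))
        assert len(events[events["origin"] == "external"]) == 0

    def test_self_gow_on_whisking_resumption(self):
        cfg = w.SessionConfig(duration=10.0)
        n = cfg.n_frames
        surface = np.full(n, 0.8)       # stationary, in R1 reach
        whisking = np.ones(n, dtype=bool)
        whisking[n // 3: n // 2] = False
        events, _ = derive_contact_truth(cfg, surface, whisking)
        selfs = events[events["origin"] == "self"]
        assert len(selfs) == 1
        assert selfs["kind"].iloc[0] == "GoW"
        assert selfs["time"].iloc[0] == pytest.approx((n // 2) / cfg.frame_rate, abs=1e-6)

    def test_repetition_indices_increment_per_stream(self, medium_session):
        ev = medium_session.ground_truth.contact_events
        for _, grp in ev.groupby(["kind", "origin", "direction"]):
            reps = grp.sort_values("time")["repetition_index"].to_numpy()
            assert np.array_equal(reps, np.arange(1, len(reps) + 1))


class TestSpikes:
    def test_homogeneous_poisson_count(self):
        cfg = w.SessionConfig(duration=100.0, seed=1)
        spec = w.NeuronSpec(neuron_id=0, baseline_rate=10.0)
        empty = events_frame([])
        spikes, _ = simulate_spikes(empty, np.zeros((cfg.n_frames, 2), bool), [spec], cfg)
        n = len(spikes[0])
        assert abs(n - 1000) < 3 * np.sqrt(1000)

    def test_fano_factor_near_one(self):
        # variance/mean of window counts across repeated draws at baseline only
        cfg = w.SessionConfig(duration=20.0, seed=1)
        empty = events_frame([])
        contact = np.zeros((cfg.n_frames, 2), bool)
        counts = []
        for s in range(500):
            spec = w.NeuronSpec(neuron_id=s, baseline_rate=8.0)
            spikes, _ = simulate_spikes(empty, contact, [spec], cfg, seed=s)
            st = spikes[s]
            counts.append(np.sum((st >= 5.0) & (st < 6.0)))
        counts = np.asarray(counts, dtype=float)
        fano = counts.var(ddof=1) / counts.mean()
        assert 0.8 <= fano <= 1.2

    def test_self_attenuation_recovered_from_rate_ratio(self):
        cfg = w.SessionConfig(duration=500.0, seed=3)
        t_ext = 2.0 + 4.0 * np.arange(120)
        t_self = 4.0 + 4.0 * np.arange(120)
        rows = [(t, "R1", "GoW", "external", "rostral", i + 1) for i, t in enumerate(t_ext)]
        rows += [(t, "R1", "GoW", "self", "none", i + 1) for i, t in enumerate(t_self)]
        spec = w.NeuronSpec(neuron_id=0, baseline_rate=10.0, transient_gain=60.0,
                            self_attenuation=0.5)
        spikes, _ = simulate_spikes(events_frame(rows),
                                    np.zeros((cfg.n_frames, 2), bool), [spec], cfg)
        st = spikes[0]
        deltas = {}
        for name, times in (("ext", t_ext), ("self", t_self)):
            post = w.window_rates(st, times, (0.01, 0.11)).mean()
            pre = w.window_rates(st, times, (-0.3, 0.0)).mean()
            deltas[name] = post - pre
        assert deltas["self"] / deltas["ext"] == pytest.approx(0.5, abs=0.1)

    def test_habituation_slope_recovered(self):
        cfg = w.SessionConfig(duration=400.0, seed=4)
        times = 5.0 + 12.0 * np.arange(30)
        rows = [(t, "R1", "GoW", "external", "rostral", i + 1) for i, t in enumerate(times)]
        gain = 60.0
        spec = w.NeuronSpec(neuron_id=0, baseline_rate=10.0, transient_gain=gain,
                            habituation_slope=-0.02)
        spikes, _ = simulate_spikes(events_frame(rows),
                                    np.zeros((cfg.n_frames, 2), bool), [spec], cfg)
        window = (0.0, 0.3)
        rates = w.window_rates(spikes[0], times, window)
        fit = w.repetition_regression(rates)
        # oracle: expected windowed-rate slope = fractional slope x gain x
        # (kernel mass in window) / (window width)
        tt = np.linspace(window[0], window[1], 3001)
        mass = np.trapezoid(transient_kernel(tt, spec.onset_latency, spec.tau_rise,
                                             spec.tau_decay), tt)
        expected = -0.02 * gain * mass / (window[1] - window[0])
        assert fit.slope == pytest.approx(expected, abs=2 * fit.stderr)
        assert fit.slope < 0

    def test_negative_rate_config_rejected(self):
        cfg = w.SessionConfig(duration=1.0)
        spec = w.NeuronSpec(neuron_id=0, baseline_rate=-1.0)
        with pytest.raises(ConfigError):
            simulate_spikes(events_frame([]), np.zeros((cfg.n_frames, 2), bool),
                            [spec], cfg)

    def test_refractory_period_enforced(self):
        cfg = w.SessionConfig(duration=50.0, seed=6)
        spec = w.NeuronSpec(neuron_id=0, baseline_rate=80.0)
        spikes, _ = simulate_spikes(events_frame([]),
                                    np.zeros((cfg.n_frames, 2), bool), [spec], cfg)
        assert np.all(np.diff(spikes[0]) >= 0.002 - 1e-12)
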