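"""Synthetic closed-loop whisker-VR session generator.

Emulates the behavioural and neural statistics the analysis pipeline
assumes: volitional run/rest locomotion, rhythmic whisking with quiescent
bouts and surface tracking, distance-triggered surface translations with
randomized outcomes, gain/loss-of-whisker-contact (GoW/LoW) events of
external or self-generated origin, and inhomogeneous-Poisson spike trains
with transient kernels, sustained touch drive, self-generation attenuation
and linear habituation across external stimulus repetitions.

Every stochastic component draws from a named substream of the master seed
(see :func:`whiskvr.config.substream`), so the locomotion trace, for
example, is unchanged when the neuron count changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError, NeuronSpec, SessionConfig, substream
from .session import (ContactEvent, GroundTruth, Session, Trial,
                      events_to_frame, trials_to_frame)

__all__ = [
    "generate_locomotion",
    "generate_whisking",
    "simulate_surface",
    "derive_contact_truth",
    "simulate_spikes",
    "render_tracks",
    "simulate_session",
    "make_population",
    "transient_kernel",
    "WhiskingResult",
]

#: absolute refractory period of the thinning sampler, seconds
REFRACTORY = 0.002
#: axial surface position (cm) used for the optional "out of field" outcome
OUT_POSITION_CM = 3.0


# ---------------------------------------------------------------------------
# behaviour

def _bout_mask(rng: np.random.Generator, n_frames: int, frame_rate: float,
               on_mean: float, off_mean: float,
               min_on: float = 1.0, min_off: float = 0.3) -> np.ndarray:
    """Alternating on/off boolean mask from exponential bout lengths."""
    if off_mean <= 0:
        return np.ones(n_frames, dtype=bool)
    mask = np.zeros(n_frames, dtype=bool)
    i = 0
    on = True
    while i < n_frames:
        mean = on_mean if on else off_mean
        floor = min_on if on else min_off
        length = max(floor, rng.exponential(mean))
        j = min(n_frames, i + int(round(length * frame_rate)))
        if on:
            mask[i:j] = True
        i = j
        on = not on
    return mask


def generate_locomotion(cfg: SessionConfig, seed: int | None = None) -> np.ndarray:
    """Per-frame treadmill speed (cm/s) with alternating run/rest bouts.

    During run bouts the speed fluctuates slowly (AR(1), 2 s correlation
    time, stationary s.d. ``speed_noise_sd``) around ``mean_run_speed`` and
    is clipped at zero; rest bouts are zero speed.
    """
    cfg.validate()
    rng = substream(cfg.seed if seed is None else seed, "locomotion")
    n = cfg.n_frames
    run = _bout_mask(rng, n, cfg.frame_rate, cfg.run_bout_mean, cfg.rest_bout_mean,
                     min_on=2.0, min_off=0.5)
    speed = np.zeros(n)
    if cfg.speed_noise_sd > 0:
        tau = 2.0
        a = np.exp(-1.0 / (tau * cfg.frame_rate))
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, cfg.speed_noise_sd)
        innov = rng.normal(0.0, cfg.speed_noise_sd * np.sqrt(1 - a * a), n)
        for i in range(1, n):
            noise[i] = a * noise[i - 1] + innov[i]
    else:
        noise = np.zeros(n)
    speed[run] = np.clip(cfg.mean_run_speed + noise[run], 0.0, None)
    return speed


@dataclass
class WhiskingResult:
    angles: np.ndarray        # (n_frames, n_whiskers), degrees
    whisking_mask: np.ndarray  # (n_frames,) bool
    drive: np.ndarray         # shared oscillation component, degrees
    setpoint_offset: np.ndarray  # tracking offset shared by all whiskers


def _whisk_phase_trace(rng: np.random.Generator, duration: float,
                       frame_rate: float, freq: float, jitter: float) -> np.ndarray:
    """Unwrapped phase of a sinusoid with per-cycle multiplicative frequency jitter."""
    n_cycles = int(np.ceil(duration * freq * 2)) + 4
    f_cyc = freq * np.clip(1.0 + jitter * rng.standard_normal(n_cycles), 0.2, 5.0)
    durations = 1.0 / f_cyc
    starts = np.concatenate([[0.0], np.cumsum(durations)])
    t = np.arange(int(round(duration * frame_rate))) / frame_rate
    cyc = np.searchsorted(starts, t, side="right") - 1
    frac = (t - starts[cyc]) / durations[cyc]
    return 2 * np.pi * (cyc + frac)


def generate_whisking(cfg: SessionConfig, surface: np.ndarray,
                      seed: int | None = None) -> WhiskingResult:
    """Per-whisker angle traces with whisk/quiescent bouts and surface tracking.

    During whisking bouts each whisker oscillates at ``whisk_freq`` (with
    per-cycle jitter) around a setpoint that shifts with the surface
    position by ``whisk_setpoint_tracking`` degrees per cm (low-pass, 200 ms);
    during quiescent bouts the angle sits at the setpoint.
    """
    cfg.validate()
    rng = substream(cfg.seed if seed is None else seed, "whisking")
    n = cfg.n_frames
    if len(surface) != n:
        raise ConfigError("surface trace length does not match the configuration")
    whisking = _bout_mask(rng, n, cfg.frame_rate, cfg.whisk_bout_mean,
                          cfg.whisk_rest_mean, min_on=1.0, min_off=0.3)
    phase = _whisk_phase_trace(rng, cfg.duration, cfg.frame_rate,
                               cfg.whisk_freq, cfg.whisk_freq_jitter)[:n]
    drive = np.where(whisking, cfg.whisk_amplitude * np.cos(phase), 0.0)
    # low-pass surface tracking of the whisking setpoint
    alpha = 1.0 - np.exp(-1.0 / (0.2 * cfg.frame_rate))
    tracked = np.empty(n)
    acc = surface[0]
    for i in range(n):
        acc += alpha * (surface[i] - acc)
        tracked[i] = acc
    offset = cfg.base_setpoint + cfg.whisk_setpoint_tracking * tracked
    setpoints = np.array([w.setpoint_deg for w in cfg.whiskers])
    angles = setpoints[None, :] + (offset + drive)[:, None]
    return WhiskingResult(angles=angles, whisking_mask=whisking,
                          drive=drive, setpoint_offset=offset)


# ---------------------------------------------------------------------------
# surface protocol

def simulate_surface(speed: np.ndarray, cfg: SessionConfig,
                     seed: int | None = None) -> tuple[np.ndarray, pd.DataFrame]:
    """Distance-triggered surface translations with randomized outcomes.

    A trigger fires each time cumulative locomotor distance since the last
    trigger crosses ``trial_distance``.  At the center position the outcome
    is drawn from ``outcome_probs`` (rostral/caudal move ``translation_distance``
    cm; center stays; the optional ``out`` outcome moves the surface outside
    the whisker field); at a displaced position the trigger produces the
    return movement to center.  Movements are linear ramps of
    ``translation_duration`` seconds.
    """
    cfg.validate()
    if np.any(~np.isfinite(speed)) or np.any(speed < 0):
        raise ConfigError("speed trace must be finite and nonnegative")
    rng = substream(cfg.seed if seed is None else seed, "outcomes")
    n = len(speed)
    dt = 1.0 / cfg.frame_rate
    cumdist = np.cumsum(speed) * dt
    surface = np.zeros(n)
    trials: list[Trial] = []
    labels = list(cfg.outcome_probs)
    probs = np.array([cfg.outcome_probs[k] for k in labels])
    targets = {"rostral": cfg.translation_distance,
               "caudal": -cfg.translation_distance,
               "center": 0.0,
               "out": OUT_POSITION_CM}
    ramp_frames = max(1, int(round(cfg.translation_duration * cfg.frame_rate)))

    pos = 0.0
    at_center = True
    last_dist = 0.0
    frame = 0
    while True:
        nxt = int(np.searchsorted(cumdist, last_dist + cfg.trial_distance))
        if nxt >= n:
            surface[frame:] = pos
            break
        surface[frame:nxt] = pos
        covered = cumdist[nxt] - last_dist
        if at_center:
            outcome = labels[rng.choice(len(labels), p=probs)]
            new_pos = targets[outcome]
            is_return = False
            at_center = outcome == "center"
        else:
            outcome = "center"
            new_pos = 0.0
            is_return = True
            at_center = True
        trials.append(Trial(onset_time=nxt / cfg.frame_rate, outcome=outcome,
                            is_return=is_return, distance_covered=covered))
        end = min(n, nxt + ramp_frames)
        surface[nxt:end] = pos + (new_pos - pos) * np.arange(1, end - nxt + 1) / ramp_frames
        pos = new_pos
        last_dist = cumdist[nxt]
        frame = end
    return surface, trials_to_frame(trials)


# ---------------------------------------------------------------------------
# contact ground truth

def derive_contact_truth(cfg: SessionConfig, surface: np.ndarray,
                         whisking_mask: np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
    """Ground-truth GoW/LoW contact events and the per-whisker contact mask.

    A whisker is *in reach* when the surface azimuth falls inside the
    angular interval ``setpoint ± reach`` of its resting geometry; contact
    requires the animal to be whisking.  Surface motion that adds/removes a
    whisker from reach while whisking emits an external GoW/LoW event at
    the crossing frame; resumption of whisking against a stationary
    in-reach surface emits a self GoW per in-reach whisker.  Repetition
    indices count from 1 within each (kind, origin, direction) stream.
    """
    n = len(surface)
    azimuth = surface * cfg.deg_per_cm
    setpoints = np.array([w.setpoint_deg for w in cfg.whiskers])
    reach = np.array([w.reach_deg for w in cfg.whiskers])
    in_reach = np.abs(azimuth[:, None] - setpoints[None, :]) <= reach[None, :]
    moving = np.zeros(n, dtype=bool)
    moving[1:] = np.diff(surface) != 0
    contact = in_reach & whisking_mask[:, None]

    raw: list[tuple[float, str, str, str, str]] = []
    dr = np.zeros(n)
    dr[1:] = np.diff(surface)
    for wi, w in enumerate(cfg.whiskers):
        gain = np.flatnonzero(in_reach[1:, wi] & ~in_reach[:-1, wi]) + 1
        loss = np.flatnonzero(~in_reach[1:, wi] & in_reach[:-1, wi]) + 1
        for f in gain:
            if moving[f] and whisking_mask[f]:
                direction = "rostral" if dr[f] > 0 else "caudal"
                raw.append((f / cfg.frame_rate, w.whisker_id, "GoW", "external", direction))
        for f in loss:
            if moving[f] and whisking_mask[f]:
                direction = "rostral" if dr[f] > 0 else "caudal"
                raw.append((f / cfg.frame_rate, w.whisker_id, "LoW", "external", direction))
    # self-generated gains: whisking resumes against a stationary in-reach surface
    resume = np.flatnonzero(whisking_mask[1:] & ~whisking_mask[:-1]) + 1
    for f in resume:
        if moving[f]:
            continue
        for wi, w in enumerate(cfg.whiskers):
            if in_reach[f, wi]:
                raw.append((f / cfg.frame_rate, w.whisker_id, "GoW", "self", "none"))

    raw.sort(key=lambda r: r[0])
    counters: dict[tuple[str, str, str], int] = {}
    events = []
    for t, wid, kind, origin, direction in raw:
        key = (kind, origin, direction)
        counters[key] = counters.get(key, 0) + 1
        events.append(ContactEvent(time=t, whisker_id=wid, kind=kind, origin=origin,
                                   direction=direction, repetition_index=counters[key]))
    return events_to_frame(events), contact


# ---------------------------------------------------------------------------
# spiking

def transient_kernel(t: np.ndarray, latency: float, tau_rise: float,
                     tau_decay: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials response kernel.

    ``k(t) = (1 - exp(-(t-lat)/tau_rise)) * exp(-(t-lat)/tau_decay)`` for
    ``t > latency``, normalized so its maximum is 1.
    """
    tt = np.asarray(t, dtype=float) - latency
    out = np.zeros_like(tt)
    pos = tt > 0
    out[pos] = (1.0 - np.exp(-tt[pos] / tau_rise)) * np.exp(-tt[pos] / tau_decay)
    t_peak = tau_rise * np.log1p(tau_decay / tau_rise)
    peak = (1.0 - np.exp(-t_peak / tau_rise)) * np.exp(-t_peak / tau_decay)
    return out / peak


def _kernel_support(spec: NeuronSpec) -> float:
    return spec.onset_latency + spec.tau_rise + 8.0 * spec.tau_decay


def _event_amplitudes(spec: NeuronSpec, events: pd.DataFrame) -> np.ndarray:
    """Signed kernel peak amplitude (spikes/s) contributed by each event."""
    amp = np.zeros(len(events))
    if len(events) == 0 or spec.transient_gain == 0:
        return amp
    kinds = events["kind"].to_numpy()
    origins = events["origin"].to_numpy()
    reps = events["repetition_index"].to_numpy()
    whiskers = events["whisker_id"].to_numpy()
    for i in range(len(events)):
        if spec.preferred_whiskers and whiskers[i] not in spec.preferred_whiskers:
            continue
        if kinds[i] == "GoW":
            sign = spec.gow_sign
        elif kinds[i] == "LoW":
            sign = spec.low_sign
        else:
            continue
        origin_factor = 1.0 if origins[i] == "external" else spec.self_attenuation
        hab = 1.0
        if kinds[i] == "GoW" and origins[i] == "external":
            hab = max(0.0, 1.0 + spec.habituation_slope * (reps[i] - 1))
        amp[i] = spec.transient_gain * sign * origin_factor * hab
    return amp


def _sample_thinning(rng: np.random.Generator, duration: float, lam_max: float,
                     rate_at: callable) -> np.ndarray:
    """Inhomogeneous Poisson times by thinning, with absolute refractory period."""
    if lam_max <= 0:
        return np.empty(0)
    n_cand = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, n_cand))
    keep = rng.uniform(0.0, lam_max, n_cand) < rate_at(cand)
    times = cand[keep]
    if len(times) == 0:
        return times
    out = [times[0]]
    last = times[0]
    for t in times[1:]:
        if t - last >= REFRACTORY:
            out.append(t)
            last = t
    return np.asarray(out)


def simulate_spikes(events: pd.DataFrame, contact: np.ndarray,
                    specs: list[NeuronSpec], cfg: SessionConfig,
                    seed: int | None = None,
                    ) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray]]:
    """Spike trains (and per-spike waveform amplitudes) for a population.

    Each neuron's rate is its baseline plus transient-kernel contributions
    from GoW/LoW events (scaled by polarity, self-attenuation and
    habituation; see :class:`whiskvr.config.NeuronSpec`) plus
    ``sustained_gain`` while a preferred whisker is touching.  The
    sustained drive rises exponentially (``tau_sustained``) after contact
    onset, emulating activity that builds over successive active touches
    rather than stepping instantaneously.  Spikes are drawn by thinning an
    inhomogeneous Poisson process with a 2 ms absolute refractory period.
    """
    for s in specs:
        s.validate()
    whisker_ids = [w.whisker_id for w in cfg.whiskers]
    duration = contact.shape[0] / cfg.frame_rate
    ev_times = events["time"].to_numpy() if len(events) else np.empty(0)
    master = cfg.seed if seed is None else seed

    spikes: dict[int, np.ndarray] = {}
    amplitudes: dict[int, np.ndarray] = {}
    for spec in specs:
        rng = np.random.default_rng(np.random.SeedSequence([int(master), 4, int(spec.neuron_id)]))
        amps = _event_amplitudes(spec, events)
        if spec.preferred_whiskers:
            cols = [whisker_ids.index(w) for w in spec.preferred_whiskers if w in whisker_ids]
            touching = contact[:, cols].any(axis=1) if cols else np.zeros(contact.shape[0], bool)
        else:
            touching = contact.any(axis=1)
        if spec.sustained_gain > 0 and spec.tau_sustained > 0:
            from scipy.signal import lfilter
            alpha = 1.0 - np.exp(-1.0 / (spec.tau_sustained * cfg.frame_rate))
            touching = lfilter([alpha], [1.0, -(1.0 - alpha)],
                               touching.astype(float))
        else:
            touching = touching.astype(float)
        support = _kernel_support(spec)
        # upper rate bound: baseline + sustained + the largest sum of |kernel
        # peaks| over any window of overlapping events
        overlap = 0.0
        if len(ev_times):
            abs_amps = np.abs(amps)
            for i in range(len(ev_times)):
                hi = np.searchsorted(ev_times, ev_times[i] + support)
                overlap = max(overlap, abs_amps[i:hi].sum())
        lam_max = spec.baseline_rate + spec.sustained_gain + overlap

        def rate_at(t: np.ndarray, spec=spec, amps=amps, touching=touching,
                    support=support) -> np.ndarray:
            frames = np.clip((t * cfg.frame_rate).astype(int), 0, len(touching) - 1)
            rate = np.full(len(t), float(spec.baseline_rate))
            rate += spec.sustained_gain * touching[frames]
            for a, te in zip(amps, ev_times):
                if a == 0.0:
                    continue
                lo = np.searchsorted(t, te + spec.onset_latency)
                hi = np.searchsorted(t, te + support)
                if hi > lo:
                    rate[lo:hi] += a * transient_kernel(
                        t[lo:hi] - te, spec.onset_latency, spec.tau_rise, spec.tau_decay)
            return np.clip(rate, 0.0, None)

        st = _sample_thinning(rng, duration, lam_max, rate_at)
        spikes[spec.neuron_id] = st
        amplitudes[spec.neuron_id] = (1.0 + spec.amplitude_drift * st
                                      + spec.amplitude_noise * rng.standard_normal(len(st)))
    return spikes, amplitudes


# ---------------------------------------------------------------------------
# track rendering

def render_tracks(cfg: SessionConfig, angles: np.ndarray, contact: np.ndarray,
                  seed: int | None = None) -> pd.DataFrame:
    """Render per-whisker angles as four labelled points in image coordinates.

    Points lie along a ray from the face reference point at the whisker
    angle (0 deg = vertically above the face point, positive rostral = +x).
    While the whisker is in contact the shaft is rendered as a circular arc
    of curvature ``contact_bend`` (1/px, 10 ms smoothed rise), so the
    Menger curvature of the labels recovers the configured bend exactly;
    Gaussian label jitter is added on top.
    """
    rng = substream(cfg.seed if seed is None else seed, "tracks")
    n_frames, n_whiskers = angles.shape
    radii = np.asarray(cfg.label_radii_px)
    xf, yf = cfg.face_point
    # smooth the contact mask so the rendered bend has a finite rise
    ramp = np.ones(max(1, int(round(0.01 * cfg.frame_rate))))
    ramp /= len(ramp)
    frames = np.repeat(np.arange(n_frames), len(radii))
    recs = []
    for wi, w in enumerate(cfg.whiskers):
        theta = np.deg2rad(angles[:, wi])
        bend = np.convolve(contact[:, wi].astype(float), ramp, mode="same") * cfg.contact_bend
        ux, uy = np.sin(theta), -np.cos(theta)      # along-ray unit vector
        px_, py_ = np.cos(theta), np.sin(theta)     # perpendicular (caudal-bend) vector
        c = bend[:, None]
        s = radii[None, :] * np.ones((n_frames, 1))
        with np.errstate(invalid="ignore", divide="ignore"):
            along = np.where(c > 0, np.sin(c * s) / np.where(c > 0, c, 1.0), s)
            perp = np.where(c > 0, (1.0 - np.cos(c * s)) / np.where(c > 0, c, 1.0), 0.0)
        x = xf + along * ux[:, None] - perp * px_[:, None]
        y = yf + along * uy[:, None] - perp * py_[:, None]
        x += rng.normal(0.0, cfg.label_noise_px, x.shape)
        y += rng.normal(0.0, cfg.label_noise_px, y.shape)
        recs.append(pd.DataFrame({
            "frame": frames,
            "whisker_id": w.whisker_id,
            "label_index": np.tile(np.arange(len(radii)), n_frames),
            "x_px": x.ravel(),
            "y_px": y.ravel(),
        }))
    return pd.concat(recs, ignore_index=True)


# ---------------------------------------------------------------------------
# population + full session

def make_population(n_neurons: int, seed: int = 0, *,
                    responsive_fraction: float = 0.67,
                    transient_share: float = 0.5,
                    baseline_rate: float = 10.0,
                    transient_gain: float = 100.0,
                    sustained_gain: float = 15.0,
                    self_attenuation: float = 0.3,
                    habituation_slope: float = 0.0,
                    gow_preferring_fraction: float = 1.0,
                    somatotopic: bool = True,
                    whisker_ids: tuple[str, ...] = ("R1", "C1")) -> list[NeuronSpec]:
    """Construct a neuron population with the configured class mixture.

    ``responsive_fraction`` of the neurons receive strong gains, split
    ``transient_share`` : (1 - ``transient_share``) between transient and
    sustained classes; the rest are baseline-only.  Within the responsive
    neurons, ``gow_preferring_fraction`` respond positively to gains and
    negatively to losses of contact (the converse for the remainder).
    When ``somatotopic``, responsive neurons are assigned single preferred
    whiskers in rotation, so movements that engage different whiskers
    activate different neurons — the substrate for direction decoding.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    n_resp = int(round(n_neurons * responsive_fraction))
    n_trans = int(round(n_resp * transient_share))
    n_gow = int(round(n_resp * gow_preferring_fraction))
    specs = []
    for i in range(n_neurons):
        base = float(np.clip(rng.normal(baseline_rate, baseline_rate * 0.15), 2.0, None))
        if i < n_resp:
            label = "transient" if i < n_trans else "sustained"
            prefers_gow = i % n_resp < n_gow if n_resp else True
            preferred = (whisker_ids[i % len(whisker_ids)],) if somatotopic else ()
            specs.append(NeuronSpec(
                neuron_id=i, class_label=label, baseline_rate=base,
                transient_gain=transient_gain if label == "transient" else 0.0,
                sustained_gain=sustained_gain if label == "sustained" else 0.0,
                self_attenuation=self_attenuation,
                habituation_slope=habituation_slope if label == "transient" else 0.0,
                gow_sign=1 if prefers_gow else -1,
                low_sign=-1 if prefers_gow else 1,
                preferred_whiskers=preferred,
            ))
        else:
            specs.append(NeuronSpec(neuron_id=i, class_label="nonresponsive",
                                    baseline_rate=base))
    return specs


def simulate_session(cfg: SessionConfig, specs: list[NeuronSpec] | None = None,
                     *, render: bool = True) -> Session:
    """Generate a complete synthetic session with ground truth.

    ``render=False`` skips the whisker point-track rendering (the largest
    artifact), which analyses that start from spike trains do not need.
    """
    cfg.validate()
    if specs is None:
        specs = make_population(50, seed=cfg.seed)
    speed = generate_locomotion(cfg)
    surface, trials = simulate_surface(speed, cfg)
    whisking = generate_whisking(cfg, surface)
    events, contact = derive_contact_truth(cfg, surface, whisking.whisking_mask)
    spikes, amps = simulate_spikes(events, contact, specs, cfg)
    tracks = (render_tracks(cfg, whisking.angles, contact)
              if render else pd.DataFrame(columns=["frame", "whisker_id", "label_index",
                                                   "x_px", "y_px"]))
    truth = GroundTruth(contact_events=events, neuron_params=specs,
                        contact_mask=contact, whisking_mask=whisking.whisking_mask)
    return Session(config=cfg, speed=speed, surface=surface, whisker_tracks=tracks,
                   spike_trains=spikes, spike_amplitudes=amps,
                   trial_table=trials, ground_truth=truth)
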