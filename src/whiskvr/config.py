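"""Configuration types for synthetic whisker-VR sessions.

A session emulates a head-fixed mouse running on a treadmill while whisking
against a rotating surface whose axial position is yoked to locomotion.
After every ``trial_distance`` centimetres of running the surface translates
``translation_distance`` cm into rostral or caudal whisker space, or stays
put, with configurable outcome probabilities; displaced positions return to
center after another ``trial_distance`` cm.  Neurons are described by
:class:`NeuronSpec` and driven by an inhomogeneous Poisson rate model built
from the session's contact events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ConfigError",
    "SessionConfig",
    "WhiskerGeometry",
    "NeuronSpec",
    "substream",
]


class ConfigError(ValueError):
    """Raised when a configuration value is invalid."""


#: Named random substreams derived from the master seed.  Each component
#: draws from its own stream so changing the number of draws in one
#: component does not perturb the others.
_STREAMS = {
    "locomotion": 1,
    "whisking": 2,
    "outcomes": 3,
    "spikes": 4,
    "tracks": 5,
    "amplitudes": 6,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the named random substream for a master seed."""
    if name not in _STREAMS:
        raise KeyError(f"unknown random substream {name!r}")
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[name]]))


@dataclass
class WhiskerGeometry:
    """Angular placement of one whisker relative to the face.

    ``setpoint_deg`` is the resting angle (0 = vertical above the face
    point, positive rostral); the whisker can reach the surface whenever the
    surface azimuth falls within ``setpoint_deg ± reach_deg`` and the animal
    is whisking.
    """

    whisker_id: str
    setpoint_deg: float
    reach_deg: float = 4.0


@dataclass
class SessionConfig:
    duration: float = 600.0          # s
    frame_rate: float = 500.0        # frames/s
    # locomotion
    mean_run_speed: float = 23.7     # cm/s, running-epoch mean
    speed_noise_sd: float = 1.6      # cm/s, slow within-bout fluctuation
    run_bout_mean: float = 30.0      # s, mean run-bout length
    rest_bout_mean: float = 3.0      # s, mean rest length; 0 disables rests
    # whisking
    whisk_freq: float = 19.0         # Hz
    whisk_amplitude: float = 15.0    # deg, half peak-to-peak
    whisk_freq_jitter: float = 0.05  # multiplicative per-cycle s.d.
    whisk_bout_mean: float = 12.0    # s
    whisk_rest_mean: float = 1.5     # s, quiescent-bout mean; 0 disables
    whisk_setpoint_tracking: float = 5.0  # deg of setpoint shift per cm of surface offset
    base_setpoint: float = 0.0       # deg, whisking midpoint at center surface
    # trial structure
    trial_distance: float = 200.0    # cm of locomotion per trigger
    translation_distance: float = 1.0  # cm
    translation_duration: float = 0.25  # s, linear ramp of the 1 cm move
    outcome_probs: dict[str, float] = field(
        default_factory=lambda: {"rostral": 1 / 3, "caudal": 1 / 3, "center": 1 / 3}
    )
    # geometry / rendering
    deg_per_cm: float = 10.0         # surface azimuth change per cm of axial position
    whiskers: list[WhiskerGeometry] = field(
        default_factory=lambda: [
            WhiskerGeometry("R1", setpoint_deg=8.0),
            WhiskerGeometry("C1", setpoint_deg=-8.0),
        ]
    )
    face_point: tuple[float, float] = (200.0, 300.0)  # px, image coordinates
    label_radii_px: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0)
    label_noise_px: float = 0.3
    contact_bend: float = 0.02       # 1/px peak curvature rendered under contact
    px_per_mm: float = 20.0          # 1 px = 0.05 mm
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be positive")
        if self.mean_run_speed < 0 or self.speed_noise_sd < 0:
            raise ConfigError("speeds must be nonnegative")
        if self.trial_distance <= 0 or self.translation_distance <= 0:
            raise ConfigError("distances must be positive")
        if self.translation_duration <= 0:
            raise ConfigError("translation_duration must be positive")
        if self.whisk_freq >= self.frame_rate / 2:
            raise ConfigError("whisk_freq must be below the Nyquist frequency")
        total = sum(self.outcome_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"outcome_probs must sum to 1, got {total}")
        if any(p < 0 for p in self.outcome_probs.values()):
            raise ConfigError("outcome_probs must be nonnegative")
        if not self.whiskers:
            raise ConfigError("at least one whisker is required")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["whiskers"] = [asdict(w) for w in self.whiskers]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        d["whiskers"] = [WhiskerGeometry(**w) for w in d.get("whiskers", [])]
        if "face_point" in d:
            d["face_point"] = tuple(d["face_point"])
        if "label_radii_px" in d:
            d["label_radii_px"] = tuple(d["label_radii_px"])
        return cls(**d)


@dataclass
class NeuronSpec:
    """Generative parameters of one simulated neuron.

    The firing rate is

    ``rate(t) = baseline_rate
               + sum_events kernel(t - t_ev) * transient_gain * sign(kind)
                 * origin_factor * max(0, 1 + habituation_slope * (rep - 1))
               + sustained_gain * touching(t)``

    where ``origin_factor`` is 1 for externally generated events and
    ``self_attenuation`` for self-generated ones, ``sign(kind)`` is
    ``gow_sign`` for gains and ``low_sign`` for losses of contact, and
    ``rep`` is the event's repetition index within its stimulus stream.
    Spikes are drawn by thinning with an absolute refractory period.
    """

    neuron_id: int
    class_label: str = "nonresponsive"   # {transient, sustained, both, nonresponsive}
    baseline_rate: float = 10.0          # spikes/s
    transient_gain: float = 0.0          # peak added rate on external GoW, spikes/s
    onset_latency: float = 0.010         # s
    tau_rise: float = 0.010              # s
    tau_decay: float = 0.050             # s
    self_attenuation: float = 0.3        # scales transient gain for self events
    sustained_gain: float = 0.0          # added rate while touching, spikes/s
    tau_sustained: float = 0.5           # s, rise time of the sustained drive
    habituation_slope: float = 0.0       # fractional change per repetition, <= 0
    gow_sign: int = 1
    low_sign: int = 1
    preferred_whiskers: tuple[str, ...] = ()   # empty = all whiskers
    amplitude_drift: float = 0.0         # waveform-amplitude drift per second
    amplitude_noise: float = 0.02

    def validate(self) -> None:
        if self.baseline_rate < 0:
            raise ConfigError(f"neuron {self.neuron_id}: baseline_rate must be >= 0")
        if not 0.0 <= self.self_attenuation <= 1.0:
            raise ConfigError(f"neuron {self.neuron_id}: self_attenuation must be in [0, 1]")
        if self.transient_gain < 0 or self.sustained_gain < 0:
            raise ConfigError(f"neuron {self.neuron_id}: gains must be >= 0 (use signs for polarity)")
        if self.habituation_slope > 0:
            raise ConfigError(f"neuron {self.neuron_id}: habituation_slope must be <= 0")
        if self.gow_sign not in (-1, 1) or self.low_sign not in (-1, 1):
            raise ConfigError(f"neuron {self.neuron_id}: signs must be +1 or -1")
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ConfigError(f"neuron {self.neuron_id}: time constants must be positive")
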