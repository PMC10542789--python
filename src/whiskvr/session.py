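"""In-memory session model.

All traces share one frame clock (``frame_rate`` frames/s); event times are
stored in seconds as ``frame_index / frame_rate`` and intervals are half
open ``[t0, t1)``.

Tabular data are plain pandas DataFrames with fixed column sets:

``trial_table``
    onset_time (s), outcome {rostral, caudal, center, out}, is_return,
    distance_covered (cm), gow, low  (the last two filled by the
    alignment stage or by ground truth).
``events``
    time (s), whisker_id, kind {GoW, LoW, touch}, origin {external, self},
    direction {rostral, caudal, none}, repetition_index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import NeuronSpec, SessionConfig

__all__ = ["ContactEvent", "Trial", "GroundTruth", "Session",
           "events_to_frame", "trials_to_frame"]

TRIAL_COLUMNS = ["onset_time", "outcome", "is_return", "distance_covered"]
EVENT_COLUMNS = ["time", "whisker_id", "kind", "origin", "direction", "repetition_index"]


@dataclass(frozen=True)
class ContactEvent:
    time: float
    whisker_id: str
    kind: str            # GoW | LoW | touch
    origin: str          # external | self
    direction: str       # rostral | caudal | none
    repetition_index: int = 0


@dataclass(frozen=True)
class Trial:
    onset_time: float
    outcome: str         # rostral | caudal | center | out
    is_return: bool
    distance_covered: float


def events_to_frame(events: list[ContactEvent]) -> pd.DataFrame:
    if not events:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    df = pd.DataFrame([e.__dict__ for e in events])
    return df[EVENT_COLUMNS].sort_values("time", kind="stable").reset_index(drop=True)


def trials_to_frame(trials: list[Trial]) -> pd.DataFrame:
    if not trials:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    return pd.DataFrame([t.__dict__ for t in trials])[TRIAL_COLUMNS]


@dataclass
class GroundTruth:
    """Generator-side truth attached to synthetic sessions."""

    contact_events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EVENT_COLUMNS))
    neuron_params: list[NeuronSpec] = field(default_factory=list)
    #: per-whisker per-frame contact mask used by the rate model
    contact_mask: np.ndarray | None = None
    #: per-frame whisking-bout mask
    whisking_mask: np.ndarray | None = None


@dataclass
class Session:
    config: SessionConfig
    speed: np.ndarray                      # cm/s per frame
    surface: np.ndarray                    # surface axial position, cm per frame
    whisker_tracks: pd.DataFrame           # frame, whisker_id, label_index, x_px, y_px
    spike_trains: dict[int, np.ndarray]    # neuron_id -> spike times (s)
    spike_amplitudes: dict[int, np.ndarray] = field(default_factory=dict)
    trial_table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=TRIAL_COLUMNS))
    ground_truth: GroundTruth | None = None

    @property
    def frame_rate(self) -> float:
        return self.config.frame_rate

    @property
    def duration(self) -> float:
        return len(self.speed) / self.config.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.speed)) / self.config.frame_rate

    def check(self) -> list[str]:
        """Return a list of invariant violations (empty = consistent)."""
        problems: list[str] = []
        n = len(self.speed)
        if len(self.surface) != n:
            problems.append("surface trace length differs from speed trace")
        if np.any(~np.isfinite(self.speed)) or np.any(self.speed < 0):
            problems.append("speed trace has negative or non-finite values")
        dur = self.duration
        for nid, st in self.spike_trains.items():
            if len(st) and (st.min() < 0 or st.max() > dur):
                problems.append(f"neuron {nid}: spike times outside [0, duration]")
            if len(st) > 1 and np.any(np.diff(st) < 0):
                problems.append(f"neuron {nid}: spike times not sorted")
        if len(self.whisker_tracks):
            if self.whisker_tracks["frame"].max() >= n:
                problems.append("whisker tracks reference frames beyond the traces")
        return problems
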