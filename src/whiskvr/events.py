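"""Trial segmentation, GoW/LoW labelling, spike alignment and analysis windows.

The peri-event epoch is fixed at [-1.0, +2.0] s around each event.  The
standard analysis windows are: baseline = 300 ms before movement onset;
transient = data-driven (see :func:`find_transient_window`); sustained =
300 ms starting one second after the transient window ends; touch = 50 ms
after touch onset; modulation = 500 ms before and after movement onset.
All windows are half open ``[t0, t1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .config import SessionConfig
from .session import Session

__all__ = [
    "AlignmentError",
    "ResponseWindows",
    "PSTH",
    "segment_trials",
    "label_gow_low",
    "align_and_bin",
    "zscore_psth",
    "find_transient_window",
    "window_rates",
    "exclude_contaminated",
]

PERI_EPOCH = (-1.0, 2.0)


class AlignmentError(ValueError):
    """Raised on invalid alignment inputs."""


@dataclass
class ResponseWindows:
    """Per-population analysis windows, seconds relative to event onset."""

    baseline: tuple[float, float] = (-0.3, 0.0)
    transient: tuple[float, float] = (0.0, 0.3)
    gow: float = 0.05                       # width of the post-touch window
    modulation: float = 0.5                 # width of the pre/post movement windows

    @property
    def sustained(self) -> tuple[float, float]:
        """300 ms window starting one second after the transient window ends."""
        t1 = self.transient[1]
        return (t1 + 1.0, t1 + 1.3)

    def validate(self) -> None:
        if not self.transient[0] < self.transient[1]:
            raise AlignmentError("transient window must have t0 < t1")
        for w in (self.baseline, self.transient, self.sustained):
            if not (PERI_EPOCH[0] <= w[0] < w[1] <= PERI_EPOCH[1]):
                raise AlignmentError(f"window {w} outside the peri-event epoch {PERI_EPOCH}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sustained"] = self.sustained
        return d


# ---------------------------------------------------------------------------
# trials

def segment_trials(speed: np.ndarray, surface: np.ndarray,
                   cfg: SessionConfig) -> pd.DataFrame:
    """Recover the trial table from the speed and surface traces.

    Each sustained change of surface position is one trial; the outcome is
    the destination (rostral/caudal/out relative to the center position,
    taken as the starting position; center = a return movement).
    ``distance_covered`` is the locomotor distance since the previous
    movement onset.  A constant surface trace yields an empty table.
    """
    if len(speed) != len(surface):
        raise AlignmentError("speed and surface traces must share the frame clock")
    dt = 1.0 / cfg.frame_rate
    cumdist = np.cumsum(speed) * dt
    dpos = np.diff(surface)
    moving = dpos != 0
    onsets = np.flatnonzero(moving & ~np.concatenate([[False], moving[:-1]])) + 1
    center = surface[0]
    rows = []
    prev_onset = 0
    for f in onsets:
        stop = f
        while stop < len(surface) - 1 and surface[stop + 1] != surface[stop]:
            stop += 1
        dest = surface[stop]
        if np.isclose(dest, center):
            outcome, is_return = "center", True
        elif dest > center + 2 * cfg.translation_distance:
            outcome, is_return = "out", False
        elif dest > center:
            outcome, is_return = "rostral", False
        else:
            outcome, is_return = "caudal", False
        rows.append({"onset_time": (f - 1) / cfg.frame_rate,
                     "outcome": outcome, "is_return": is_return,
                     "distance_covered": cumdist[f - 1] - cumdist[prev_onset]})
        prev_onset = f - 1
    return pd.DataFrame(rows, columns=["onset_time", "outcome", "is_return",
                                       "distance_covered"])


def label_gow_low(trials: pd.DataFrame, events: pd.DataFrame,
                  cfg: SessionConfig, margin: float = 0.05) -> pd.DataFrame:
    """Annotate each movement as a GoW and/or LoW stimulus.

    A movement is GoW if at least one whisker gained contact within the
    movement epoch (onset to onset + translation duration + margin), LoW if
    at least one lost contact; both can hold; a movement within the
    already-contacted span is neither.
    """
    out = trials.copy()
    gow = np.zeros(len(trials), dtype=bool)
    low = np.zeros(len(trials), dtype=bool)
    if len(events):
        ext = events[events["origin"] == "external"]
        times = ext["time"].to_numpy()
        kinds = ext["kind"].to_numpy()
        for i, onset in enumerate(trials["onset_time"].to_numpy()):
            in_epoch = (times >= onset) & (times < onset + cfg.translation_duration + margin)
            gow[i] = np.any(in_epoch & (kinds == "GoW"))
            low[i] = np.any(in_epoch & (kinds == "LoW"))
    out["gow"] = gow
    out["low"] = low
    return out


# ---------------------------------------------------------------------------
# PSTH

@dataclass
class PSTH:
    """Event-aligned binned spike counts.

    ``counts`` is (n_events, n_bins) spike counts in half-open bins;
    ``rate``/``sem`` are across-event mean and s.e.m. in spikes/s;
    ``baseline_mean``/``baseline_sd`` are the across-event statistics of
    the baseline-window rate, used for z-scoring.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    baseline_mean: float = np.nan
    baseline_sd: float = np.nan
    z: np.ndarray | None = None

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2

    @property
    def rate(self) -> np.ndarray:
        return self.counts.mean(axis=0) / self.bin_width

    @property
    def sem(self) -> np.ndarray:
        n = self.counts.shape[0]
        return self.counts.std(axis=0, ddof=1) / self.bin_width / np.sqrt(n) if n > 1 \
            else np.zeros(self.counts.shape[1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"bin_start": self.bin_edges[:-1], "bin_end": self.bin_edges[1:],
                           "mean_rate": self.rate, "sem": self.sem})
        if self.z is not None:
            df["z"] = self.z
        return df


def align_and_bin(spikes: np.ndarray, event_times: np.ndarray,
                  window: tuple[float, float] = PERI_EPOCH,
                  bin_width: float = 0.05) -> PSTH:
    """Bin spikes into half-open bins aligned to each event."""
    event_times = np.asarray(event_times, dtype=float)
    if len(event_times) == 0:
        raise AlignmentError("need at least one event to build a PSTH")
    if bin_width <= 0:
        raise AlignmentError("bin width must be positive")
    n_bins = int(round((window[1] - window[0]) / bin_width))
    edges = window[0] + bin_width * np.arange(n_bins + 1)
    spikes = np.asarray(spikes, dtype=float)
    counts = np.empty((len(event_times), n_bins), dtype=float)
    for i, t0 in enumerate(event_times):
        rel = spikes[(spikes >= t0 + edges[0]) & (spikes < t0 + edges[-1])] - t0
        counts[i] = np.histogram(rel, bins=edges)[0]
    return PSTH(bin_edges=edges, counts=counts)


def zscore_psth(psth: PSTH, baseline: tuple[float, float] = (-0.3, 0.0)) -> PSTH:
    """Z-score the PSTH rate against the per-event baseline-window rate.

    Raises :class:`AlignmentError` when the baseline standard deviation is
    zero — such neurons are flagged and excluded upstream, never silently
    zeroed.
    """
    edges = psth.bin_edges
    sel = (edges[:-1] >= baseline[0]) & (edges[1:] <= baseline[1])
    if not sel.any():
        raise AlignmentError("baseline window does not overlap the PSTH bins")
    base_rates = psth.counts[:, sel].sum(axis=1) / (sel.sum() * psth.bin_width)
    mu = float(base_rates.mean())
    sd = float(base_rates.std(ddof=1)) if len(base_rates) > 1 else 0.0
    if sd <= 1e-12 * max(1.0, abs(mu)):
        raise AlignmentError("zero baseline variance; neuron must be excluded")
    z = (psth.rate - mu) / sd
    return PSTH(bin_edges=edges, counts=psth.counts, baseline_mean=mu,
                baseline_sd=sd, z=z)


# ---------------------------------------------------------------------------
# windows

def find_transient_window(psth: PSTH, search: tuple[float, float] = (0.0, 0.6),
                          clamp: tuple[float, float] = (0.0, 0.8),
                          fallback: tuple[float, float] = (0.0, 0.3),
                          ) -> tuple[float, float]:
    """Automated transient-window selection from a population-mean PSTH.

    The peak is the maximum bin in ``search`` (post onset); the window runs
    from the nearest local minimum preceding the peak to the nearest local
    minimum following it, clamped to ``clamp``.  If no interior peak
    exceeds the pre-onset baseline mean + 2 s.d., the fixed ``fallback``
    window is returned.  The rule is invariant to adding a constant rate.
    """
    rate = psth.rate
    centers = psth.bin_centers
    pre = rate[centers < 0]
    in_search = (centers > search[0]) & (centers <= search[1])
    if not in_search.any() or len(pre) == 0:
        return fallback
    thresh = pre.mean() + 2 * (pre.std(ddof=1) if len(pre) > 1 else 0.0)
    seg = np.flatnonzero(in_search)
    peak_i = seg[np.argmax(rate[seg])]
    if rate[peak_i] <= thresh:
        return fallback
    # nearest local minima around the peak; plateaus are crossed and the
    # first bin attaining the minimum of the descent is the trough
    i = peak_i
    while i > 0 and rate[i - 1] <= rate[i]:
        i -= 1
    i = i + int(np.argmin(rate[i:peak_i + 1]))
    j = peak_i
    while j < len(rate) - 1 and rate[j + 1] <= rate[j]:
        j += 1
    j = peak_i + int(np.argmin(rate[peak_i:j + 1]))
    t0 = max(clamp[0], float(psth.bin_edges[i]))
    t1 = min(clamp[1], float(psth.bin_edges[j + 1]))
    if t1 <= t0:
        return fallback
    return (t0, t1)


def window_rates(spikes: np.ndarray, event_times: np.ndarray,
                 window: tuple[float, float], duration: float | None = None,
                 ) -> np.ndarray:
    """Per-event firing rate (spikes/s) in a window relative to each event."""
    event_times = np.asarray(event_times, dtype=float)
    spikes = np.asarray(spikes, dtype=float)
    if duration is not None:
        bad = [float(t) for t in event_times
               if t + window[0] < 0 or t + window[1] > duration]
        if bad:
            raise AlignmentError(f"window extends beyond the recording for events {bad}")
    width = window[1] - window[0]
    lo = np.searchsorted(spikes, event_times + window[0], side="left")
    hi = np.searchsorted(spikes, event_times + window[1], side="left")
    return (hi - lo) / width


def exclude_contaminated(event_times: np.ndarray,
                         baseline: tuple[float, float] = (-0.3, 0.0)) -> np.ndarray:
    """Drop events with another event of the same stream inside their baseline window."""
    t = np.sort(np.asarray(event_times, dtype=float))
    keep = np.ones(len(t), dtype=bool)
    keep[1:] = np.diff(t) >= -baseline[0]
    return t[keep]
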