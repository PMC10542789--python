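"""Response magnitude versus stimulus repetition.

Transient neurons habituate to repeated external gains in whisker contact:
their windowed response declines roughly linearly with repetition number
over tens of minutes, while sustained (self-generated) activity is stable.
This module screens neurons for baseline drift, fits per-neuron ordinary
least-squares slopes of response rate against repetition index, tests the
population of slopes, and tracks control covariates (whisker position and
spike-waveform amplitude, range-normalized to [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HabituationError",
    "drift_screen",
    "repetition_regression",
    "population_slope_test",
    "normalize_range",
    "waveform_amplitude_series",
    "RegressionResult",
]

DRIFT_ALPHA = 0.05
DRIFT_BLOCK = 10


class HabituationError(ValueError):
    """Raised on invalid habituation-analysis inputs."""


def drift_screen(baseline_rates: np.ndarray, alpha: float = DRIFT_ALPHA) -> bool | None:
    """Flag baseline drift: first 10 vs last 10 trials, Wilcoxon signed rank.

    Trials are paired by order within each block (i-th of the first block
    with i-th of the last).  Returns True (drifting — exclude), False
    (stable), or None when fewer than 20 trials are available (the neuron
    is skipped, not an error).
    """
    x = np.asarray(baseline_rates, dtype=float)
    if len(x) < 2 * DRIFT_BLOCK:
        return None
    first, last = x[:DRIFT_BLOCK], x[-DRIFT_BLOCK:]
    diff = last - first
    if np.all(diff == 0):
        return False
    res = stats.wilcoxon(diff[diff != 0], method="exact")
    return bool(res.pvalue < alpha)


@dataclass
class RegressionResult:
    slope: float        # spikes/s per repetition
    intercept: float
    p_value: float      # two-sided test of zero slope
    stderr: float
    n: int


def repetition_regression(responses: np.ndarray,
                          repetitions: np.ndarray | None = None) -> RegressionResult:
    """OLS fit of response rate against repetition index.

    ``responses`` may contain NaN for skipped repetitions (gaps, not
    zeros); those points are dropped.  Requires at least 3 distinct
    repetitions.
    """
    y = np.asarray(responses, dtype=float)
    x = np.arange(1, len(y) + 1, dtype=float) if repetitions is None \
        else np.asarray(repetitions, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    x, y = x[ok], y[ok]
    if len(np.unique(x)) < 3:
        raise HabituationError("need at least 3 distinct repetitions to fit a slope")
    res = stats.linregress(x, y)
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            p_value=p, stderr=float(res.stderr), n=len(x))


def population_slope_test(slopes: np.ndarray, alternative: str = "less") -> float:
    """One-sided one-sample t-test of the population of slopes against 0.

    The default alternative is a negative mean slope (habituation)."""
    s = np.asarray(slopes, dtype=float)
    s = s[np.isfinite(s)]
    if len(s) < 3:
        raise HabituationError("need at least 3 slopes")
    if np.ptp(s) == 0:
        raise HabituationError("slope vector has zero variance")
    res = stats.ttest_1samp(s, 0.0, alternative=alternative)
    return float(res.pvalue)


def normalize_range(values: np.ndarray) -> np.ndarray:
    """Scale to range: (x - min) / (max - min); min maps to 0, max to 1."""
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if len(finite) == 0:
        raise HabituationError("no finite values to normalize")
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        raise HabituationError("cannot range-normalize a constant vector")
    return (x - lo) / (hi - lo)


def waveform_amplitude_series(spike_times: np.ndarray, amplitudes: np.ndarray,
                              event_times: np.ndarray,
                              window: tuple[float, float]) -> pd.DataFrame:
    """Mean normalized spike-waveform amplitude per stimulus repetition.

    For each repetition, the mean amplitude of spikes falling in the
    transient window; repetitions with no spikes are gaps (NaN).  The
    series is range-normalized; a degenerate (constant) series is reported
    with status ``"stable (degenerate range)"`` and NaN normalized values
    instead of raising.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    means = []
    for t0 in np.asarray(event_times, dtype=float):
        sel = (spike_times >= t0 + window[0]) & (spike_times < t0 + window[1])
        means.append(float(amplitudes[sel].mean()) if sel.any() else np.nan)
    means = np.asarray(means)
    status = "ok"
    try:
        norm = normalize_range(means)
    except HabituationError:
        norm = np.full_like(means, np.nan)
        status = "stable (degenerate range)"
    return pd.DataFrame({"repetition": np.arange(1, len(means) + 1),
                         "mean_amplitude": means,
                         "normalized_amplitude": norm,
                         "status": status})
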