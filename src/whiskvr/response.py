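"""Neuron classification and response statistics.

Neurons are classified from per-trial firing rates in the baseline,
transient and sustained windows: a one-way ANOVA across the three windows
gates at alpha = 0.05, followed by Tukey-corrected pairwise comparisons
(studentized range, family alpha 0.05 across the three pairs).  A neuron
is *sustained* when baseline and sustained rates differ significantly;
*transient* when the transient rate differs significantly from baseline
and exceeds both the baseline and sustained means; *both* when both rules
fire; otherwise *nonresponsive*.  Neurons with a significant transient
and/or sustained response count as tactile responsive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ResponseError",
    "NeuronClassification",
    "classify_neuron",
    "modulation_index",
    "gow_response",
    "compare_external_self",
    "GoWComparison",
    "RESPONSIVE_LABELS",
]

ALPHA = 0.05
MIN_TRIALS = 5
RESPONSIVE_LABELS = frozenset({"transient", "sustained", "both"})


class ResponseError(ValueError):
    """Raised on invalid response-statistics inputs."""


@dataclass
class NeuronClassification:
    neuron_id: int
    label: str                      # transient | sustained | both | nonresponsive
    anova_p: float
    sig_baseline_transient: bool
    sig_baseline_sustained: bool
    sig_transient_sustained: bool

    @property
    def responsive(self) -> bool:
        return self.label in RESPONSIVE_LABELS


def classify_neuron(baseline: np.ndarray, transient: np.ndarray,
                    sustained: np.ndarray, neuron_id: int = -1,
                    alpha: float = ALPHA) -> NeuronClassification:
    """Classify one neuron from its per-trial window rates."""
    groups = [np.asarray(g, dtype=float) for g in (baseline, transient, sustained)]
    if min(len(g) for g in groups) < MIN_TRIALS:
        raise ResponseError(
            f"neuron {neuron_id}: need at least {MIN_TRIALS} trials per window")
    if np.ptp(np.concatenate(groups)) == 0:
        # exact ties everywhere: no evidence of any difference
        return NeuronClassification(neuron_id, "nonresponsive", 1.0, False, False, False)
    with np.errstate(invalid="ignore", divide="ignore"):
        anova = stats.f_oneway(*groups)
    anova_p = float(anova.pvalue) if np.isfinite(anova.pvalue) else 1.0
    sig_bt = sig_bs = sig_ts = False
    if anova_p < alpha:
        tukey = stats.tukey_hsd(*groups)
        sig_bt = tukey.pvalue[0, 1] < alpha
        sig_bs = tukey.pvalue[0, 2] < alpha
        sig_ts = tukey.pvalue[1, 2] < alpha
    mb, mt, ms = (g.mean() for g in groups)
    is_sustained = sig_bs
    is_transient = sig_bt and mt > mb and mt > ms
    if is_transient and is_sustained:
        label = "both"
    elif is_transient:
        label = "transient"
    elif is_sustained:
        label = "sustained"
    else:
        label = "nonresponsive"
    return NeuronClassification(neuron_id, label, anova_p, sig_bt, sig_bs, sig_ts)


def classify_population(window_rate_table: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]],
                        alpha: float = ALPHA) -> pd.DataFrame:
    """Classify many neurons; returns a tidy table, skipping under-sampled ones."""
    rows = []
    for nid, (b, t, s) in window_rate_table.items():
        try:
            c = classify_neuron(b, t, s, neuron_id=nid, alpha=alpha)
        except ResponseError:
            continue
        rows.append({"neuron_id": nid, "label": c.label, "anova_p": c.anova_p,
                     "sig_baseline_transient": c.sig_baseline_transient,
                     "sig_baseline_sustained": c.sig_baseline_sustained,
                     "sig_transient_sustained": c.sig_transient_sustained,
                     "responsive": c.responsive})
    return pd.DataFrame(rows, columns=["neuron_id", "label", "anova_p",
                                       "sig_baseline_transient", "sig_baseline_sustained",
                                       "sig_transient_sustained", "responsive"])


# ---------------------------------------------------------------------------
# modulation index

def modulation_index(pre_rate, post_rate):
    """(post - pre) / (post + pre), defined as 0 when both rates are 0.

    Bounded in [-1, 1] for nonnegative rates; antisymmetric in its
    arguments.  Accepts scalars or arrays.
    """
    pre = np.asarray(pre_rate, dtype=float)
    post = np.asarray(post_rate, dtype=float)
    if np.any(pre < 0) or np.any(post < 0):
        raise ResponseError("rates must be nonnegative")
    total = pre + post
    with np.errstate(invalid="ignore", divide="ignore"):
        mi = np.where(total > 0, (post - pre) / np.where(total > 0, total, 1.0), 0.0)
    return float(mi) if mi.ndim == 0 else mi


# ---------------------------------------------------------------------------
# external vs self GoW

def gow_response(spikes: np.ndarray, external_times: np.ndarray,
                 self_times: np.ndarray, window: float = 0.05,
                 baseline_window: tuple[float, float] = (-0.3, 0.0),
                 ) -> tuple[float, float]:
    """Baseline-subtracted GoW responses (spikes/s) per condition.

    The external response is the mean rate in the ``window`` seconds after
    touch onset minus the pre-touch (free-whisking) rate; the self response
    is the same window rate minus the rate during self-motion (the
    pre-touch window of the self events).  A missing condition yields NaN.
    """
    from .events import window_rates

    def delta(times: np.ndarray) -> float:
        times = np.asarray(times, dtype=float)
        if len(times) == 0:
            return float("nan")
        post = window_rates(spikes, times, (0.0, window)).mean()
        pre = window_rates(spikes, times, baseline_window).mean()
        return float(post - pre)

    return delta(external_times), delta(self_times)


@dataclass
class GoWComparison:
    statistic: float
    p_value: float
    p_paired_t: float
    median_external: float
    median_self: float
    fraction_external_larger: float
    n: int


def compare_external_self(d_external: np.ndarray, d_self: np.ndarray) -> GoWComparison:
    """Two-sided Wilcoxon signed-rank comparison of paired responses.

    Zero differences are dropped (standard convention); the exact null
    distribution is used for n <= 25, a continuity-corrected normal
    approximation above.  A paired t-test is reported alongside.
    """
    d_external = np.asarray(d_external, dtype=float)
    d_self = np.asarray(d_self, dtype=float)
    if len(d_external) != len(d_self):
        raise ResponseError("paired vectors must have equal length")
    diff = d_external - d_self
    nonzero = diff[diff != 0]
    if len(nonzero) == 0:
        stat, p = 0.0, 1.0
    else:
        res = stats.wilcoxon(nonzero, correction=len(nonzero) > 25,
                             method="exact" if len(nonzero) <= 25 else "approx")
        stat, p = float(res.statistic), float(res.pvalue)
    t_res = stats.ttest_rel(d_external, d_self)
    return GoWComparison(
        statistic=stat, p_value=p,
        p_paired_t=float(t_res.pvalue) if np.isfinite(t_res.pvalue) else 1.0,
        median_external=float(np.median(d_external)),
        median_self=float(np.median(d_self)),
        fraction_external_larger=float(np.mean(diff > 0)),
        n=len(d_external))
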