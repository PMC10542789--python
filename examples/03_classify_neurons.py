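"""Transient / sustained / nonresponsive classification.

Aligns spikes to gain-of-contact surface movements, finds the transient
window from the population PSTH, computes baseline / transient / sustained
window rates per trial, and classifies each neuron with a one-way ANOVA
plus Tukey-corrected pairwise comparisons.  The printed confusion matrix
compares recovered labels with the generator's classes.
"""

import numpy as np
import pandas as pd

import whiskvr as w
from whiskvr import events as ev
from whiskvr.response import classify_population

cfg = w.SessionConfig(duration=900.0, seed=5)
specs = w.make_population(60, seed=5)
session = w.simulate_session(cfg, specs, render=False)

trials = ev.label_gow_low(ev.segment_trials(session.speed, session.surface, cfg),
                          session.ground_truth.contact_events, cfg)
gow = ev.exclude_contaminated(trials.loc[trials["gow"], "onset_time"].to_numpy())
gow = gow[(gow - 1 >= 0) & (gow + 2 <= session.duration)]
print(f"{len(gow)} gain-of-contact movements")

pooled = np.sort(np.concatenate(list(session.spike_trains.values())))
windows = ev.ResponseWindows(
    transient=ev.find_transient_window(ev.align_and_bin(pooled, gow)))
print(f"transient window  : {windows.transient[0]:.2f}..{windows.transient[1]:.2f} s")
print(f"sustained window  : {windows.sustained[0]:.2f}..{windows.sustained[1]:.2f} s")

table = {nid: (ev.window_rates(st, gow, windows.baseline),
               ev.window_rates(st, gow, windows.transient),
               ev.window_rates(st, gow, windows.sustained))
         for nid, st in session.spike_trains.items()}
cls = classify_population(table)
truth = {s.neuron_id: s.class_label for s in specs}
cls["generator"] = cls["neuron_id"].map(truth)
print(f"responsive        : {cls['responsive'].mean() * 100:.0f}%")
print(pd.crosstab(cls["generator"], cls["label"]))
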