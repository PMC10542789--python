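"""Habituation of the transient response across stimulus repetitions.

Transient neurons are generated with a fractional response decline per
external gain-of-contact repetition; sustained neurons are stable.  The
example screens for baseline drift, fits per-neuron OLS slopes of windowed
rate against repetition index, and runs the one-sided population t-test:
expect a strongly negative transient population (small p) and a null
sustained population (large p).
"""

import numpy as np

import whiskvr as w
from whiskvr import events as ev
from whiskvr.habituation import drift_screen, population_slope_test, repetition_regression

cfg = w.SessionConfig(duration=2400.0, seed=3)
specs = w.make_population(60, seed=3, habituation_slope=-0.02)
session = w.simulate_session(cfg, specs, render=False)

trials = ev.label_gow_low(ev.segment_trials(session.speed, session.surface, cfg),
                          session.ground_truth.contact_events, cfg)
gow = ev.exclude_contaminated(trials.loc[trials["gow"], "onset_time"].to_numpy())
gow = gow[(gow - 1 >= 0) & (gow + 2 <= session.duration)]
print(f"{len(gow)} gain-of-contact repetitions")

windows = ev.ResponseWindows()
slopes = {"transient": [], "sustained": []}
n_drifting = 0
for spec in specs:
    if spec.class_label not in slopes:
        continue
    st = session.spike_trains[spec.neuron_id]
    base = ev.window_rates(st, gow, windows.baseline)
    if drift_screen(base):
        n_drifting += 1
        continue
    win = windows.transient if spec.class_label == "transient" else windows.sustained
    fit = repetition_regression(ev.window_rates(st, gow, win) - base)
    slopes[spec.class_label].append(fit.slope)

print(f"{n_drifting} neurons excluded for baseline drift")
for label, sl in slopes.items():
    sl = np.asarray(sl)
    p = population_slope_test(sl)
    print(f"{label:9s}: median slope {np.median(sl):+.3f} spikes/s per repetition, "
          f"one-sided t-test p = {p:.2e} (n = {len(sl)})")
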