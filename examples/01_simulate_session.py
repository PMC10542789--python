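"""Generate a synthetic whisker-VR session and summarize its behaviour.

A head-fixed virtual mouse runs (~23.7 cm/s), whisks (~19 Hz) against a
surface yoked to its locomotion, and every 200 cm the surface translates
1 cm rostrally or caudally or stays put with equal probability.  The
printed numbers are the realized behavioural statistics — they should sit
near the configured values above.
"""

import numpy as np
from scipy import signal

import whiskvr as w

cfg = w.SessionConfig(duration=300.0, seed=42)
session = w.simulate_session(cfg, w.make_population(20, seed=42), render=False)

speed = session.speed
running = speed > 1.0
print(f"mean running speed : {speed[running].mean():.1f} cm/s "
      f"({running.mean() * 100:.0f}% of frames running)")

whisking = session.ground_truth.whisking_mask
drive = w.generate_whisking(cfg, session.surface).drive
f, p = signal.welch(drive[whisking] - drive[whisking].mean(),
                    fs=cfg.frame_rate, nperseg=2 ** 13)
band = (f >= 5) & (f <= 30)
print(f"whisking peak      : {f[band][np.argmax(p[band])]:.1f} Hz")

trials = session.trial_table
draws = trials[~trials["is_return"]]
print(f"trials             : {len(trials)} ({len(draws)} outcome draws)")
print(f"outcome counts     : {draws['outcome'].value_counts().to_dict()}")

events = session.ground_truth.contact_events
print("contact events     :")
print(events.groupby(["kind", "origin"]).size().to_string())
print(f"spikes (20 neurons): {sum(len(s) for s in session.spike_trains.values())}")
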