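"""Optional import of NWB-formatted recordings onto the session model.

NWB files are HDF5; this reader maps the fields the pipeline consumes —
acquisition time series for treadmill speed and surface position,
behavioural point tracks, and per-unit spike times — directly with h5py.
Fields absent from the file are left empty, never fabricated.  The import
path is optional: all analyses run on synthetic or TSV sessions without it.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import SessionConfig
from .session import Session

__all__ = ["read_nwb"]


def _series(group: h5py.Group, name: str) -> np.ndarray | None:
    if name in group and "data" in group[name]:
        return np.asarray(group[name]["data"])
    return None


def _series_rate(group: h5py.Group, name: str) -> float | None:
    if name in group and "starting_time" in group[name]:
        st = group[name]["starting_time"]
        if "rate" in st.attrs:
            return float(st.attrs["rate"])
    return None


def read_nwb(path: str | Path, *, speed_series: str = "speed",
             surface_series: str = "surface") -> Session:
    """Map an NWB file onto a :class:`~whiskvr.session.Session`.

    ``speed_series`` and ``surface_series`` name the acquisition
    TimeSeries holding the treadmill speed (cm/s) and surface position
    (cm).  Unit spike times are read from the ``/units`` ragged table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no NWB file at {path}")
    with h5py.File(path, "r") as f:
        acq = f.get("acquisition", {})
        speed = _series(acq, speed_series)
        surface = _series(acq, surface_series)
        rate = _series_rate(acq, speed_series) or _series_rate(acq, surface_series) or 500.0

        spike_trains: dict[int, np.ndarray] = {}
        if "units" in f and "spike_times" in f["units"]:
            times = np.asarray(f["units"]["spike_times"])
            index = np.asarray(f["units"]["spike_times_index"])
            start = 0
            for uid, stop in enumerate(index):
                spike_trains[uid] = np.sort(times[start:int(stop)])
                start = int(stop)

        tracks = pd.DataFrame(columns=["frame", "whisker_id", "label_index", "x_px", "y_px"])
        behav = f.get("processing/behavior", None)
        if behav is not None and "whisker_tracks" in behav:
            grp = behav["whisker_tracks"]
            cols = {c: np.asarray(grp[c]) for c in
                    ("frame", "whisker_id", "label_index", "x_px", "y_px") if c in grp}
            if cols:
                tracks = pd.DataFrame(cols)
                if "whisker_id" in tracks:
                    tracks["whisker_id"] = tracks["whisker_id"].map(
                        lambda v: v.decode() if isinstance(v, bytes) else v)

    n = max((len(x) for x in (speed, surface) if x is not None), default=0)
    if speed is None:
        speed = np.zeros(n)
    if surface is None:
        surface = np.zeros(n)
    duration = max(n / rate, max((st.max() for st in spike_trains.values()
                                  if len(st)), default=0.0))
    cfg = SessionConfig(duration=max(duration, 1.0 / rate), frame_rate=rate)
    return Session(config=cfg, speed=np.asarray(speed, float),
                   surface=np.asarray(surface, float), whisker_tracks=tracks,
                   spike_trains=spike_trains)
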