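"""Session directory persistence.

A session is a directory of tab-separated tables plus ``session.json``:

* ``speed.tsv`` — frame, cm_per_s
* ``surface.tsv`` — frame, position_cm
* ``whiskers.tsv`` — frame, whisker_id, label_index, x_px, y_px
* ``spikes.tsv`` — neuron_id, time_s [, amplitude]
* ``trials.tsv`` — onset_time, outcome, is_return, distance_covered
* ``events_truth.tsv`` / ``neurons_truth.tsv`` — synthetic ground truth
* ``session.json`` — config echo, format version, seed

The round trip is lossless up to text float formatting.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import NeuronSpec, SessionConfig
from .session import EVENT_COLUMNS, TRIAL_COLUMNS, GroundTruth, Session

__all__ = ["write_session", "read_session", "validate_session",
           "SessionFormatError", "FORMAT_VERSION"]

FORMAT_VERSION = 1

REQUIRED_TABLES = ["speed.tsv", "surface.tsv", "whiskers.tsv", "spikes.tsv", "trials.tsv"]


class SessionFormatError(ValueError):
    """Raised when a session directory is malformed."""


def _write_tsv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_session(session: Session, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n = len(session.speed)
    _write_tsv(path / "speed.tsv",
               pd.DataFrame({"frame": np.arange(n), "cm_per_s": session.speed}))
    _write_tsv(path / "surface.tsv",
               pd.DataFrame({"frame": np.arange(n), "position_cm": session.surface}))
    _write_tsv(path / "whiskers.tsv", session.whisker_tracks)
    rows = []
    for nid in sorted(session.spike_trains):
        st = session.spike_trains[nid]
        amp = session.spike_amplitudes.get(nid)
        rows.append(pd.DataFrame({
            "neuron_id": nid, "time_s": st,
            "amplitude": amp if amp is not None else np.nan,
        }))
    spikes = (pd.concat(rows, ignore_index=True) if rows
              else pd.DataFrame(columns=["neuron_id", "time_s", "amplitude"]))
    _write_tsv(path / "spikes.tsv", spikes)
    _write_tsv(path / "trials.tsv", session.trial_table)
    if session.ground_truth is not None:
        _write_tsv(path / "events_truth.tsv", session.ground_truth.contact_events)
        _write_tsv(path / "neurons_truth.tsv",
                   pd.DataFrame([dataclasses.asdict(s) for s in session.ground_truth.neuron_params]))
    meta = {
        "format_version": FORMAT_VERSION,
        "seed": session.config.seed,
        "config": session.config.to_dict(),
        "neuron_ids": sorted(int(k) for k in session.spike_trains),
    }
    (path / "session.json").write_text(json.dumps(meta, indent=1))
    return path


def _read_tsv(path: Path, name: str) -> pd.DataFrame:
    f = path / name
    if not f.exists():
        raise SessionFormatError(f"missing required table {name!r} in {path}")
    try:
        return pd.read_csv(f, sep="\t")
    except Exception as exc:  # malformed table
        raise SessionFormatError(f"malformed table {name!r}: {exc}") from exc


def read_session(path: str | Path) -> Session:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no session at {path}")
    meta_file = path / "session.json"
    if not meta_file.exists():
        raise SessionFormatError(f"missing required table 'session.json' in {path}")
    meta = json.loads(meta_file.read_text())
    version = meta.get("format_version")
    if version != FORMAT_VERSION:
        raise SessionFormatError(
            f"format version mismatch: file has {version}, reader supports {FORMAT_VERSION}")
    cfg = SessionConfig.from_dict(meta["config"])

    speed = _read_tsv(path, "speed.tsv")["cm_per_s"].to_numpy(float)
    surface = _read_tsv(path, "surface.tsv")["position_cm"].to_numpy(float)
    tracks = _read_tsv(path, "whiskers.tsv")
    spikes_df = _read_tsv(path, "spikes.tsv")
    trials = _read_tsv(path, "trials.tsv")
    for col in TRIAL_COLUMNS:
        if col not in trials.columns and len(trials):
            raise SessionFormatError(f"trials.tsv lacks column {col!r}")

    spike_trains: dict[int, np.ndarray] = {}
    amplitudes: dict[int, np.ndarray] = {}
    ids = meta.get("neuron_ids", sorted(spikes_df["neuron_id"].unique())) if len(spikes_df) \
        else meta.get("neuron_ids", [])
    for nid in ids:
        sub = spikes_df[spikes_df["neuron_id"] == nid]
        spike_trains[int(nid)] = sub["time_s"].to_numpy(float)
        if "amplitude" in sub.columns and not sub["amplitude"].isna().all():
            amplitudes[int(nid)] = sub["amplitude"].to_numpy(float)

    truth = None
    ev_file = path / "events_truth.tsv"
    if ev_file.exists():
        events = pd.read_csv(ev_file, sep="\t")
        if len(events) == 0:
            events = pd.DataFrame(columns=EVENT_COLUMNS)
        specs = []
        nt = path / "neurons_truth.tsv"
        if nt.exists():
            for rec in pd.read_csv(nt, sep="\t").to_dict("records"):
                if isinstance(rec.get("preferred_whiskers"), str):
                    rec["preferred_whiskers"] = tuple(
                        eval(rec["preferred_whiskers"]) if rec["preferred_whiskers"].startswith("(")
                        else (rec["preferred_whiskers"],))
                elif not isinstance(rec.get("preferred_whiskers"), tuple):
                    rec["preferred_whiskers"] = ()
                specs.append(NeuronSpec(**rec))
        truth = GroundTruth(contact_events=events, neuron_params=specs)
    return Session(config=cfg, speed=speed, surface=surface, whisker_tracks=tracks,
                   spike_trains=spike_trains, spike_amplitudes=amplitudes,
                   trial_table=trials, ground_truth=truth)


def validate_session(path: str | Path) -> list[str]:
    """Check a session directory; return a list of violations (empty = valid).

    Checks the schema (required tables and columns), clock alignment of the
    traces, spike-time bounds and monotonicity.  Violations are reported,
    never repaired.
    """
    path = Path(path)
    problems: list[str] = []
    if not path.exists():
        raise FileNotFoundError(f"no session at {path}")
    for name in REQUIRED_TABLES + ["session.json"]:
        if not (path / name).exists():
            problems.append(f"schema: missing table {name!r}")
    if problems:
        return problems
    try:
        session = read_session(path)
    except SessionFormatError as exc:
        return [f"schema: {exc}"]
    problems.extend(session.check())
    return problems
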