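"""End-to-end pipeline: simulate/load -> kinematics -> alignment ->
classification -> habituation -> decoding.

Each stage writes its artifacts under the output directory and the run
ends with ``summary.json`` (machine readable: neuron counts per class,
population test results, peak decoding accuracy) and ``report.txt``.  A
stage failure aborts with the stage name; artifacts of completed stages
are retained.  For a fixed master seed the full pipeline is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import events as ev
from . import habituation as hab
from . import response as resp
from .config import ConfigError, SessionConfig
from .decoding import DecodingConfig, cross_validated_decode, feature_matrix
from .io import read_session, write_session
from .kinematics import compute_kinematics, detect_touch
from .session import Session
from .simulate import make_population, simulate_session

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("whiskvr")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str | Path | None = None
    session_config: SessionConfig | None = None
    session_path: str | Path | None = None
    seed: int = 0
    n_neurons: int = 50
    stages: tuple[str, ...] = ("kinematics", "align", "classify", "habituation", "decode")
    decoding: DecodingConfig = field(default_factory=DecodingConfig)
    render_tracks: bool = True

    def validate(self) -> None:
        if self.out_dir is None:
            raise ConfigError("an output directory is required")
        if (self.session_config is None) == (self.session_path is None):
            raise ConfigError("exactly one of session_config or session_path is required")


def _config_hash(cfg: PipelineConfig) -> str:
    if cfg.session_config is not None:
        payload = json.dumps(cfg.session_config.to_dict(), sort_keys=True)
    else:
        payload = str(cfg.session_path)
    return hashlib.sha1(f"{payload}|{cfg.seed}".encode()).hexdigest()[:12]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
            log.info("stage=%s wall_s=%.2f", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_stage("simulate")
def _get_session(cfg: PipelineConfig) -> Session:
    if cfg.session_path is not None:
        return read_session(cfg.session_path)
    scfg = cfg.session_config
    scfg.seed = cfg.seed
    specs = make_population(cfg.n_neurons, seed=cfg.seed)
    return simulate_session(scfg, specs, render=cfg.render_tracks)


@_stage("kinematics")
def _run_kinematics(session: Session, out: Path) -> pd.DataFrame | None:
    if not len(session.whisker_tracks):
        return None
    kin = compute_kinematics(session.whisker_tracks, session.config.face_point,
                             session.frame_rate, px_per_mm=session.config.px_per_mm)
    kin.to_csv(out / "kinematics.tsv", sep="\t", index=False, float_format="%.6g")
    touches = []
    for wid, grp in kin.groupby("whisker_id"):
        t = detect_touch(grp["curvature"].to_numpy(), grp["dkappa_dt"].to_numpy(),
                         session.frame_rate, phase=grp["phase"].to_numpy())
        t.insert(1, "whisker_id", wid)
        touches.append(t)
    pd.concat(touches, ignore_index=True).to_csv(
        out / "touches.tsv", sep="\t", index=False, float_format="%.6g")
    return kin


@_stage("align")
def _run_align(session: Session, windows_out: Path):
    trials = ev.segment_trials(session.speed, session.surface, session.config)
    events = (session.ground_truth.contact_events if session.ground_truth is not None
              else pd.DataFrame(columns=["time", "whisker_id", "kind", "origin",
                                         "direction", "repetition_index"]))
    trials = ev.label_gow_low(trials, events, session.config)
    trials.to_csv(windows_out / "trials.tsv", sep="\t", index=False, float_format="%.6g")
    events.to_csv(windows_out / "events.tsv", sep="\t", index=False, float_format="%.6g")

    # GoW stimuli are aligned at movement onset (windows are defined
    # relative to the start of surface movement)
    gow_times = ev.exclude_contaminated(
        trials.loc[trials["gow"], "onset_time"].to_numpy())
    dur = session.duration
    gow_times = gow_times[(gow_times + ev.PERI_EPOCH[0] >= 0)
                          & (gow_times + ev.PERI_EPOCH[1] <= dur)]
    windows = ev.ResponseWindows()
    if len(gow_times):
        pooled = np.sort(np.concatenate([
            st for st in session.spike_trains.values()])) if session.spike_trains else np.empty(0)
        pop = ev.align_and_bin(pooled, gow_times, bin_width=0.05)
        windows = ev.ResponseWindows(transient=ev.find_transient_window(pop))
        pop.to_frame().to_csv(windows_out / "psth_external_gow.tsv", sep="\t",
                              index=False, float_format="%.6g")
    (windows_out / "windows.json").write_text(json.dumps(windows.to_dict(), indent=1))
    return trials, events, windows, gow_times


@_stage("classify")
def _run_classify(session: Session, windows: ev.ResponseWindows,
                  gow_times: np.ndarray, trials: pd.DataFrame, out: Path):
    table = {}
    for nid, st in session.spike_trains.items():
        if len(gow_times) < resp.MIN_TRIALS:
            break
        table[nid] = (ev.window_rates(st, gow_times, windows.baseline),
                      ev.window_rates(st, gow_times, windows.transient),
                      ev.window_rates(st, gow_times, windows.sustained))
    classes = resp.classify_population(table)
    classes.to_csv(out / "neuron_class.tsv", sep="\t", index=False, float_format="%.6g")

    # decoding labels come from the ground-truth trial table when present
    # (it includes center draws, which produce no surface movement)
    if session.ground_truth is not None and len(session.trial_table):
        draws = session.trial_table[~session.trial_table["is_return"]]
    else:
        draws = trials[~trials["is_return"]]
    gow_on = trials[trials["gow"]]["onset_time"].to_numpy()
    low_on = trials[trials["low"]]["onset_time"].to_numpy()
    w = ev.ResponseWindows().modulation
    rows = []
    for nid, st in session.spike_trains.items():
        def mi(onsets):
            if len(onsets) == 0:
                return np.nan
            pre = ev.window_rates(st, onsets, (-w, 0.0)).mean()
            post = ev.window_rates(st, onsets, (0.0, w)).mean()
            return resp.modulation_index(pre, post)
        rows.append({"neuron_id": nid, "gow_mi": mi(gow_on), "low_mi": mi(low_on)})
    mod = pd.DataFrame(rows)
    mod.to_csv(out / "modulation.tsv", sep="\t", index=False, float_format="%.6g")
    return classes, mod, draws


@_stage("habituation")
def _run_habituation(session: Session, classes: pd.DataFrame,
                     windows: ev.ResponseWindows, gow_times: np.ndarray, out: Path):
    label_of = dict(zip(classes["neuron_id"], classes["label"]))
    rows, slope_rows = [], []
    for nid, st in session.spike_trains.items():
        label = label_of.get(nid, "nonresponsive")
        if label not in resp.RESPONSIVE_LABELS or len(gow_times) < 3:
            continue
        base = ev.window_rates(st, gow_times, windows.baseline)
        drift = hab.drift_screen(base)
        if drift:
            slope_rows.append({"neuron_id": nid, "label": label, "drift": True,
                               "slope": np.nan, "p": np.nan})
            continue
        window = windows.transient if label in ("transient", "both") else windows.sustained
        rates = ev.window_rates(st, gow_times, window) - base
        try:
            fit = hab.repetition_regression(rates)
        except hab.HabituationError:
            continue
        slope_rows.append({"neuron_id": nid, "label": label,
                           "drift": bool(drift) if drift is not None else False,
                           "slope": fit.slope, "p": fit.p_value})
        for r, v in enumerate(rates, start=1):
            rows.append({"neuron_id": nid, "stream": "external_gow", "rep": r, "rate": v})
    pd.DataFrame(rows).to_csv(out / "repetition_series.tsv", sep="\t", index=False,
                              float_format="%.6g")
    slopes = pd.DataFrame(slope_rows)
    slopes.to_csv(out / "slopes.tsv", sep="\t", index=False, float_format="%.6g")
    pops = {}
    for lab in ("transient", "sustained"):
        sel = slopes[(slopes.get("label") == lab) & (~slopes.get("drift", False))] \
            if len(slopes) else slopes
        vals = sel["slope"].dropna().to_numpy() if len(sel) else np.empty(0)
        try:
            pops[lab] = hab.population_slope_test(vals)
        except hab.HabituationError:
            pops[lab] = None
    return slopes, pops


@_stage("decode")
def _run_decode(session: Session, draws: pd.DataFrame, cfg: PipelineConfig, out: Path):
    labels = draws["outcome"].to_numpy()
    onsets = draws["onset_time"].to_numpy()
    dcfg = cfg.decoding
    dur = session.duration
    ok = (onsets + dcfg.epoch[0] >= 0) & (onsets + dcfg.epoch[1] <= dur)
    onsets, labels = onsets[ok], labels[ok]
    feats = feature_matrix(session.spike_trains, onsets, dcfg)
    result = cross_validated_decode(feats, labels, dcfg, seed=cfg.seed)
    pd.DataFrame({"time_s": result.times, "mean_acc": result.accuracy,
                  "sem": result.sem, "chance": result.chance}).to_csv(
        out / "decode_accuracy.tsv", sep="\t", index=False, float_format="%.6g")
    return result


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages; returns the summary dictionary."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "config_hash": _config_hash(cfg)}

    session = _get_session(cfg)
    if cfg.session_config is not None:
        write_session(session, out / "session")

    if "kinematics" in cfg.stages:
        _run_kinematics(session, out)

    trials = events = windows = None
    gow_times = np.empty(0)
    if "align" in cfg.stages:
        trials, events, windows, gow_times = _run_align(session, out)
        summary["n_trials"] = int(len(trials))
        summary["n_external_gow"] = int(len(gow_times))
        summary["transient_window"] = list(windows.transient)

    classes = mod = draws = None
    if "classify" in cfg.stages and trials is not None:
        classes, mod, draws = _run_classify(session, windows, gow_times, trials, out)
        counts = classes["label"].value_counts().to_dict() if len(classes) else {}
        summary["neuron_counts"] = {k: int(v) for k, v in counts.items()}
        if len(classes):
            summary["responsive_fraction"] = float(classes["responsive"].mean())

    if "habituation" in cfg.stages and classes is not None:
        slopes, pops = _run_habituation(session, classes, windows, gow_times, out)
        summary["population_slope_p"] = pops

    if "decode" in cfg.stages and draws is not None and len(draws) >= cfg.decoding.folds * 2:
        result = _run_decode(session, draws, cfg, out)
        summary["peak_decode_accuracy"] = float(result.accuracy.max())
        summary["decode_chance"] = result.chance

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    report = [f"whiskvr pipeline summary (seed {cfg.seed})"]
    for k, v in sorted(summary.items()):
        report.append(f"  {k}: {v}")
    (out / "report.txt").write_text("\n".join(report) + "\n")
    return summary
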