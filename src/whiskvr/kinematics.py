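"""Whisker kinematics from labelled point tracks.

Angle is measured per labelled point with reference to a fixed face point,
relative to the image's vertical axis (0 deg = vertically above the face
point, positive rostral).  The angle is band-pass filtered 1-30 Hz
(4th-order Butterworth, zero-phase) before phase extraction; whisker bend
is the signed Menger curvature of the three distal labels, and its
derivative is the local slope of a cubic least-squares fit in a moving
100 ms window (a Savitzky-Golay first derivative).  Touch onsets are
detected from curvature-derivative excursions against a robust (MAD-based)
spread estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "KinematicsError",
    "whisker_angle",
    "bandpass_angle",
    "menger_curvature",
    "curvature_derivative",
    "whisk_phase",
    "detect_touch",
    "compute_kinematics",
    "TouchConfig",
]


class KinematicsError(ValueError):
    """Raised on invalid kinematic inputs or configuration."""


# ---------------------------------------------------------------------------
# angle

def whisker_angle(tracks: pd.DataFrame, face_point: tuple[float, float]) -> pd.DataFrame:
    """Per-frame, per-whisker angle (degrees) from labelled points.

    Returns a frame-indexed DataFrame with one column per whisker holding
    the mean-of-labels angle; frames with no labels for a whisker are NaN.
    """
    xf, yf = face_point
    df = tracks.copy()
    df["angle"] = point_angle(df["x_px"].to_numpy(float), df["y_px"].to_numpy(float), xf, yf)
    wide = df.groupby(["frame", "whisker_id"])["angle"].mean().unstack("whisker_id")
    full = wide.reindex(np.arange(int(tracks["frame"].max()) + 1 if len(tracks) else 0))
    full.index.name = "frame"
    return full


def point_angle(x: np.ndarray, y: np.ndarray, xf: float, yf: float) -> np.ndarray:
    """Angle of points about the face point, degrees; 0 = vertically above,
    positive toward rostral (+x)."""
    return np.degrees(np.arctan2(x - xf, yf - y))


# ---------------------------------------------------------------------------
# filtering

def bandpass_angle(angle: np.ndarray, frame_rate: float, low: float = 1.0,
                   high: float = 30.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass of the whisker angle.

    Forward-backward application removes filter delay so event timing is
    unbiased; DC is rejected by the band.  NaN gaps shorter than 20 ms are
    bridged by linear interpolation; longer gaps stay NaN and split the
    trace into independently filtered segments.
    """
    angle = np.asarray(angle, dtype=float)
    if angle.ndim != 1:
        raise KinematicsError("angle trace must be one-dimensional")
    min_len = 3 * (order + 1)
    if np.sum(np.isfinite(angle)) < min_len:
        raise KinematicsError(f"trace shorter than {min_len} valid samples")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=frame_rate, output="sos")
    filled = _bridge_gaps(angle, max_gap=int(round(0.02 * frame_rate)))
    out = np.full_like(filled, np.nan)
    for start, stop in _finite_segments(filled):
        if stop - start >= min_len:
            out[start:stop] = signal.sosfiltfilt(sos, filled[start:stop])
    return out


def _bridge_gaps(x: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate NaN runs of at most ``max_gap`` samples."""
    x = x.copy()
    isnan = ~np.isfinite(x)
    if not isnan.any():
        return x
    idx = np.arange(len(x))
    for start, stop in _runs(isnan):
        if stop - start <= max_gap and start > 0 and stop < len(x):
            x[start:stop] = np.interp(idx[start:stop], [start - 1, stop],
                                      [x[start - 1], x[stop]])
    return x


def _runs(mask: np.ndarray):
    d = np.diff(mask.astype(int), prepend=0, append=0)
    return zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1))


def _finite_segments(x: np.ndarray):
    return _runs(np.isfinite(x))


# ---------------------------------------------------------------------------
# curvature

def menger_curvature(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed Menger curvature of point triples.

    ``|k| = 4 * Area(p1, p2, p3) / (|p1p2| |p2p3| |p1p3|)`` equals the
    inverse circumradius of the triple; the sign is that of the z component
    of ``(p2 - p1) x (p3 - p2)``.  Accepts single points (shape ``(2,)``)
    or stacked arrays (shape ``(n, 2)``); collinear triples give 0.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    a = p2 - p1
    b = p3 - p2
    c = p3 - p1
    la = np.linalg.norm(a, axis=-1)
    lb = np.linalg.norm(b, axis=-1)
    lc = np.linalg.norm(c, axis=-1)
    if np.any(la == 0) or np.any(lb == 0) or np.any(lc == 0):
        raise KinematicsError("coincident points have undefined curvature")
    cross = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return 2.0 * cross / (la * lb * lc)


def whisker_curvature(tracks: pd.DataFrame, px_per_mm: float = 20.0) -> pd.DataFrame:
    """Per-frame signed curvature (1/mm) from the three distal labels."""
    distal = tracks[tracks["label_index"] >= tracks["label_index"].max() - 2]
    out = {}
    n_frames = int(tracks["frame"].max()) + 1 if len(tracks) else 0
    for wid, grp in distal.groupby("whisker_id"):
        wide = grp.pivot_table(index="frame", columns="label_index", values=["x_px", "y_px"])
        labels = sorted({c[1] for c in wide.columns})
        pts = [np.column_stack([wide[("x_px", l)], wide[("y_px", l)]]) for l in labels[:3]]
        kappa = np.full(n_frames, np.nan)
        valid = np.all([np.isfinite(p).all(axis=1) for p in pts], axis=0)
        idx = wide.index.to_numpy()[valid]
        kappa[idx] = menger_curvature(pts[0][valid], pts[1][valid], pts[2][valid]) * px_per_mm
        out[wid] = kappa
    df = pd.DataFrame(out)
    df.index.name = "frame"
    return df


# ---------------------------------------------------------------------------
# curvature derivative

def curvature_derivative(kappa: np.ndarray, frame_rate: float,
                         window: float = 0.1) -> np.ndarray:
    """Local slope of a cubic fit to the curvature in a moving window.

    At each frame the first derivative at the window centre of a cubic
    polynomial least-squares fit to ``kappa`` within a centred ``window``
    seconds (Savitzky-Golay first derivative, polynomial order 3); edge
    frames use truncated least-squares windows.
    """
    kappa = np.asarray(kappa, dtype=float)
    w = int(round(window * frame_rate))
    if w % 2 == 0:
        w += 1
    if w < 5:
        raise KinematicsError("derivative window must span at least 4 samples")
    dt = 1.0 / frame_rate
    out = np.full_like(kappa, np.nan)
    for start, stop in _finite_segments(kappa):
        seg = kappa[start:stop]
        if len(seg) < 5:
            continue
        ww = min(w, len(seg) if len(seg) % 2 else len(seg) - 1)
        d = signal.savgol_filter(seg, ww, polyorder=3, deriv=1, delta=dt, mode="interp")
        half = ww // 2
        # truncated-window fits at the edges
        for i in range(half):
            for idx, sl in ((i, slice(0, i + half + 1)),
                            (len(seg) - 1 - i, slice(len(seg) - i - half - 1, len(seg)))):
                xs = (np.arange(sl.start, sl.stop) - idx) * dt
                coef = np.polynomial.polynomial.polyfit(xs, seg[sl], min(3, len(xs) - 1))
                d[idx] = coef[1]
        out[start:stop] = d
    return out


# ---------------------------------------------------------------------------
# phase

def whisk_phase(filtered_angle: np.ndarray, var_tol: float = 1e-6,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous whisk phase and protraction mask from the analytic signal.

    Phase is in ``(-pi, pi]`` with 0 at rostral (protracted) peaks;
    protraction — the half-cycle of increasing angle toward rostral — is
    the phase interval ``(-pi, 0)``.  Near-constant input yields NaN phase
    and an all-false mask rather than an exception.
    """
    x = np.asarray(filtered_angle, dtype=float)
    phase = np.full_like(x, np.nan)
    for start, stop in _finite_segments(x):
        seg = x[start:stop]
        if len(seg) < 3 or np.var(seg) < var_tol:
            continue
        phase[start:stop] = np.angle(signal.hilbert(seg))
    protraction = (phase > -np.pi) & (phase < 0)
    return phase, protraction


# ---------------------------------------------------------------------------
# touch detection

@dataclass
class TouchConfig:
    """Defaults tuned once against simulator ground truth and frozen."""

    k: float = 5.0           # threshold in robust s.d. units of |dkappa/dt|
    hold: float = 0.010      # s the curvature excursion must persist
    dead_time: float = 0.020  # s minimum separation between onsets


def detect_touch(kappa: np.ndarray, dkappa: np.ndarray, frame_rate: float,
                 cfg: TouchConfig | None = None,
                 phase: np.ndarray | None = None) -> pd.DataFrame:
    """Detect touch onsets from curvature-derivative excursions.

    A candidate is a region where ``|dkappa/dt|`` exceeds ``k`` robust
    standard deviations (1.4826 x median absolute deviation, dominated by
    the no-contact portion of the trace).  The onset is refined to the
    frame where the curvature excursion away from its median first crosses
    its own robust threshold — the curvature rise is much sharper than the
    smoothed derivative — and is kept only if the excursion persists at
    least ``hold`` seconds and the 30 ms before the onset were below
    threshold (rejecting contact *releases*).  Onsets closer than
    ``dead_time`` are merged.  Returns frame, time_s, phase_at_onset and a
    detection score (peak threshold multiple).
    """
    cfg = cfg or TouchConfig()
    kappa = np.asarray(kappa, dtype=float)
    dk = np.asarray(dkappa, dtype=float)
    if len(kappa) == 0 or not np.isfinite(kappa).any():
        raise KinematicsError("empty kinematic series")
    finite = np.isfinite(dk)
    mad = np.median(np.abs(dk[finite] - np.median(dk[finite]))) if finite.any() else 0.0
    spread = 1.4826 * mad
    if spread == 0 or not np.isfinite(cfg.k):
        return pd.DataFrame(columns=["frame", "time_s", "phase_at_onset", "score"])
    thresh = cfg.k * spread
    above = finite & (np.abs(dk) > thresh)

    k_med = np.nanmedian(kappa)
    k_spread = 1.4826 * np.nanmedian(np.abs(kappa - k_med))
    hold_frames = max(1, int(round(cfg.hold * frame_rate)))
    dead_frames = max(1, int(round(cfg.dead_time * frame_rate)))

    excursion = np.abs(kappa - k_med) > 3.0 * k_spread
    pre_frames = max(1, int(round(0.03 * frame_rate)))
    onsets, scores = [], []
    last = -dead_frames - 1
    for start, stop in _runs(above):
        seg_end = min(len(kappa), stop + 4 * hold_frames)
        rise = np.flatnonzero(excursion[start:seg_end])
        if len(rise) == 0:
            continue
        onset = start + rise[0]
        if onset - last < dead_frames:
            continue
        # the excursion must persist: a contiguous >= hold run shortly after onset
        look = excursion[onset:onset + 4 * hold_frames]
        if not any(e - s >= hold_frames for s, e in _runs(look)):
            continue
        pre = excursion[max(0, onset - pre_frames):onset]
        if len(pre) and pre.mean() > 0.5:
            continue
        onsets.append(onset)
        scores.append(float(np.nanmax(np.abs(dk[start:stop])) / thresh))
        last = onset
    out = pd.DataFrame({
        "frame": onsets,
        "time_s": np.asarray(onsets, dtype=float) / frame_rate,
        "phase_at_onset": (phase[onsets] if phase is not None and len(onsets)
                           else np.full(len(onsets), np.nan)),
        "score": scores,
    })
    return out


# ---------------------------------------------------------------------------
# full series

def compute_kinematics(tracks: pd.DataFrame, face_point: tuple[float, float],
                       frame_rate: float, px_per_mm: float = 20.0) -> pd.DataFrame:
    """All kinematic series in long form.

    Columns: frame, whisker_id, angle, filtered_angle, curvature,
    dkappa_dt, phase, protraction.
    """
    angles = whisker_angle(tracks, face_point)
    curv = whisker_curvature(tracks, px_per_mm=px_per_mm)
    recs = []
    for wid in angles.columns:
        a = angles[wid].to_numpy()
        filt = bandpass_angle(a, frame_rate)
        kappa = curv[wid].to_numpy() if wid in curv else np.full_like(a, np.nan)
        dk = curvature_derivative(kappa, frame_rate)
        phase, prot = whisk_phase(filt)
        recs.append(pd.DataFrame({
            "frame": angles.index, "whisker_id": wid, "angle": a,
            "filtered_angle": filt, "curvature": kappa, "dkappa_dt": dk,
            "phase": phase, "protraction": prot,
        }))
    return pd.concat(recs, ignore_index=True)
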