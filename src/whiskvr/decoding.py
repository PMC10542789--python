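"""Time-resolved population decoding of surface location.

Per-neuron spike rates in 150 ms bins, evaluated every 20 ms across the
peri-movement epoch (bins overlap between successive prediction times),
feed a linear one-vs-rest maximum-margin classifier.  Features are
z-scored with statistics fit on the training split only.  Accuracy is the
held-out zero-one loss, averaged over stratified 10-fold cross-validation
and 50 resample runs (each resample re-randomizes the fold assignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

__all__ = ["DecodingConfig", "DecodingResult", "DecodingError",
           "feature_matrix", "zscore_features", "cross_validated_decode",
           "subpopulation_decode"]


class DecodingError(ValueError):
    """Raised on invalid decoding inputs."""


@dataclass
class DecodingConfig:
    bin_width: float = 0.15       # s
    step: float = 0.02            # s between prediction times
    folds: int = 10
    resamples: int = 50
    epoch: tuple[float, float] = (-1.0, 2.0)   # relative to movement onset
    C: float = 1.0                # margin regularization constant

    def validate(self) -> None:
        if self.folds < 2:
            raise DecodingError("need at least 2 folds")
        if self.step > self.bin_width:
            raise DecodingError("prediction step must not exceed the bin width")
        if self.bin_width <= 0 or self.step <= 0:
            raise DecodingError("bin width and step must be positive")

    @property
    def prediction_times(self) -> np.ndarray:
        half = self.bin_width / 2
        return np.arange(self.epoch[0] + half, self.epoch[1] - half + 1e-12, self.step)


@dataclass
class DecodingResult:
    times: np.ndarray             # prediction times, s relative to onset
    accuracy: np.ndarray          # mean zero-one accuracy per time
    sem: np.ndarray               # s.e.m. over resamples
    chance: float                 # 1 / n_classes
    classes: list = field(default_factory=list)


def feature_matrix(spike_trains: dict[int, np.ndarray], onsets: np.ndarray,
                   cfg: DecodingConfig) -> np.ndarray:
    """(n_times, n_trials, n_neurons) firing rates in sliding 150 ms bins.

    For each prediction time t the bin is ``[t - w/2, t + w/2)`` relative
    to each trial onset; successive bins overlap, so a spike can appear in
    several of them.  Prediction times whose bin would leave the epoch are
    a configuration error (the default grid never does).
    """
    cfg.validate()
    onsets = np.asarray(onsets, dtype=float)
    times = cfg.prediction_times
    half = cfg.bin_width / 2
    if times[0] - half < cfg.epoch[0] - 1e-9 or times[-1] + half > cfg.epoch[1] + 1e-9:
        raise DecodingError("prediction bins extend beyond the peri-movement epoch")
    ids = sorted(spike_trains)
    out = np.zeros((len(times), len(onsets), len(ids)))
    for k, nid in enumerate(ids):
        st = np.sort(np.asarray(spike_trains[nid], dtype=float))
        for j, t0 in enumerate(onsets):
            lo = np.searchsorted(st, t0 + times - half, side="left")
            hi = np.searchsorted(st, t0 + times + half, side="left")
            out[:, j, k] = (hi - lo) / cfg.bin_width
    return out


def zscore_features(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score per neuron with statistics from the training split only.

    Zero-variance neurons pass through as zero columns in both splits.
    """
    if train.shape[0] == 0:
        raise DecodingError("training split is empty")
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    ok = sd > 1e-12 * np.maximum(1.0, np.abs(mu))
    safe = np.where(ok, sd, 1.0)
    tr = np.where(ok, (train - mu) / safe, 0.0)
    te = np.where(ok, (test - mu) / safe, 0.0)
    return tr, te


def _check_class_counts(labels: np.ndarray, folds: int) -> None:
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise DecodingError("need at least 2 classes")
    for c, n in zip(classes, counts):
        if n < folds:
            raise DecodingError(f"class {c!r} has {n} trials, fewer than {folds} folds")


def cross_validated_decode(features: np.ndarray, labels: np.ndarray,
                           cfg: DecodingConfig, seed: int = 0) -> DecodingResult:
    """Stratified k-fold, resampled, time-resolved decoding accuracy.

    ``features`` is the (n_times, n_trials, n_neurons) array from
    :func:`feature_matrix`.  Each resample draws a fresh stratified fold
    assignment from the seed; accuracy is averaged over folds within a
    resample and the s.e.m. is taken over resamples.  Ties in the
    one-vs-rest decision values are broken by the lowest class index.
    """
    cfg.validate()
    labels = np.asarray(labels)
    _check_class_counts(labels, cfg.folds)
    n_times, n_trials, _ = features.shape
    rng = np.random.default_rng(seed)
    acc = np.zeros((cfg.resamples, n_times))
    for r in range(cfg.resamples):
        skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        correct = np.zeros(n_times)
        for train_idx, test_idx in skf.split(np.zeros(n_trials), labels):
            for ti in range(n_times):
                xtr, xte = zscore_features(features[ti, train_idx],
                                           features[ti, test_idx])
                clf = LinearSVC(C=cfg.C)
                clf.fit(xtr, labels[train_idx])
                correct[ti] += np.sum(clf.predict(xte) == labels[test_idx])
        acc[r] = correct / n_trials
    mean = acc.mean(axis=0)
    sem = (acc.std(axis=0, ddof=1) / np.sqrt(cfg.resamples) if cfg.resamples > 1
           else np.zeros(n_times))
    classes = sorted(np.unique(labels).tolist())
    return DecodingResult(times=cfg.prediction_times, accuracy=mean, sem=sem,
                          chance=1.0 / len(classes), classes=classes)


def subpopulation_decode(spike_trains: dict[int, np.ndarray], onsets: np.ndarray,
                         labels: np.ndarray, classification: dict[int, str],
                         cfg: DecodingConfig, seed: int = 0,
                         ) -> dict[str, DecodingResult]:
    """Independent decodes for transient and sustained subpopulations.

    Both subpopulations are decoded with identical trial splits (shared
    seed) so their accuracy curves are directly comparable.
    """
    groups: dict[str, dict[int, np.ndarray]] = {"transient": {}, "sustained": {}}
    for nid, lab in classification.items():
        if lab in ("transient", "both"):
            groups["transient"][nid] = spike_trains[nid]
        if lab in ("sustained", "both"):
            groups["sustained"][nid] = spike_trains[nid]
    results = {}
    for name, trains in groups.items():
        if not trains:
            raise DecodingError(f"subpopulation {name!r} is empty")
        feats = feature_matrix(trains, onsets, cfg)
        results[name] = cross_validated_decode(feats, labels, cfg, seed=seed)
    return results
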