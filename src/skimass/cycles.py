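"""IMU cycle detection, sub-technique classification, and cycle kinematics.

Skating movement cycles are detected from the mediolateral acceleration of a
chest-worn IMU: the signal is Gaussian-smoothed and a cycle starts where the
upper body is at its leftmost position with the lowest (most negative
leftward) acceleration, i.e. at each prominent local minimum.  Consecutive
minima delimit cycles.  Each cycle window is reduced to a fixed-length
feature vector and classified into the skating gears G2, G3, G4 or Other
(downhill tuck, transitions, breaks, not-skiing) with an RBF support-vector
machine.  Cycle length (CL) and cycle rate (CR) follow from the boundaries
and the belt speed: CL = v̄·Δt, CR = 60/Δt, so CL·CR = 60·v̄ identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import joblib
import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .streams import SensorStream

GEARS = ("G2", "G3", "G4", "Other")
N_SHAPE_POINTS = 30  # per-axis time-normalized profile length
FEATURE_LENGTH = 3 * N_SHAPE_POINTS + 4  # 3 profiles + duration + 3 variances

__all__ = [
    "GEARS",
    "FEATURE_LENGTH",
    "CycleRecord",
    "GearModel",
    "detect_cycles",
    "extract_features",
    "features_for_cycles",
    "train_gear_model",
    "classify",
    "cycle_kinematics",
    "gear_per_second",
]


@dataclass
class CycleRecord:
    """One detected movement cycle."""

    t_start: float
    t_end: float
    gear: str = "Other"
    cl: float = np.nan  # m
    cr: float = np.nan  # cycles/min
    lap: int = 0
    segment: str = ""

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def detect_cycles(
    imu: SensorStream,
    smoothing_sigma: float = 0.1,
    min_period: float = 0.8,
    prominence: float = 0.5,
    channel: str = "acc_y",
) -> list[tuple[float, float]]:
    """Detect cycle boundaries from the mediolateral IMU channel.

    The channel is smoothed with a Gaussian kernel (``smoothing_sigma`` in
    seconds, default 0.1 s) and local minima at least ``min_period`` apart
    (default 0.8 s, i.e. at most 75 cycles/min) with at least ``prominence``
    m/s² of prominence are taken as cycle starts; leftward acceleration is
    negative by convention, so only minima below zero qualify.  Consecutive
    minima delimit cycles.

    Returns a list of (t_start, t_end) pairs on the master timeline; empty
    for streams shorter than 2 s or without qualifying minima.
    """
    if channel not in imu.channels:
        raise KeyError(f"channel {channel!r} missing from {imu.instrument} stream")
    y = np.asarray(imu[channel], dtype=float)
    if y.size / imu.rate < 2.0:
        return []
    smooth = gaussian_filter1d(y, sigma=smoothing_sigma * imu.rate)
    idx, _ = find_peaks(
        -smooth, distance=max(1, int(round(min_period * imu.rate))), prominence=prominence
    )
    idx = idx[smooth[idx] < 0.0]
    if idx.size < 2:
        return []
    t = imu.t0_offset + idx / imu.rate
    return list(zip(t[:-1], t[1:]))


def extract_features(
    window: np.ndarray, rate: float
) -> np.ndarray:
    """Fixed-length feature vector for one cycle window.

    ``window`` is an (n, 3) array of the accelerometer axes over one cycle.
    Each axis is time-normalized to ``N_SHAPE_POINTS`` samples and scaled by
    its in-window standard deviation (shape is amplitude-invariant); the raw
    per-axis variances and the cycle duration are appended, so an
    amplitude-doubled window changes only the variance features (×4).
    """
    window = np.asarray(window, dtype=float)
    n = window.shape[0]
    if n < 2:
        raise ValueError("degenerate cycle window")
    duration = n / rate
    grid = np.linspace(0.0, 1.0, N_SHAPE_POINTS)
    src = np.linspace(0.0, 1.0, n)
    parts = []
    variances = []
    for ax in range(3):
        sig = window[:, ax]
        sd = sig.std()
        variances.append(sd**2)
        shape = np.interp(grid, src, sig / sd if sd > 0 else sig)
        parts.append(shape)
    return np.concatenate(parts + [[duration], variances])


def features_for_cycles(
    imu: SensorStream,
    boundaries: Sequence[tuple[float, float]],
    channels: tuple[str, str, str] = ("acc_x", "acc_y", "acc_z"),
) -> np.ndarray:
    """Feature matrix for a list of cycle boundaries."""
    acc = np.column_stack([np.asarray(imu[c], dtype=float) for c in channels])
    rows = []
    for t0, t1 in boundaries:
        i0 = int(round((t0 - imu.t0_offset) * imu.rate))
        i1 = int(round((t1 - imu.t0_offset) * imu.rate))
        rows.append(extract_features(acc[i0:i1], imu.rate))
    return np.asarray(rows)


@dataclass
class GearModel:
    """Trained sub-technique classifier (feature scaling + RBF SVM)."""

    pipeline: Pipeline
    classes: tuple[str, ...]
    n_features: int

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "GearModel":
        model = joblib.load(path)
        if not isinstance(model, GearModel):
            raise TypeError(f"{path} does not contain a GearModel")
        return model


def train_gear_model(
    features: np.ndarray, labels: Sequence[str], seed: int = 0
) -> GearModel:
    """Train the gear classifier on labelled cycle features.

    Requires at least two distinct classes; all labels must belong to
    ``GEARS``.  The model is deterministic given ``seed`` and invariant to
    the order of the training rows.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    unknown = set(labels) - set(GEARS)
    if unknown:
        raise ValueError(f"unknown gear labels: {sorted(unknown)}")
    if len(set(labels)) < 2:
        raise ValueError("training data must contain at least two classes")
    order = np.lexsort(features.T[::-1])  # canonical row order
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf", C=10.0, gamma="scale", random_state=seed)),
        ]
    )
    pipe.fit(features[order], labels[order])
    return GearModel(
        pipeline=pipe,
        classes=tuple(pipe.named_steps["svm"].classes_),
        n_features=features.shape[1],
    )


def classify(model: GearModel, features: np.ndarray) -> np.ndarray:
    """Predict the gear of each feature row."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {features.shape[1]}"
        )
    return model.pipeline.predict(features)


def cycle_kinematics(
    boundaries: Sequence[tuple[float, float]],
    speed_ms: Callable[[float], float] | np.ndarray,
    speed_t0: float = 0.0,
) -> list[tuple[float, float]]:
    """Cycle length (m) and rate (cycles/min) for each boundary pair.

    ``speed_ms`` is either a callable t → belt speed (m/s) or a 1-Hz array of
    speeds starting at ``speed_t0``.  The mean speed over each cycle span is
    used, so CL·CR = 60·v̄ holds exactly.
    """
    out = []
    arr = None if callable(speed_ms) else np.asarray(speed_ms, dtype=float)
    for t0, t1 in boundaries:
        dur = t1 - t0
        if dur <= 0:
            raise ValueError("zero-duration cycle")
        if arr is None:
            mids = np.linspace(t0, t1, 21)
            v = float(np.mean([speed_ms(t) for t in mids]))
        else:
            i0 = int(np.floor(t0 - speed_t0))
            i1 = max(i0 + 1, int(np.ceil(t1 - speed_t0)))
            v = float(arr[max(i0, 0) : i1].mean())
        out.append((v * dur, 60.0 / dur))
    return out


def gear_per_second(
    records: Sequence[CycleRecord], t_grid: np.ndarray
) -> np.ndarray:
    """Per-second gear labels: the gear of the cycle covering each second.

    A second is attributed to the cycle containing its midpoint; seconds not
    covered by any cycle are 'Other'.
    """
    labels = np.full(len(t_grid), "Other", dtype=object)
    if not records:
        return labels
    starts = np.array([r.t_start for r in records])
    ends = np.array([r.t_end for r in records])
    mids = np.asarray(t_grid, dtype=float) + 0.5
    idx = np.searchsorted(starts, mids, side="right") - 1
    ok = (idx >= 0) & (mids < ends[np.clip(idx, 0, len(ends) - 1)])
    for i in np.nonzero(ok)[0]:
        labels[i] = records[idx[i]].gear
    return labels
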