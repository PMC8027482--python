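"""End-to-end processing of one trial: streams in, master timeline out.

Thin orchestration over the stage modules: detect cycles on the IMU,
classify them with a gear model (trained here from ground-truth labels, or
supplied), derive CL/CR from the belt-speed schedule, decompose power where
force and marker streams exist, and fuse everything at 1 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cycles as cyc
from . import metabolism, power, timeline
from .protocol import ProtocolSpec
from .synthesize import GroundTruth
from .streams import SensorStream

__all__ = ["TrialResult", "label_cycles_from_truth", "process_trial", "decompose_trial"]


@dataclass
class TrialResult:
    records: list
    master: pd.DataFrame
    model: cyc.GearModel
    decompositions: list | None = None


def label_cycles_from_truth(
    boundaries: list[tuple[float, float]], truth: GroundTruth
) -> np.ndarray:
    """Gear labels for detected cycles: the true gear at each cycle midpoint.

    Detected cycles whose midpoint falls outside any true cycle (breaks,
    downhill, transitions) are labelled 'Other'.
    """
    tc = truth.cycles
    labels = np.full(len(boundaries), "Other", dtype=object)
    if len(tc) == 0:
        return labels
    starts = tc["t_start"].to_numpy()
    ends = tc["t_end"].to_numpy()
    gears = tc["gear"].to_numpy()
    for i, (t0, t1) in enumerate(boundaries):
        mid = 0.5 * (t0 + t1)
        j = np.searchsorted(starts, mid, side="right") - 1
        if j >= 0 and mid < ends[j]:
            labels[i] = gears[j]
    return labels


def _belt_speed_fn(schedule: pd.DataFrame):
    t = schedule["t"].to_numpy(dtype=float)
    v = schedule["speed_kmh"].to_numpy(dtype=float) / 3.6

    def speed(ts: float) -> float:
        i = int(np.clip(np.floor(ts - t[0]), 0, len(v) - 1))
        return float(v[i])

    return speed


def process_trial(
    spec: ProtocolSpec,
    streams: dict,
    truth: GroundTruth,
    model: cyc.GearModel | None = None,
    tte: float | None = None,
    hrmax: float | None = None,
    vo2max: float | None = None,
    mass: float | None = None,
) -> TrialResult:
    """Run the full pipeline on one trial's streams.

    If no gear model is given, one is trained on this trial's detected
    cycles labelled from ground truth (self-training); for held-out
    evaluation pass a model trained on a different seed.
    """
    imu = streams["imu"]
    boundaries = cyc.detect_cycles(imu)
    feats = cyc.features_for_cycles(imu, boundaries)
    if model is None:
        labels = label_cycles_from_truth(boundaries, truth)
        model = cyc.train_gear_model(feats, labels)
    predicted = cyc.classify(model, feats) if len(boundaries) else np.array([])
    speed = _belt_speed_fn(truth.schedule)
    kin = cyc.cycle_kinematics(boundaries, speed)
    ip_end = spec.initial_duration
    records = []
    for (t0, t1), gear, (cl, cr) in zip(boundaries, predicted, kin):
        if t0 < 0 or t0 >= ip_end + (tte or 1e12):
            continue
        lap = int(t0 // spec.lap_duration) + 1 if t0 < ip_end else spec.laps + 1
        seg = spec.segment_at(t0)[1].label if t0 < ip_end else "AOS"
        records.append(
            cyc.CycleRecord(t_start=t0, t_end=t1, gear=gear, cl=cl, cr=cr,
                            lap=lap, segment=seg)
        )
    decomps = None
    if "pole_force" in streams and "markers" in streams and mass is not None:
        decomps = decompose_trial(streams, records, mass, schedule=truth.schedule)
    use_tte = tte if tte is not None else float(truth.schedule["t"].iloc[-1]) + 1 - ip_end
    master = timeline.build_master(
        spec, streams, records, tte=use_tte, hrmax=hrmax, vo2max=vo2max,
        decompositions=decomps,
    )
    return TrialResult(records=records, master=master, model=model,
                       decompositions=decomps)


def decompose_trial(
    streams: dict,
    records: list,
    mass: float,
    spec: ProtocolSpec | None = None,
    schedule: pd.DataFrame | None = None,
) -> list:
    """Per-cycle pole/ski power decomposition from force + marker streams.

    Returns one :class:`skimass.power.PowerDecomposition` (or None when the
    cycle lies outside the marker window) per cycle record.
    """
    mstream: SensorStream = streams["markers"]
    rate = mstream.rate
    markers = {k: power.lowpass(np.asarray(v, dtype=float), rate)
               for k, v in mstream.channels.items()}
    com = power.compute_com(markers, mass)
    v_com = power.com_velocity(com, rate)
    tip_l = markers["pole_tip_l"]
    force = streams["pole_force"]
    filtered = SensorStream(
        force.instrument, force.rate, force.t0_offset,
        {k: power.lowpass(np.asarray(v, dtype=float), force.rate)
         for k, v in force.channels.items()},
    )
    _, aligned = power.align_streams(
        filtered, tip_l[:, 2], kin_rate=rate, kin_t0=mstream.t0_offset
    )
    p_side = {}
    for side in ("l", "r"):
        fvec = power.pole_force_vector(
            aligned[f"force_{side}"], markers[f"pole_handle_{side}"],
            markers[f"pole_tip_{side}"],
        )
        p_side[side] = power.pole_power(fvec, v_com)
    t0 = mstream.t0_offset
    t_end = t0 + mstream.duration
    out = []
    for r in records:
        if r.t_start < t0 or r.t_end > t_end or r.gear not in ("G2", "G3", "G4"):
            out.append(None)
            continue
        v_mean = r.cl * r.cr / 60.0
        incline = _incline_at(schedule, spec, r.t_start)
        p_cycle = metabolism.external_work_rate(mass, incline, v_mean)
        out.append(
            power.decompose_cycle(
                r.t_start, r.t_end, p_side["l"], p_side["r"], rate, t0, p_cycle
            )
        )
    return out


def _incline_at(schedule, spec, t):
    if schedule is not None:
        i = int(np.clip(t - schedule["t"].iloc[0], 0, len(schedule) - 1))
        return float(schedule["incline_pct"].iloc[i])
    if spec is not None:
        return spec.incline_at(t)
    raise ValueError("need schedule or spec for incline lookup")
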