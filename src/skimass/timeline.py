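"""Fusion of all sensor streams onto a common 1-Hz master timeline.

Every stream is reduced to 1-Hz resolution by averaging the samples falling
in each second (after applying its clock offset); 10-s mixing-chamber oxygen
values are step-held across the ten seconds they cover.  NIRS tissue
saturation is special-cased: 1-s dropouts are first filled with the mean of
the two neighbouring values, and the 1-Hz values are means over three
seconds to remove any residual gaps.  The fused table carries per-second
belt speed, incline, lap and segment from the protocol, gear / cycle length
/ cycle rate / power split from the covering movement cycle, and the
relative intensities against personal maxima.  Missing values stay missing
(NaN), never zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cycles import CycleRecord, gear_per_second
from .protocol import ProtocolSpec
from .streams import SensorStream

__all__ = [
    "resample_1hz",
    "clean_nirs",
    "build_master",
    "laps_mean",
    "aos_first_steps_mean",
]

MASTER_COLUMNS = [
    "t", "speed_kmh", "incline_pct", "lap", "segment", "phase",
    "hr_bpm", "pct_hrmax", "vo2_ml_kg_min", "pct_vo2max",
    "tsi_leg", "tsi_arm", "gear", "cl_m", "cr_cpm",
    "p_cycle_w", "pct_pole", "pct_ski", "pct_pole_left", "pct_pole_right",
]


def resample_1hz(
    stream: SensorStream,
    channel: str,
    t_grid: np.ndarray,
    offset: float | None = None,
) -> np.ndarray:
    """Reduce one channel to 1-Hz values on ``t_grid`` (integer seconds).

    For rates ≥ 1 Hz each output value is the mean of the samples in
    [t, t+1); seconds containing no sample are NaN.  For rates below 1 Hz
    (10-s oxygen values) each sample is step-held across the seconds of its
    bin, since the fused table must carry a value each second.
    """
    t_grid = np.asarray(t_grid)
    values = np.asarray(stream[channel], dtype=float)
    t0 = stream.t0_offset if offset is None else offset
    times = t0 + np.arange(len(values)) / stream.rate
    out = np.full(len(t_grid), np.nan)
    if stream.rate >= 1.0:
        sec = np.floor(times).astype(int)
        base = int(t_grid[0])
        idx = sec - base
        ok = (idx >= 0) & (idx < len(t_grid)) & np.isfinite(values)
        sums = np.bincount(idx[ok], weights=values[ok], minlength=len(t_grid))
        counts = np.bincount(idx[ok], minlength=len(t_grid))
        nz = counts > 0
        out[nz] = sums[nz] / counts[nz]
    else:
        hold = 1.0 / stream.rate
        for tv, v in zip(times, values):
            i0 = int(np.floor(tv - t_grid[0]))
            i1 = int(np.floor(tv + hold - t_grid[0]))
            lo, hi = max(i0, 0), min(i1, len(t_grid))
            if hi > lo:
                out[lo:hi] = v
    return out


def clean_nirs(
    stream: SensorStream, channel: str, t_grid: np.ndarray
) -> np.ndarray:
    """Gap-filled, 3-s-averaged 1-Hz tissue saturation.

    Dropouts of at most one second are replaced by the mean of the two
    neighbouring valid samples; the stream is then reduced to 1 Hz and
    smoothed with a centred 3-s moving mean, which removes any residual 1-s
    gaps.  Gaps longer than one second remain missing.
    """
    values = np.asarray(stream[channel], dtype=float).copy()
    max_gap = int(round(stream.rate))  # samples in one second
    isnan = np.isnan(values)
    if isnan.any():
        idx = np.nonzero(isnan)[0]
        runs = np.split(idx, np.nonzero(np.diff(idx) > 1)[0] + 1)
        for run in runs:
            lo, hi = run[0] - 1, run[-1] + 1
            if len(run) <= max_gap and lo >= 0 and hi < len(values):
                values[run] = 0.5 * (values[lo] + values[hi])
    filled = SensorStream(stream.instrument, stream.rate, stream.t0_offset,
                          {channel: values})
    at_1hz = resample_1hz(filled, channel, t_grid)
    out = (
        pd.Series(at_1hz)
        .rolling(window=3, center=True, min_periods=2)
        .mean()
        .to_numpy()
    )
    # a second whose source samples were all part of a >1-s gap stays missing
    out[np.isnan(at_1hz) & np.isnan(pd.Series(at_1hz).ffill(limit=1).to_numpy())] = np.nan
    return out


def build_master(
    spec: ProtocolSpec,
    streams: dict,
    records: list[CycleRecord],
    tte: float,
    hrmax: float | None = None,
    vo2max: float | None = None,
    decompositions: list | None = None,
) -> pd.DataFrame:
    """Fuse streams and classified cycles into the 1-Hz master table.

    Covers [0, IP end + tte).  ``records`` are classified cycles with CL/CR;
    ``decompositions`` optionally pairs each record with a
    :class:`skimass.power.PowerDecomposition` (or None) to fill the power
    columns.  Personal maxima fill the relative-intensity columns; if
    omitted, the observed maxima of the trial are used for HR (the personal
    maximum is by definition the highest value measured at any time).
    """
    ip_end = spec.initial_duration
    n = int(np.floor(ip_end + tte))
    t = np.arange(n)
    rows = {
        "t": t,
        "speed_kmh": [spec.speed_at(s) for s in t],
        "incline_pct": [spec.incline_at(s) for s in t],
        "lap": [spec.segment_at(s)[0] if s < ip_end else spec.laps + 1 for s in t],
        "segment": [
            spec.segment_at(s)[1].label if s < ip_end else "AOS" for s in t
        ],
        "phase": np.where(t < ip_end, "ip", "aos"),
    }
    df = pd.DataFrame(rows)

    if any(r1.t_start < r0.t_end for r0, r1 in zip(records, records[1:])):
        raise ValueError("overlapping cycles")

    if "hr" in streams:
        df["hr_bpm"] = resample_1hz(streams["hr"], "hr_bpm", t)
        personal = hrmax if hrmax is not None else np.nanmax(df["hr_bpm"])
        df["pct_hrmax"] = df["hr_bpm"] / personal * 100.0
    else:
        df["hr_bpm"] = np.nan
        df["pct_hrmax"] = np.nan
    if "vo2" in streams:
        df["vo2_ml_kg_min"] = resample_1hz(streams["vo2"], "vo2_ml_kg_min", t)
        if vo2max is not None:
            df["pct_vo2max"] = df["vo2_ml_kg_min"] / vo2max * 100.0
        else:
            df["pct_vo2max"] = np.nan
    else:
        df["vo2_ml_kg_min"] = np.nan
        df["pct_vo2max"] = np.nan
    if "nirs" in streams:
        df["tsi_leg"] = clean_nirs(streams["nirs"], "tsi_leg", t)
        df["tsi_arm"] = clean_nirs(streams["nirs"], "tsi_arm", t)
    else:
        df["tsi_leg"] = np.nan
        df["tsi_arm"] = np.nan

    df["gear"] = gear_per_second(records, t)
    for col in ("cl_m", "cr_cpm", "p_cycle_w", "pct_pole", "pct_ski",
                "pct_pole_left", "pct_pole_right"):
        df[col] = np.nan
    if records:
        starts = np.array([r.t_start for r in records])
        ends = np.array([r.t_end for r in records])
        mids = t + 0.5
        idx = np.searchsorted(starts, mids, side="right") - 1
        ok = (idx >= 0) & (mids < ends[np.clip(idx, 0, len(ends) - 1)])
        for i in np.nonzero(ok)[0]:
            r = records[idx[i]]
            df.loc[i, "cl_m"] = r.cl
            df.loc[i, "cr_cpm"] = r.cr
            if decompositions is not None and decompositions[idx[i]] is not None:
                d = decompositions[idx[i]]
                df.loc[i, "p_cycle_w"] = d.p_cycle
                df.loc[i, "pct_pole"] = d.pct_pole
                df.loc[i, "pct_ski"] = d.pct_ski
                df.loc[i, "pct_pole_left"] = d.pct_pole_left
                df.loc[i, "pct_pole_right"] = d.pct_pole_right
    return df[MASTER_COLUMNS]


def laps_mean(master: pd.DataFrame, column: str, laps=(1, 2, 3)) -> float:
    """Mean of a column over the given initial-part laps (default laps 1-3,
    the window that includes every skier regardless of breaks)."""
    sel = master[(master["phase"] == "ip") & (master["lap"].isin(laps))]
    return float(sel[column].mean())


def aos_first_steps_mean(
    master: pd.DataFrame, spec: ProtocolSpec, column: str, n_steps: int = 3
) -> float:
    """Mean of a column over the first ``n_steps`` sprint speed steps."""
    ip_end = spec.initial_duration
    horizon = ip_end + n_steps * spec.aos_step_duration
    sel = master[(master["t"] >= ip_end) & (master["t"] < horizon)]
    return float(sel[column].mean())
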