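"""Synthetic multi-sensor roller-ski trials with known ground truth.

Generates the full instrument bundle of one simulated mass-start — chest IMU
(256 Hz accelerometer/gyroscope, 64 Hz barometer), per-pole axial force
(100 Hz), reflective-marker positions (200 Hz), heart rate (1 Hz), 10-s
mixing-chamber oxygen uptake, and 10-Hz NIRS tissue saturation — together
with a ground-truth sidecar (cycle boundaries, gear labels, metabolic demand,
per-cycle pole-power fraction) so that every downstream stage can be tested
by parameter recovery without any recorded data.

The generator emulates the statistical structure the analysis relies on, not
biomechanical fidelity: gear-specific quasi-periodic sway with one
mediolateral minimum per cycle, bell-shaped pole-force impulses exceeding
10 N only during ground contact, markers rigidly attached to a
centre-of-mass trajectory whose forward speed equals belt speed (the
treadmill belt is "un-rolled" into a ground-fixed frame), first-order VO2/HR
kinetics driven by the work-rate demand, a linear lap-to-lap HR drift, and
arm-specific NIRS desaturation drift.  Every random element is drawn from a
seeded generator, so identical (protocol, profile, seed) gives identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from . import metabolism
from .protocol import ProtocolSpec, aos_speed_at, build_protocol
from .streams import SensorStream

__all__ = [
    "SkierProfile",
    "NoiseConfig",
    "GroundTruth",
    "CYCLE_PERIOD_S",
    "SEGMENT_GEAR",
    "build_schedule",
    "generate_imu",
    "generate_breath_series",
    "generate_nirs",
    "generate_force_and_markers",
    "generate_trial",
    "generate_ge_bout",
    "cohort_profiles",
]

# Gear chosen on each segment of the track (downhill is a tuck: no cycles).
SEGMENT_GEAR = {"S1": "G3", "S2": "G4", "S3": "G2", "S4": "Other"}
# Movement-cycle period per gear, seconds.  Chosen so cycle rates fall in the
# observed 29-36 cycles/min band for G3 at sprint speeds, with the uphill
# gear quicker and the flat gear slower.
CYCLE_PERIOD_S = {"G2": 1.6, "G3": 1.9, "G4": 2.2}

# Familiarization-lap speeds (low intensity), km/h per segment label.
_FAMILIARIZATION_SPEEDS = {"S1": 14.0, "S2": 20.0, "S3": 8.0, "S4": 22.0}

# Oxygen demand (mL·min⁻¹·kg⁻¹) for non-propulsive states.
_DEMAND_TUCK = 20.0
_DEMAND_BREAK = 15.0
_DEMAND_REST = 6.0

# HR demand is soft-capped at this fraction of the oxygen reserve so the
# injected linear drift is not truncated by the personal maximum during the
# steep-uphill seconds (identifiability of the lap-drift statistic).
_HR_DEMAND_CAP = 0.85


@dataclass(frozen=True)
class SkierProfile:
    """Per-skier physiology and trial outcome parameters."""

    skier_id: str = "S01"
    mass: float = 79.3  # kg
    vo2max: float = 69.5  # mL·min⁻¹·kg⁻¹
    hrmax: float = 193.5  # beats·min⁻¹
    hr_rest: float = 45.0
    ge_by_gear: dict = field(
        default_factory=lambda: {"G2": 17.0, "G3": 15.0, "G4": 12.5}
    )
    vo2_tau: float = 25.0  # s, first-order time constant
    hr_tau: float = 20.0  # s
    hr_drift: float = 7.9  # pp of HRmax, lap 7 minus lap 2
    tsi_arm_drift: float = -3.0  # pp, lap 7 minus lap 2
    tsi_leg_drift: float = 0.0
    break_times: tuple = ()  # s since IP start
    tte: float = 130.0  # s in the AOS
    pole_fraction: float = 0.60  # of cycle work rate
    pole_left_share: float = 0.50  # of pole power
    rer: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be > 0")
        if self.vo2_tau <= 0 or self.hr_tau <= 0:
            raise ValueError("time constants must be > 0")
        for gear, ge in self.ge_by_gear.items():
            if not (0 < ge < 30):
                raise ValueError(f"ge_by_gear[{gear}] outside (0, 30)")


@dataclass(frozen=True)
class NoiseConfig:
    """Additive Gaussian noise SDs per channel family."""

    imu: float = 0.3  # m/s^2
    force: float = 2.0  # N
    marker: float = 0.002  # m
    hr: float = 1.0  # bpm
    vo2: float = 1.0  # mL·min⁻¹·kg⁻¹ per 10-s bin
    tsi: float = 0.5  # pp
    baro: float = 0.1  # hPa

    @classmethod
    def zero(cls) -> "NoiseConfig":
        return cls(imu=0.0, force=0.0, marker=0.0, hr=0.0, vo2=0.0, tsi=0.0, baro=0.0)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    schedule: pd.DataFrame  # per-second: t, phase, lap, segment, speed, incline, gear
    cycles: pd.DataFrame  # per cycle: t_start, t_end, gear (strictly increasing)
    demand_vo2: np.ndarray  # mL·min⁻¹·kg⁻¹ at 1 Hz over the schedule span
    demand_hr: np.ndarray  # bpm at 1 Hz
    ge_by_gear: dict
    hr_drift: float
    tsi_arm_drift: float
    cycle_power: pd.DataFrame | None = None  # per-cycle true power split

    @property
    def boundaries(self) -> np.ndarray:
        """Sorted union of cycle start/end instants."""
        return np.unique(
            np.concatenate([self.cycles["t_start"], self.cycles["t_end"]])
        )

    @property
    def gears(self) -> np.ndarray:
        return self.cycles["gear"].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        """Write the sidecar (schedule + cycles) as two plain CSVs."""
        path = Path(path)
        self.schedule.to_csv(path.with_suffix(".schedule.csv"), index=False)
        self.cycles.to_csv(path.with_suffix(".cycles.csv"), index=False)


def build_schedule(
    spec: ProtocolSpec,
    profile: SkierProfile,
    include_familiarization: bool = True,
) -> pd.DataFrame:
    """Per-second trial schedule on the master timeline.

    t = 0 at the start of the mass-start initial part.  If familiarization is
    included, it occupies the 21 min before a 5-min standing recovery that
    ends at t = 0.  Columns: t, phase (familiarization / recovery / ip /
    aos), lap, segment, speed_kmh, incline_pct, gear.  Breaks override the
    gear to 'Other' for 30-s windows while belt speed continues.
    """
    ip_end = spec.initial_duration
    if profile.tte < 0:
        raise ValueError("tte must be >= 0")
    rows = []
    t_start = -(spec.initial_duration + 300.0) if include_familiarization else 0.0
    for t in range(int(t_start), int(np.ceil(ip_end + profile.tte))):
        if t < -300:
            tf = t - t_start
            lap, seg = spec.segment_at(tf)
            speed = _FAMILIARIZATION_SPEEDS.get(seg.label, seg.speed)
            rows.append((t, "familiarization", lap, seg.label, speed, seg.incline,
                         SEGMENT_GEAR.get(seg.label, "Other")))
        elif t < 0:
            rows.append((t, "recovery", 0, "", 0.0, 0.0, "Other"))
        elif t < ip_end:
            lap, seg = spec.segment_at(t)
            rows.append((t, "ip", lap, seg.label, seg.speed, seg.incline,
                         SEGMENT_GEAR.get(seg.label, "Other")))
        else:
            speed = aos_speed_at(spec, t - ip_end)
            rows.append((t, "aos", spec.laps + 1, "AOS", speed, spec.aos_incline, "G3"))
    df = pd.DataFrame(
        rows,
        columns=["t", "phase", "lap", "segment", "speed_kmh", "incline_pct", "gear"],
    )
    for bt in profile.break_times:
        if not (0 <= bt < ip_end):
            raise ValueError(f"break time {bt:g} outside the initial part")
        mask = (df["t"] >= bt) & (df["t"] < bt + spec.break_duration)
        df.loc[mask, "gear"] = "Other"
    return df


def _gear_bouts(schedule: pd.DataFrame) -> list[tuple[float, float, str]]:
    """Contiguous same-gear runs of G2/G3/G4 as (t0, t1, gear)."""
    bouts = []
    gears = schedule["gear"].to_numpy()
    ts = schedule["t"].to_numpy(dtype=float)
    start = None
    for i in range(len(schedule)):
        g = gears[i]
        if start is None:
            if g != "Other":
                start = i
        elif g != gears[start]:
            bouts.append((ts[start], ts[i - 1] + 1.0, gears[start]))
            start = i if g != "Other" else None
    if start is not None:
        bouts.append((ts[start], ts[-1] + 1.0, gears[start]))
    return bouts


def _truth_cycles(schedule: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth cycles (t_start, t_end, gear) from the schedule.

    Within each skiing bout cycles are contiguous with the gear's period;
    any partial remainder at the end of a bout is not a cycle.
    """
    rows = []
    for t0, t1, gear in _gear_bouts(schedule):
        period = CYCLE_PERIOD_S[gear]
        n = int(np.floor((t1 - t0) / period))
        for k in range(n):
            rows.append((t0 + k * period, t0 + (k + 1) * period, gear))
    return pd.DataFrame(rows, columns=["t_start", "t_end", "gear"])


# Per-gear harmonic signatures of the forward (x) and vertical (z)
# accelerometer axes: (amplitude, cycles-per-cycle, phase) terms.  The
# mediolateral axis is common to all gears (one minimum per cycle); the x/z
# mixes and the distinct cycle periods separate the classes.
_GEAR_XZ = {
    "G2": (((1.5, 1, 0.0), (1.2, 2, 0.7)), ((1.0, 1, 1.2), (0.5, 3, 0.4))),
    "G3": (((2.0, 2, 0.3),), ((1.5, 2, 1.0), (0.6, 1, 2.0))),
    "G4": (((1.1, 1, 2.1), (0.7, 3, 0.9)), ((1.6, 1, 0.5),)),
}
_SWAY_AMPLITUDE = 2.0  # m/s^2 on the mediolateral axis


def _other_wobble(rng: np.random.Generator, n: int, rate: float, sd: float = 0.8):
    """Aperiodic low-frequency wobble for non-skiing spans."""
    if n == 0:
        return np.zeros(0)
    x = rng.standard_normal(n)
    x = gaussian_filter1d(x, sigma=0.35 * rate, mode="nearest")
    s = x.std()
    return x / s * sd if s > 0 else x


def generate_imu(
    schedule: pd.DataFrame,
    noise: NoiseConfig,
    seed: int,
    rate: float = 256.0,
) -> tuple[SensorStream, pd.DataFrame]:
    """Chest-IMU stream plus ground-truth cycle boundaries and gear labels.

    The mediolateral channel (acc_y) of each skiing bout is a cosine with one
    minimum per cycle at the leftmost position (leftward acceleration
    negative); forward/vertical axes carry gear-specific harmonic mixes.
    Non-skiing spans (downhill tuck, breaks, rest) are aperiodic wobble.
    Gyroscope channels mirror the accelerometer harmonics and the barometric
    channel is generated separately (different rate).
    """
    rng = np.random.default_rng(seed)
    unknown = set(schedule["gear"]) - {"G2", "G3", "G4", "Other"}
    if unknown:
        raise ValueError(f"unknown gear labels: {sorted(unknown)}")
    t0 = float(schedule["t"].iloc[0])
    t_end = float(schedule["t"].iloc[-1]) + 1.0
    n = int(round((t_end - t0) * rate))
    t = t0 + np.arange(n) / rate
    acc_x = np.zeros(n)
    acc_y = np.zeros(n)
    acc_z = np.zeros(n)
    covered = np.zeros(n, dtype=bool)
    for b0, b1, gear in _gear_bouts(schedule):
        sl = slice(int(round((b0 - t0) * rate)), int(round((b1 - t0) * rate)))
        tau = t[sl] - b0
        period = CYCLE_PERIOD_S[gear]
        acc_y[sl] = -_SWAY_AMPLITUDE * np.cos(2 * np.pi * tau / period)
        xs, zs = _GEAR_XZ[gear]
        for amp, mult, ph in xs:
            acc_x[sl] += amp * np.sin(2 * np.pi * mult * tau / period + ph)
        for amp, mult, ph in zs:
            acc_z[sl] += amp * np.sin(2 * np.pi * mult * tau / period + ph)
        covered[sl] = True
    for ax in (acc_x, acc_y, acc_z):
        idx = np.nonzero(~covered)[0]
        if idx.size:
            # fill each uncovered run with independent aperiodic wobble
            splits = np.split(idx, np.nonzero(np.diff(idx) > 1)[0] + 1)
            for run in splits:
                ax[run] = _other_wobble(rng, run.size, rate)
    acc_z += 9.81
    channels = {
        "acc_x": acc_x + rng.normal(0, noise.imu, n) if noise.imu else acc_x,
        "acc_y": acc_y + rng.normal(0, noise.imu, n) if noise.imu else acc_y,
        "acc_z": acc_z + rng.normal(0, noise.imu, n) if noise.imu else acc_z,
        "gyr_x": 0.5 * acc_y + (rng.normal(0, noise.imu, n) if noise.imu else 0.0),
        "gyr_y": 0.4 * acc_x + (rng.normal(0, noise.imu, n) if noise.imu else 0.0),
        "gyr_z": 0.3 * acc_z + (rng.normal(0, noise.imu, n) if noise.imu else 0.0),
    }
    stream = SensorStream("imu", rate, t0, channels)
    return stream, _truth_cycles(schedule)


def generate_baro(
    schedule: pd.DataFrame, noise: NoiseConfig, seed: int, rate: float = 64.0
) -> SensorStream:
    """Barometric pressure consistent with incline × speed altitude gain."""
    rng = np.random.default_rng(seed)
    v = schedule["speed_kmh"].to_numpy(dtype=float) / 3.6
    climb = v * schedule["incline_pct"].to_numpy(dtype=float) / 100.0  # m/s
    alt = np.concatenate([[0.0], np.cumsum(climb)])
    t0 = float(schedule["t"].iloc[0])
    n = int(round(len(schedule) * rate))
    tt = np.arange(n) / rate
    alt_hi = np.interp(tt, np.arange(len(alt)), alt)
    pressure = 1013.25 * np.exp(-alt_hi / 8434.0)
    if noise.baro:
        pressure = pressure + rng.normal(0, noise.baro, n)
    return SensorStream("baro", rate, t0, {"pressure_hpa": pressure})


def _demand_vo2(schedule: pd.DataFrame, profile: SkierProfile) -> np.ndarray:
    """Per-second oxygen demand (mL·min⁻¹·kg⁻¹) from the work-rate schedule."""
    out = np.empty(len(schedule))
    for i, row in enumerate(schedule.itertuples(index=False)):
        if row.gear in profile.ge_by_gear:
            p = metabolism.external_work_rate(
                profile.mass, row.incline_pct, row.speed_kmh / 3.6
            )
            vo2_lmin = metabolism.vo2_for_power(
                p, profile.ge_by_gear[row.gear], profile.rer
            )
            out[i] = vo2_lmin * 1000.0 / profile.mass
        elif row.phase in ("ip", "aos"):
            out[i] = _DEMAND_BREAK if row.phase == "ip" and row.segment != "S4" else _DEMAND_TUCK
        elif row.phase == "familiarization":
            out[i] = _DEMAND_TUCK if row.segment == "S4" else _DEMAND_TUCK
        else:
            out[i] = _DEMAND_REST
    return np.minimum(out, profile.vo2max)


def _first_order(demand: np.ndarray, tau: float, v0: float) -> np.ndarray:
    """Exact first-order response to a per-second piecewise-constant demand."""
    decay = np.exp(-1.0 / tau)
    out = np.empty_like(demand)
    v = v0
    for i, d in enumerate(demand):
        v = d + (v - d) * decay
        out[i] = v
    return out


def _drift_term(
    schedule: pd.DataFrame, total_pp: float, spec: ProtocolSpec
) -> np.ndarray:
    """Linear drift reaching ``total_pp`` between the lap-2 and lap-7 means.

    Zero before the IP, linear in time during it, frozen afterwards.  With a
    slope of total/((laps−2)·lap) the difference between the last-lap and
    lap-2 means equals ``total_pp`` exactly.
    """
    t = schedule["t"].to_numpy(dtype=float)
    span = (spec.laps - 2) * spec.lap_duration
    if span <= 0:
        return np.zeros(len(t))
    slope = total_pp / span
    return slope * np.clip(t, 0.0, spec.initial_duration)


def generate_breath_series(
    spec: ProtocolSpec,
    profile: SkierProfile,
    schedule: pd.DataFrame,
    noise: NoiseConfig,
    seed: int,
) -> tuple[SensorStream, SensorStream, np.ndarray, np.ndarray]:
    """VO2 (10-s mixing chamber) and HR (1 Hz) streams with known demand.

    Measured VO2 follows first-order kinetics towards the work-rate demand
    (dV/dt = (demand − V)/τ) and is binned into 10-s means; HR follows the
    same kinetics on the heart-rate reserve plus a linear lap-to-lap drift.
    Values never exceed the profile maxima.

    Returns (vo2 stream, hr stream, per-second demand VO2, demand HR).
    """
    rng = np.random.default_rng(seed)
    demand = _demand_vo2(schedule, profile)
    vo2 = _first_order(demand, profile.vo2_tau, _DEMAND_REST)
    n10 = len(vo2) // 10
    vo2_10s = vo2[: n10 * 10].reshape(n10, 10).mean(axis=1)
    if noise.vo2:
        vo2_10s = vo2_10s + rng.normal(0, noise.vo2, n10)
    vo2_10s = np.clip(vo2_10s, 0.0, profile.vo2max)
    t0 = float(schedule["t"].iloc[0])
    vo2_stream = SensorStream(
        "vo2",
        0.1,
        t0,
        {
            "vo2_ml_kg_min": vo2_10s,
            "vo2_l_min": vo2_10s * profile.mass / 1000.0,
            "rer": np.full(n10, profile.rer),
        },
    )
    frac = np.minimum(demand / profile.vo2max, _HR_DEMAND_CAP)
    hr_demand = profile.hr_rest + (profile.hrmax - profile.hr_rest) * frac
    hr_demand = hr_demand + _drift_term(
        schedule, profile.hr_drift / 100.0 * profile.hrmax, spec
    )
    hr = _first_order(hr_demand, profile.hr_tau, profile.hr_rest)
    if noise.hr:
        hr = hr + rng.normal(0, noise.hr, len(hr))
    hr = np.clip(hr, 30.0, profile.hrmax)
    hr_stream = SensorStream("hr", 1.0, t0, {"hr_bpm": hr})
    return vo2_stream, hr_stream, demand, hr_demand


def generate_nirs(
    spec: ProtocolSpec,
    profile: SkierProfile,
    schedule: pd.DataFrame,
    noise: NoiseConfig,
    seed: int,
    rate: float = 10.0,
    dropout_rate_per_min: float = 1.0,
) -> SensorStream:
    """10-Hz tissue-saturation streams for leg and arm.

    TSI is a baseline minus an intensity-proportional desaturation, smoothed
    with a short first-order response, plus a linear arm drift and slow
    fluctuation.  Dropouts of exactly 1 s (NaN) are injected at the given
    rate to exercise the gap-filling rule.
    """
    rng = np.random.default_rng(seed)
    demand = _demand_vo2(schedule, profile)
    frac = _first_order(demand / profile.vo2max, 8.0, 0.1)
    arm_drift = _drift_term(schedule, profile.tsi_arm_drift, spec)
    leg_drift = _drift_term(schedule, profile.tsi_leg_drift, spec)
    t0 = float(schedule["t"].iloc[0])
    n = int(round(len(schedule) * rate))
    tt = t0 + np.arange(n) / rate
    sec = np.arange(len(schedule), dtype=float)
    up = lambda x: np.interp(tt - t0, sec, x)
    tsi_leg = 68.0 - 12.0 * up(frac) + up(leg_drift) + 0.4 * np.sin(2 * np.pi * tt / 37.0)
    tsi_arm = 62.0 - 14.0 * up(frac) + up(arm_drift) + 0.4 * np.sin(2 * np.pi * tt / 29.0)
    if noise.tsi:
        tsi_leg = tsi_leg + rng.normal(0, noise.tsi, n)
        tsi_arm = tsi_arm + rng.normal(0, noise.tsi, n)
    if dropout_rate_per_min > 0:
        n_gaps = rng.poisson(dropout_rate_per_min * len(schedule) / 60.0)
        gap_samples = int(rate)
        for start in rng.integers(0, max(1, n - 3 * gap_samples), size=n_gaps):
            tsi_leg[start : start + gap_samples] = np.nan
            tsi_arm[start : start + gap_samples] = np.nan
    return SensorStream("nirs", rate, t0, {"tsi_leg": tsi_leg, "tsi_arm": tsi_arm})


# Rigid marker offsets from the CoM trajectory, metres (x forward, y left, z
# up).  Rigidity makes the segment-weighted CoM an exact translate of the
# true trajectory, so CoM velocity is recovered exactly.
_MARKER_OFFSETS = {
    "hip_l": (0.0, 0.12, -0.05),
    "hip_r": (0.0, -0.12, -0.05),
    "shoulder_l": (0.02, 0.18, 0.45),
    "shoulder_r": (0.02, -0.18, 0.45),
    "elbow_l": (0.10, 0.25, 0.15),
    "elbow_r": (0.10, -0.25, 0.15),
    "wrist_l": (0.30, 0.25, -0.10),
    "wrist_r": (0.30, -0.25, -0.10),
    "knee_l": (0.15, 0.15, -0.55),
    "knee_r": (0.15, -0.15, -0.55),
    "ankle_l": (0.10, 0.15, -0.95),
    "ankle_r": (0.10, -0.15, -0.95),
    "boot_l": (0.25, 0.15, -1.00),
    "boot_r": (0.25, -0.15, -1.00),
    "ski_front_l": (0.80, 0.15, -1.05),
    "ski_front_r": (0.80, -0.15, -1.05),
    "ski_rear_l": (-0.30, 0.15, -1.05),
    "ski_rear_r": (-0.30, -0.15, -1.05),
}

_POLE_LENGTH = 1.70
_CONTACT_PHASE = 0.15  # contact start, fraction of the cycle
_CONTACT_FRACTION = 0.35  # contact duration, fraction of the cycle
_THETA_SWING = np.deg2rad(15.0)
_THETA_CONTACT = (np.deg2rad(14.0), np.deg2rad(22.0))


def generate_force_and_markers(
    profile: SkierProfile,
    spec: ProtocolSpec,
    schedule: pd.DataFrame,
    noise: NoiseConfig,
    seed: int,
    t_span: tuple[float, float] | None = None,
    force_misalignment: float = 0.12,
    kin_rate: float = 200.0,
    force_rate: float = 100.0,
) -> tuple[SensorStream, SensorStream, pd.DataFrame]:
    """Pole-force streams, marker stream, and per-cycle power ground truth.

    Pole axial forces are half-sine impulses confined to ground contact
    (zero in the swing), scaled per cycle so that the cycle-average of
    F·V_CoM equals the profile's true pole fraction of the cycle work rate,
    split left/right by the asymmetry parameter.  Pole tip markers reach
    their vertical minimum exactly at contact onset, which defines the
    kinematic touchdown used for synchronization; the force stream's clock
    is skewed by ``force_misalignment`` seconds for the alignment stage to
    recover.

    Returns (force stream at 100 Hz, marker stream at 200 Hz, truth table
    with one row per cycle: t_start, t_end, gear, p_cycle, pole_fraction,
    left_share).
    """
    rng = np.random.default_rng(seed)
    if t_span is None:
        t_span = (0.0, float(schedule["t"].iloc[-1]) + 1.0)
    s0, s1 = t_span
    sub = schedule[(schedule["t"] >= s0) & (schedule["t"] < s1)].reset_index(drop=True)
    if sub.empty:
        raise ValueError("empty marker span")
    n = int(round((s1 - s0) * kin_rate))
    t = s0 + np.arange(n) / kin_rate

    # CoM trajectory: forward position integrates the per-second belt speed.
    v_sec = sub["speed_kmh"].to_numpy(dtype=float) / 3.6
    x_knots = np.concatenate([[0.0], np.cumsum(v_sec)])
    x = np.interp(t - s0, np.arange(len(x_knots)), x_knots)
    y = np.zeros(n)
    z = np.full(n, 1.05)
    cyc = [
        (row.t_start, row.t_end, row.gear)
        for row in _truth_cycles(sub).itertuples(index=False)
    ]
    for b0, b1, g in _gear_bouts(sub):
        sl = slice(int(round((b0 - s0) * kin_rate)), int(round((b1 - s0) * kin_rate)))
        tau = t[sl] - b0
        period = CYCLE_PERIOD_S[g]
        y[sl] = 0.08 * np.sin(2 * np.pi * tau / period)
        z[sl] = 1.05 + 0.04 * np.sin(4 * np.pi * tau / period)
    com = np.column_stack([x, y, z])
    v_com = np.gradient(com, 1.0 / kin_rate, axis=0)

    # Pole geometry: handle anchored ahead of the CoM at fixed height; the
    # shaft tilts forward-down so F·V_CoM is positive during contact.
    handle = {}
    tip = {}
    axial = {"l": np.zeros(n), "r": np.zeros(n)}
    theta = {}
    theta_knots: dict[str, tuple[list, list]] = {"l": ([], []), "r": ([], [])}
    for b0, b1, gear in cyc:
        period = b1 - b0
        for side in ("l", "r"):
            cs = b0 + _CONTACT_PHASE * period
            if gear == "G2" and side == "r":
                cs += 0.08 * period  # asymmetric poling
            cd = _CONTACT_FRACTION * period
            i0 = int(round((cs - s0) * kin_rate))
            i1 = int(round((cs + cd - s0) * kin_rate))
            i0, i1 = max(i0, 0), min(i1, n)
            if i1 <= i0:
                continue
            ph = (t[i0:i1] - cs) / cd
            axial[side][i0:i1] = np.sin(np.pi * ph)  # unit-amplitude impulse
            # shaft angle ramps forward during contact, eases back in swing;
            # the resulting tip height is a V with its minimum at touchdown
            theta_knots[side][0].extend([cs, cs + cd])
            theta_knots[side][1].extend(list(_THETA_CONTACT))
    for side in ("l", "r"):
        kt, kv = theta_knots[side]
        if kt:
            # ease down from the raised swing angle ahead of the first plant
            # so the first touchdown is a proper local minimum of tip height
            kt = [kt[0] - 0.6 * (kt[1] - kt[0]) / _CONTACT_FRACTION] + kt
            kv = [_THETA_CONTACT[1]] + kv
            theta[side] = np.interp(t, kt, kv)
        else:
            theta[side] = np.full(n, _THETA_SWING)
    unit = {}
    for side, sgn in (("l", 1.0), ("r", -1.0)):
        u = np.column_stack(
            [
                np.sin(theta[side]),
                np.full(n, 0.04 * sgn),
                -np.cos(theta[side]),
            ]
        )
        unit[side] = u / np.linalg.norm(u, axis=1, keepdims=True)
        handle[side] = np.column_stack(
            [x + 0.25, np.full(n, 0.30 * sgn), np.full(n, 1.25)]
        )
        tip[side] = handle[side] + _POLE_LENGTH * unit[side]

    # Scale each cycle's impulses so mean(F·V) over the cycle hits the target
    # pole power: truth fraction x cycle work rate, split by side share.
    truth_rows = []
    shares = {"l": profile.pole_left_share, "r": 1.0 - profile.pole_left_share}
    for b0, b1, gear in cyc:
        i0 = int(round((b0 - s0) * kin_rate))
        i1 = int(round((b1 - s0) * kin_rate))
        i0, i1 = max(i0, 0), min(i1, n)
        v_mean = float(np.mean(v_com[i0:i1, 0]))
        incline = float(sub.loc[int(np.clip(b0 - s0, 0, len(sub) - 1)), "incline_pct"])
        p_cycle = metabolism.external_work_rate(profile.mass, incline, v_mean)
        for side in ("l", "r"):
            p_unit = axial[side][i0:i1, None] * unit[side][i0:i1]
            m_unit = float(np.mean(np.einsum("ij,ij->i", p_unit, v_com[i0:i1])))
            target = profile.pole_fraction * p_cycle * shares[side]
            if m_unit > 1e-9:
                axial[side][i0:i1] *= target / m_unit
        truth_rows.append(
            {
                "t_start": b0,
                "t_end": b1,
                "gear": gear,
                "p_cycle": p_cycle,
                "pole_fraction": profile.pole_fraction,
                "left_share": profile.pole_left_share,
            }
        )

    markers = {}
    for name, off in _MARKER_OFFSETS.items():
        m = com + np.asarray(off)
        if noise.marker:
            m = m + rng.normal(0, noise.marker, m.shape)
        markers[name] = m
    for side, suffix in (("l", "_l"), ("r", "_r")):
        for name, arr in ((f"pole_handle{suffix}", handle[side]), (f"pole_tip{suffix}", tip[side])):
            markers[name] = arr + (
                rng.normal(0, noise.marker, arr.shape) if noise.marker else 0.0
            )
    marker_stream = SensorStream("markers", kin_rate, s0, markers)

    # Force stream on a skewed clock: the sample stamped t was physically
    # measured at t + misalignment.
    nf = int(round((s1 - s0) * force_rate))
    tf = s0 + np.arange(nf) / force_rate + force_misalignment
    fl = np.interp(tf, t, axial["l"])
    fr = np.interp(tf, t, axial["r"])
    if noise.force:
        fl = np.clip(fl + rng.normal(0, noise.force, nf), 0.0, None)
        fr = np.clip(fr + rng.normal(0, noise.force, nf), 0.0, None)
    force_stream = SensorStream("pole_force", force_rate, s0, {"force_l": fl, "force_r": fr})
    return force_stream, marker_stream, pd.DataFrame(truth_rows)


def generate_trial(
    spec: ProtocolSpec | None = None,
    profile: SkierProfile | None = None,
    noise: NoiseConfig | None = None,
    include_familiarization: bool = True,
    include_markers: bool = True,
    marker_span: tuple[float, float] | None = None,
) -> tuple[dict, GroundTruth]:
    """Generate the complete sensor bundle of one simulated mass-start trial.

    Returns ``(streams, truth)`` where ``streams`` maps instrument name →
    :class:`SensorStream` ('imu', 'baro', 'vo2', 'hr', 'nirs', and if
    requested 'pole_force' and 'markers').  Deterministic given the profile's
    seed.  ``marker_span`` limits the expensive 200-Hz marker generation to a
    sub-window of the mass-start (default: the whole IP + sprint).
    """
    spec = spec or build_protocol()
    profile = profile or SkierProfile()
    noise = noise if noise is not None else NoiseConfig()
    if profile.tte > 4 * spec.initial_duration:
        raise ValueError("tte exceeds the stream horizon")
    schedule = build_schedule(spec, profile, include_familiarization)
    seed = int(profile.seed) % (2**31)
    streams: dict[str, SensorStream] = {}
    imu, truth_cycles = generate_imu(schedule, noise, seed)
    streams["imu"] = imu
    streams["baro"] = generate_baro(schedule, noise, seed + 1)
    vo2_s, hr_s, demand_vo2, demand_hr = generate_breath_series(
        spec, profile, schedule, noise, seed + 2
    )
    streams["vo2"] = vo2_s
    streams["hr"] = hr_s
    streams["nirs"] = generate_nirs(spec, profile, schedule, noise, seed + 3)
    truth = GroundTruth(
        schedule=schedule,
        cycles=truth_cycles,
        demand_vo2=demand_vo2,
        demand_hr=demand_hr,
        ge_by_gear=dict(profile.ge_by_gear),
        hr_drift=profile.hr_drift,
        tsi_arm_drift=profile.tsi_arm_drift,
    )
    if include_markers:
        force, markers, cycle_power = generate_force_and_markers(
            profile, spec, schedule, noise, seed + 4, t_span=marker_span
        )
        streams["pole_force"] = force
        streams["markers"] = markers
        truth.cycle_power = cycle_power
    return streams, truth


def generate_ge_bout(
    profile: SkierProfile,
    gear: str,
    incline: float,
    speed_kmh: float,
    duration: float = 240.0,
    noise: NoiseConfig | None = None,
    seed: int | None = None,
) -> tuple[SensorStream, metabolism.BoutMeasurement]:
    """One constant-load submaximal bout for the efficiency protocol.

    Returns the 10-s VO2 stream (first-order kinetics from rest) and the
    :class:`BoutMeasurement` built from the last-minute mean, ready for
    :func:`skimass.metabolism.gross_efficiency`.
    """
    noise = noise if noise is not None else NoiseConfig()
    rng = np.random.default_rng(int(profile.seed if seed is None else seed) % (2**31))
    p = metabolism.external_work_rate(profile.mass, incline, speed_kmh / 3.6)
    demand_lmin = metabolism.vo2_for_power(p, profile.ge_by_gear[gear], profile.rer)
    demand = np.full(int(duration), demand_lmin * 1000.0 / profile.mass)
    vo2 = _first_order(demand, profile.vo2_tau, _DEMAND_REST)
    n10 = len(vo2) // 10
    vo2_10s = vo2[: n10 * 10].reshape(n10, 10).mean(axis=1)
    if noise.vo2:
        vo2_10s = vo2_10s + rng.normal(0, noise.vo2, n10)
    stream = SensorStream(
        "vo2", 0.1, 0.0,
        {"vo2_ml_kg_min": vo2_10s, "vo2_l_min": vo2_10s * profile.mass / 1000.0},
    )
    last_min = vo2_10s[-6:].mean() * profile.mass / 1000.0
    bout = metabolism.BoutMeasurement(
        gear=gear, incline=incline, speed=speed_kmh, vo2=float(last_min),
        rer=profile.rer, mass=profile.mass,
    )
    return stream, bout


def cohort_profiles(seed: int = 0, n: int = 13) -> list[SkierProfile]:
    """A cohort of plausible skier profiles spanning the observed outcome range.

    Breaks, TTE and efficiencies follow the per-skier study tables shipped
    with the package; physiology varies around the cohort means with the
    published SDs.
    """
    from . import fixtures

    rng = np.random.default_rng(seed)
    phys = fixtures.load_physiology()
    profiles = []
    for i in range(n):
        row = phys.iloc[i % len(phys)]
        breaks = int(row["breaks"])
        bt = tuple(300.0 + 250.0 * k for k in range(breaks))
        profiles.append(
            SkierProfile(
                skier_id=f"S{i + 1:02d}",
                mass=float(np.clip(rng.normal(79.3, 5.2), 60, 100)),
                vo2max=float(row["vo2max"]),
                hrmax=float(np.clip(rng.normal(193.5, 7.0), 170, 215)),
                ge_by_gear={
                    "G2": float(row["ge_g2"]),
                    "G3": float(row["ge_g3"]),
                    "G4": float(row["ge_g4"]),
                },
                break_times=bt,
                tte=float(row["tte_s"]),
                pole_fraction=float(np.clip(rng.normal(0.58, 0.05), 0.45, 0.72)),
                pole_left_share=float(np.clip(rng.normal(0.50, 0.03), 0.40, 0.60)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return profiles
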