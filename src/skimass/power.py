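"""Centre-of-mass kinematics and pole/ski power decomposition.

In skate skiing all propulsion comes from either the poles or the skis.  The
instantaneous pole power is the dot product of the 3-D pole force (axial
force along the pole shaft, oriented by the handle→tip marker pair) with the
centre-of-mass (CoM) velocity, computed independently per pole and summed.
The cycle work rate P_Cycle (gravity + rolling friction at the prescribed
incline and belt speed) minus the cycle-average pole power is attributed to
the skis: P_Ski = P_Cycle − P_Pole.  Percentages are expressed relative to
P_Cycle, and the left/right split relative to total pole power.

Conventions: coordinates are x forward, y left-positive, z up, in metres, in
a ground-fixed frame in which the skier advances at belt speed.  Marker and
force series are low-pass filtered (8th-order Butterworth, 15-Hz cut-off)
with zero phase lag before any differentiation.  Negative instantaneous pole
power is retained in cycle averages — clipping would break the
P_Cycle = P_Pole + P_Ski accounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .streams import SensorStream

__all__ = [
    "DE_LEVA_ADJUSTED_MALE",
    "PowerDecomposition",
    "lowpass",
    "compute_com",
    "com_velocity",
    "pole_force_vector",
    "pole_power",
    "align_streams",
    "decompose_cycle",
]

# Segment inertial parameters (adjusted male values after de Leva): mass
# fraction of whole-body mass and longitudinal CoM position as a fraction of
# the proximal→distal marker vector.  The head and trunk are treated as one
# segment bounded by the shoulder and hip midpoints; the hand is folded into
# the forearm (no hand marker in the set).  Virtual markers '*_mid' are the
# left/right means.  Fractions are renormalized at use, so a custom table
# (e.g. a two-segment toy body) is equally valid.
DE_LEVA_ADJUSTED_MALE: tuple[tuple[str, str, str, float, float], ...] = (
    # name, proximal marker, distal marker, mass fraction, CoM fraction
    ("trunk_head", "shoulder_mid", "hip_mid", 0.5046, 0.4486),
    ("thigh_l", "hip_l", "knee_l", 0.1416, 0.4095),
    ("thigh_r", "hip_r", "knee_r", 0.1416, 0.4095),
    ("shank_l", "knee_l", "ankle_l", 0.0433, 0.4459),
    ("shank_r", "knee_r", "ankle_r", 0.0433, 0.4459),
    ("foot_l", "ankle_l", "boot_l", 0.0137, 0.4415),
    ("foot_r", "ankle_r", "boot_r", 0.0137, 0.4415),
    ("upperarm_l", "shoulder_l", "elbow_l", 0.0271, 0.5772),
    ("upperarm_r", "shoulder_r", "elbow_r", 0.0271, 0.5772),
    ("forearm_hand_l", "elbow_l", "wrist_l", 0.0223, 0.6),
    ("forearm_hand_r", "elbow_r", "wrist_r", 0.0223, 0.6),
)


@dataclass
class PowerDecomposition:
    """Pole/ski split of the work rate for one movement cycle."""

    p_cycle: float  # W
    p_pole: float  # W, cycle-average summed over both poles
    p_ski: float  # W, residual
    pct_pole: float
    pct_ski: float
    pct_pole_left: float  # % of pole power
    pct_pole_right: float
    flag: str = ""


def lowpass(series: np.ndarray, rate: float, cutoff: float = 15.0, order: int = 8):
    """Zero-phase Butterworth low-pass (default 8th order, 15 Hz).

    Applied forward-backward so the passband has no phase lag.  The cut-off
    must be below the Nyquist frequency.
    """
    if cutoff >= rate / 2:
        raise ValueError(f"cutoff {cutoff:g} Hz >= Nyquist {rate / 2:g} Hz")
    series = np.asarray(series, dtype=float)
    sos = butter(order, cutoff, btype="low", fs=rate, output="sos")
    return sosfiltfilt(sos, series, axis=0)


def _resolve_marker(markers: dict, name: str) -> np.ndarray:
    if name in markers:
        return np.asarray(markers[name], dtype=float)
    if name.endswith("_mid"):
        base = name[: -len("_mid")]
        left, right = f"{base}_l", f"{base}_r"
        if left in markers and right in markers:
            return 0.5 * (
                np.asarray(markers[left], dtype=float)
                + np.asarray(markers[right], dtype=float)
            )
    raise KeyError(f"missing marker {name!r}")


def compute_com(
    markers: dict,
    mass: float,
    segment_table: tuple = DE_LEVA_ADJUSTED_MALE,
) -> np.ndarray:
    """Whole-body CoM position series from a marker dictionary.

    Each segment CoM lies at its CoM fraction along the proximal→distal
    marker vector; the body CoM is the mass-fraction-weighted mean.  ``mass``
    scales nothing here (fractions are relative) but is kept for interface
    symmetry with downstream dynamics.
    """
    if mass <= 0:
        raise ValueError("mass must be > 0")
    total = 0.0
    acc = None
    for _, prox_name, dist_name, frac, com_frac in segment_table:
        prox = _resolve_marker(markers, prox_name)
        dist = _resolve_marker(markers, dist_name)
        seg = prox + com_frac * (dist - prox)
        acc = frac * seg if acc is None else acc + frac * seg
        total += frac
    return acc / total


def com_velocity(com: np.ndarray, rate: float) -> np.ndarray:
    """CoM velocity by numerical differentiation (central differences)."""
    com = np.asarray(com, dtype=float)
    if com.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    return np.gradient(com, 1.0 / rate, axis=0)


def pole_force_vector(
    axial: np.ndarray, handle: np.ndarray, tip: np.ndarray
) -> np.ndarray:
    """3-D pole force: axial magnitude times the handle→tip unit vector."""
    axial = np.asarray(axial, dtype=float)
    handle = np.asarray(handle, dtype=float)
    tip = np.asarray(tip, dtype=float)
    shaft = tip - handle
    norm = np.linalg.norm(shaft, axis=-1)
    if np.any(norm < 1e-9):
        raise ValueError("zero-length pole vector")
    return axial[..., None] * shaft / norm[..., None]


def pole_power(force: np.ndarray, v_com: np.ndarray) -> np.ndarray:
    """Instantaneous pole power F·V for one pole, W."""
    force = np.asarray(force, dtype=float)
    v_com = np.asarray(v_com, dtype=float)
    if force.shape != v_com.shape:
        raise ValueError("force/velocity length mismatch")
    return np.einsum("ij,ij->i", force, v_com)


def align_streams(
    force: SensorStream,
    tip_z: np.ndarray,
    kin_rate: float,
    kin_t0: float,
    threshold: float = 10.0,
    channel: str = "force_l",
    depth_tol: float = 0.01,
) -> tuple[float, SensorStream]:
    """Synchronize the pole-force stream to the kinematic clock.

    The first pole touchdown is the first instant the axial force reaches the
    10-N threshold; on the kinematic side it is the first local minimum of
    the pole-tip height that comes within ``depth_tol`` metres of the global
    minimum (plant depths repeat every poling action, so the first such
    minimum is the first touchdown).  The force stream is shifted so the two
    coincide and resampled onto the kinematic clock by linear interpolation.

    Returns (offset applied in s, aligned force stream at ``kin_rate``).
    """
    from scipy.signal import find_peaks

    f = np.asarray(force[channel], dtype=float)
    above = np.nonzero(f >= threshold)[0]
    if above.size == 0:
        raise ValueError(f"no {threshold:g}-N crossing in {channel}")
    t_force = force.t0_offset + above[0] / force.rate

    tip_z = np.asarray(tip_z, dtype=float)
    margin = int(round(0.25 * kin_rate))  # skip filter-transient edges
    core = tip_z[margin : len(tip_z) - margin]
    zmin = core.min()
    minima, _ = find_peaks(-core)
    minima = minima[core[minima] <= zmin + depth_tol] + margin
    touch = minima[0] if minima.size else margin + int(np.argmin(core))
    t_kin = kin_t0 + touch / kin_rate

    offset = t_kin - t_force
    n_out = int(round(force.n_samples * kin_rate / force.rate))
    t_out = kin_t0 + np.arange(n_out) / kin_rate
    shifted = force.times() + offset
    channels = {
        name: np.interp(t_out, shifted, np.asarray(arr, dtype=float))
        for name, arr in force.channels.items()
    }
    aligned = SensorStream(
        instrument=force.instrument,
        rate=kin_rate,
        t0_offset=kin_t0,
        channels=channels,
    )
    return offset, aligned


def decompose_cycle(
    t_start: float,
    t_end: float,
    p_left: np.ndarray,
    p_right: np.ndarray,
    rate: float,
    t0: float,
    p_cycle: float,
) -> PowerDecomposition:
    """Decompose one cycle's work rate into pole and ski contributions.

    ``p_left``/``p_right`` are instantaneous per-pole power series on a
    common clock starting at ``t0`` with sampling rate ``rate``; ``p_cycle``
    is the external work rate over the cycle.  If ``p_cycle`` is not
    positive the percentages are undefined and flagged.
    """
    i0 = int(round((t_start - t0) * rate))
    i1 = int(round((t_end - t0) * rate))
    if i1 <= i0:
        raise ValueError("empty cycle span")
    pl = float(np.mean(p_left[i0:i1]))
    pr = float(np.mean(p_right[i0:i1]))
    p_pole = pl + pr
    p_ski = p_cycle - p_pole
    if p_cycle <= 0:
        return PowerDecomposition(
            p_cycle, p_pole, p_ski, np.nan, np.nan, np.nan, np.nan,
            flag="nonpositive work rate",
        )
    pct_pole = 100.0 * p_pole / p_cycle
    if p_pole != 0:
        left = 100.0 * pl / p_pole
    else:
        left = np.nan
    return PowerDecomposition(
        p_cycle=p_cycle,
        p_pole=p_pole,
        p_ski=p_ski,
        pct_pole=pct_pole,
        pct_ski=100.0 - pct_pole,
        pct_pole_left=left,
        pct_pole_right=100.0 - left if np.isfinite(left) else np.nan,
    )
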