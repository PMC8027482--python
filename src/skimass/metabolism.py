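"""External work rate, metabolic rate, gross efficiency and aerobic maxima.

Treadmill roller-skiing work rate is the sum of power against gravity,
``Pg = m·g·sin(α)·v``, and rolling friction, ``Pf = m·g·cos(α)·μ·v``, with the
treadmill angle α obtained from the percent grade as ``α = arctan(grade/100)``.
Metabolic rate is computed from oxygen uptake and the oxygen energy equivalent
selected by the respiratory exchange ratio (RER) from the standard nonprotein
respiratory-quotient table.  Gross efficiency (GE) is the ratio of the two, in
percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

G = 9.81  # m s^-2
DEFAULT_MU = 0.016  # rolling-friction coefficient of the roller skis

__all__ = [
    "WorkRateParams",
    "BoutMeasurement",
    "EfficiencyResult",
    "external_work_rate",
    "oxygen_energy_equivalent",
    "metabolic_rate",
    "vo2_for_power",
    "gross_efficiency",
    "aggregate_efficiency",
    "vo2max_from_series",
    "relative_intensity",
    "DEFAULT_MU",
    "G",
]

# Nonprotein respiratory-quotient energy equivalents of oxygen, kJ per litre
# O2 (classical table values; kcal rows x 4.184).  Linear interpolation
# between rows; RER is clamped to [0.70, 1.00] before lookup since values
# above 1.0 reflect non-metabolic CO2.
_RQ_TABLE = np.array(
    [
        [0.70, 19.606],
        [0.75, 19.828],
        [0.80, 20.087],
        [0.85, 20.343],
        [0.90, 20.602],
        [0.95, 20.857],
        [1.00, 21.117],
    ]
)


@dataclass(frozen=True)
class WorkRateParams:
    """Inputs of the treadmill work-rate formula."""

    mass: float  # kg
    grade: float  # percent, signed
    speed: float  # m/s
    mu: float = DEFAULT_MU
    g: float = G

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be > 0")
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")

    @property
    def alpha(self) -> float:
        """Treadmill angle in radians."""
        return float(np.arctan(self.grade / 100.0))

    @property
    def pg(self) -> float:
        """Power against gravity, W."""
        return self.mass * self.g * np.sin(self.alpha) * self.speed

    @property
    def pf(self) -> float:
        """Power against rolling friction, W."""
        return self.mass * self.g * np.cos(self.alpha) * self.mu * self.speed


def external_work_rate(
    mass: float, grade: float, speed: float, mu: float = DEFAULT_MU
) -> float:
    """Total external work rate ``Pg + Pf`` in W.

    Parameters
    ----------
    mass : float
        Skier mass in kg.
    grade : float
        Treadmill grade in percent (signed).
    speed : float
        Belt speed in m/s.
    mu : float
        Rolling-friction coefficient (default 0.016).
    """
    p = WorkRateParams(mass=mass, grade=grade, speed=speed, mu=mu)
    return float(p.pg + p.pf)


def oxygen_energy_equivalent(rer: float) -> float:
    """Energy equivalent of oxygen in kJ per litre O2 for a given RER.

    RER below 0.70 is physiologically implausible and raises; values above
    1.00 are clamped to 1.00.
    """
    if rer < 0.70:
        raise ValueError(f"rer={rer:g} below 0.70")
    rer = min(rer, 1.00)
    return float(np.interp(rer, _RQ_TABLE[:, 0], _RQ_TABLE[:, 1]))


def metabolic_rate(vo2: float, rer: float) -> float:
    """Metabolic rate in W from oxygen uptake (L·min⁻¹) and RER."""
    if vo2 <= 0:
        raise ValueError("vo2 must be > 0")
    return vo2 * oxygen_energy_equivalent(rer) * 1000.0 / 60.0


def vo2_for_power(power: float, ge_pct: float, rer: float) -> float:
    """Oxygen uptake (L·min⁻¹) required to sustain ``power`` W at a given GE.

    Inverse of ``gross_efficiency`` ∘ ``metabolic_rate``; used by the trial
    generator so that the efficiency computation round-trips exactly.
    """
    if ge_pct <= 0:
        raise ValueError("ge_pct must be > 0")
    mr = power / (ge_pct / 100.0)
    return mr * 60.0 / (oxygen_energy_equivalent(rer) * 1000.0)


@dataclass(frozen=True)
class BoutMeasurement:
    """Steady-state measurement of one submaximal exercise bout."""

    gear: str  # G2 / G3 / G4
    incline: float  # percent
    speed: float  # km/h
    vo2: float  # L·min⁻¹, last-minute mean
    rer: float
    mass: float  # kg
    mu: float = DEFAULT_MU

    def __post_init__(self) -> None:
        if self.vo2 <= 0:
            raise ValueError("vo2 must be > 0")
        if not (0.7 <= self.rer <= 1.3):
            raise ValueError("rer outside [0.7, 1.3]")


@dataclass(frozen=True)
class EfficiencyResult:
    """Per-bout, per-gear and overall gross efficiency in percent."""

    ge_per_bout: tuple[float, ...]
    ge_per_gear: dict
    ge_average: float
    n_bouts: int
    note: str = ""


def gross_efficiency(bout: BoutMeasurement) -> float:
    """Gross efficiency (%) of one bout: external work rate / metabolic rate."""
    work = external_work_rate(bout.mass, bout.incline, bout.speed / 3.6, bout.mu)
    met = metabolic_rate(bout.vo2, bout.rer)
    if met <= 0:
        raise ValueError("metabolic rate must be > 0")
    return 100.0 * work / met


def aggregate_efficiency(bouts: Sequence[BoutMeasurement]) -> EfficiencyResult:
    """Per-gear mean GE and the unweighted overall mean across bouts.

    The efficiency protocol prescribes 12 bouts (4 intensities x 3 gears); a
    skier may miss one, in which case the average covers 11 bouts and the
    result carries a provenance note.
    """
    if not bouts:
        raise ValueError("no bouts")
    ges = tuple(gross_efficiency(b) for b in bouts)
    per_gear: dict[str, float] = {}
    for gear in ("G2", "G3", "G4"):
        vals = [g for g, b in zip(ges, bouts) if b.gear == gear]
        if vals:
            per_gear[gear] = float(np.mean(vals))
    note = "" if len(bouts) >= 12 else f"average over {len(bouts)} bouts"
    return EfficiencyResult(
        ge_per_bout=ges,
        ge_per_gear=per_gear,
        ge_average=float(np.mean(ges)),
        n_bouts=len(bouts),
        note=note,
    )


def vo2max_from_series(vo2_10s: Iterable[float]) -> float:
    """VO2Max as the highest 30-s moving average of 10-s mixing-chamber values."""
    v = np.asarray(list(vo2_10s), dtype=float)
    if v.size < 3:
        raise ValueError("need at least three 10-s values")
    means = np.convolve(v, np.ones(3) / 3.0, mode="valid")
    return float(means.max())


def relative_intensity(series, personal_max: float):
    """Express a series as percent of a personal maximum."""
    if personal_max <= 0:
        raise ValueError("personal_max must be > 0")
    return np.asarray(series, dtype=float) / personal_max * 100.0
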