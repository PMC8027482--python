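"""Simulated mass-start protocol: track geometry, sprint speed schedule, ranking.

The simulated mass-start consists of an initial part (IP) of identical 3-min
laps skied at preset speeds on a terrain profile of four segments — moderate
uphill (S1), flat (S2), steep uphill (S3) and downhill (S4) — followed by an
incremental all-out sprint (AOS) at a fixed incline where belt speed increases
stepwise until exhaustion.  Skiers may take 30-s breaks during the IP while the
belt keeps running; performance rank is decided first by number of breaks, then
by time-to-exhaustion (TTE) in the AOS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import yaml

LAP_DURATION_S = 180.0

__all__ = [
    "TrackSegment",
    "ProtocolSpec",
    "SkierOutcome",
    "Ranking",
    "ProtocolError",
    "build_protocol",
    "aos_speed_at",
    "rank_skiers",
    "DEFAULT_CONFIG",
]


class ProtocolError(ValueError):
    """Raised for protocol configurations that violate the track invariants."""


@dataclass(frozen=True)
class TrackSegment:
    """One segment of a lap.

    Parameters
    ----------
    label : str
        Segment name (S1..S4).
    incline : float
        Treadmill grade in percent (signed; negative = downhill).
    speed : float
        Belt speed in km/h.
    duration : float
        Segment duration in seconds.
    """

    label: str
    incline: float
    speed: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ProtocolError(f"segment {self.label}: duration must be > 0")
        if self.speed < 0:
            raise ProtocolError(f"segment {self.label}: speed must be >= 0")


# Segment speeds of the high-intensity initial part are fixed by the protocol
# (S1 18, S2 24, S3 14 km/h).  Inclines and within-lap durations are config
# values chosen to match the gear-to-incline pairings of the efficiency
# protocol (G3 at 5%, G4 at 2%, G2 at 12%); they are configuration, not
# ground truth.  S4 is a downhill at negative grade.
DEFAULT_CONFIG: dict = {
    "laps": 7,
    "segments": [
        {"label": "S1", "incline": 5.0, "speed": 18.0, "duration": 60.0},
        {"label": "S2", "incline": 2.0, "speed": 24.0, "duration": 35.0},
        {"label": "S3", "incline": 12.0, "speed": 14.0, "duration": 45.0},
        {"label": "S4", "incline": -3.0, "speed": 26.0, "duration": 40.0},
    ],
    "aos": {
        "incline": 5.0,
        "start_speed": 20.0,
        "step": 1.0,
        "step_duration": 15.0,
    },
    "break_duration": 30.0,
}


@dataclass(frozen=True)
class ProtocolSpec:
    """Validated geometry of the simulated mass-start."""

    laps: int = 7
    segments: tuple[TrackSegment, ...] = ()
    aos_incline: float = 5.0
    aos_start_speed: float = 20.0
    aos_step: float = 1.0
    aos_step_duration: float = 15.0
    break_duration: float = 30.0

    def __post_init__(self) -> None:
        if self.laps < 1:
            raise ProtocolError("laps must be >= 1")
        if self.aos_step_duration <= 0:
            raise ProtocolError("aos_step_duration must be > 0")
        if not self.segments:
            raise ProtocolError("at least one segment required")
        total = sum(s.duration for s in self.segments)
        if not math.isclose(total, LAP_DURATION_S, abs_tol=1e-9):
            raise ProtocolError(
                f"segment durations sum to {total:g} s, expected {LAP_DURATION_S:g} s"
            )

    @property
    def lap_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    @property
    def initial_duration(self) -> float:
        """Duration of the initial part (all laps), in seconds."""
        return self.laps * self.lap_duration

    def segment_at(self, t: float) -> tuple[int, TrackSegment]:
        """Return (lap number 1-based, segment) at time ``t`` since IP start.

        ``t`` must lie within the initial part.
        """
        if t < 0 or t >= self.initial_duration:
            raise ProtocolError(f"t={t:g} s outside the initial part")
        lap = int(t // self.lap_duration) + 1
        within = t - (lap - 1) * self.lap_duration
        for seg in self.segments:
            if within < seg.duration:
                return lap, seg
            within -= seg.duration
        return lap, self.segments[-1]  # numerical edge

    def speed_at(self, t: float) -> float:
        """Belt speed (km/h) at time ``t`` since IP start (IP or AOS)."""
        if t < self.initial_duration:
            return self.segment_at(t)[1].speed
        return aos_speed_at(self, t - self.initial_duration)

    def incline_at(self, t: float) -> float:
        """Treadmill grade (%) at time ``t`` since IP start (IP or AOS)."""
        if t < self.initial_duration:
            return self.segment_at(t)[1].incline
        return self.aos_incline


def _merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def build_protocol(config: Mapping | str | Path | None = None) -> ProtocolSpec:
    """Build a validated :class:`ProtocolSpec` from a config mapping or YAML file.

    Missing keys fall back to the default mass-start geometry (seven 3-min
    laps; S1 18, S2 24, S3 14 km/h; AOS from 20 km/h with +1 km/h per 15 s).
    """
    if config is None:
        cfg = DEFAULT_CONFIG
    elif isinstance(config, (str, Path)):
        with open(config) as fh:
            loaded = yaml.safe_load(fh) or {}
        cfg = _merge(DEFAULT_CONFIG, loaded)
    else:
        cfg = _merge(DEFAULT_CONFIG, config)
    segments = tuple(
        TrackSegment(
            label=str(s["label"]),
            incline=float(s["incline"]),
            speed=float(s["speed"]),
            duration=float(s["duration"]),
        )
        for s in cfg["segments"]
    )
    aos = cfg["aos"]
    return ProtocolSpec(
        laps=int(cfg["laps"]),
        segments=segments,
        aos_incline=float(aos["incline"]),
        aos_start_speed=float(aos["start_speed"]),
        aos_step=float(aos["step"]),
        aos_step_duration=float(aos["step_duration"]),
        break_duration=float(cfg["break_duration"]),
    )


def aos_speed_at(spec: ProtocolSpec, t: float) -> float:
    """Belt speed (km/h) ``t`` seconds after the start of the all-out sprint.

    The sprint starts at ``aos_start_speed`` and increases by ``aos_step``
    every ``aos_step_duration`` seconds.
    """
    if t < 0:
        raise ProtocolError("t must be >= 0")
    return spec.aos_start_speed + math.floor(t / spec.aos_step_duration) * spec.aos_step


@dataclass(frozen=True)
class SkierOutcome:
    """Breaks taken and sprint time-to-exhaustion for one skier."""

    skier_id: str
    breaks: int
    tte: float

    def __post_init__(self) -> None:
        if self.breaks < 0:
            raise ProtocolError("breaks must be >= 0")
        if self.tte < 0:
            raise ProtocolError("tte must be >= 0")


@dataclass(frozen=True)
class Ranking:
    """Total performance order; rank 1 is best.

    ``tied`` lists skier_id pairs with identical (breaks, tte); such ties are
    broken by input order and flagged here.
    """

    order: tuple[str, ...]
    tied: tuple[tuple[str, str], ...] = ()

    def rank_of(self, skier_id: str) -> int:
        return self.order.index(skier_id) + 1

    @property
    def ranks(self) -> dict[str, int]:
        return {sid: i + 1 for i, sid in enumerate(self.order)}


def rank_skiers(outcomes: Sequence[SkierOutcome]) -> Ranking:
    """Rank skiers: fewest breaks first, then longest TTE within equal breaks.

    Every skier finishing the initial part without breaks outranks any skier
    with breaks, regardless of TTE.
    """
    if not outcomes:
        raise ProtocolError("outcomes must be non-empty")
    ids = [o.skier_id for o in outcomes]
    if len(set(ids)) != len(ids):
        raise ProtocolError("duplicate skier_ids")
    indexed = list(enumerate(outcomes))
    indexed.sort(key=lambda io: (io[1].breaks, -io[1].tte, io[0]))
    order = tuple(o.skier_id for _, o in indexed)
    tied = []
    for (_, a), (_, b) in zip(indexed, indexed[1:]):
        if a.breaks == b.breaks and a.tte == b.tte:
            tied.append((a.skier_id, b.skier_id))
    return Ranking(order=order, tied=tuple(tied))
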