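"""Uniformly sampled multi-channel sensor streams and their CSV form.

A :class:`SensorStream` bundles the named channels of one instrument sampled
at a single rate, with a start-time offset relative to the shared master
timeline (t = 0 at the start of the mass-start initial part).  Streams are
written as plain CSV with a ``# instrument=... rate=... t0_offset=...``
header comment followed by a ``t,<channel>...`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SensorStream", "read_stream_csv"]


@dataclass
class SensorStream:
    """One instrument's channel bundle.

    Attributes
    ----------
    instrument : str
        Instrument name (e.g. 'imu', 'pole_force', 'hr').
    rate : float
        Sampling rate in Hz (may be < 1, e.g. 0.1 Hz for 10-s mixing-chamber
        oxygen-uptake values, which are step-held downstream).
    t0_offset : float
        Time of the first sample on the master timeline, in seconds.
    channels : dict[str, np.ndarray]
        Equal-length 1-D arrays (2-D allowed for vector channels such as
        marker positions).
    """

    instrument: str
    rate: float
    t0_offset: float
    channels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have equal length")

    @property
    def n_samples(self) -> int:
        if not self.channels:
            return 0
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def times(self) -> np.ndarray:
        """Sample times on the master timeline."""
        return self.t0_offset + np.arange(self.n_samples) / self.rate

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.channels[channel]

    def to_csv(self, path: str | Path) -> None:
        cols = {}
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                cols[name] = arr
            else:
                for i, ax in enumerate("xyz"[: arr.shape[1]]):
                    cols[f"{name}_{ax}"] = arr[:, i]
        df = pd.DataFrame({"t": self.times(), **cols})
        with open(path, "w") as fh:
            fh.write(
                f"# instrument={self.instrument} rate={self.rate:g} "
                f"t0_offset={self.t0_offset:g}\n"
            )
            df.to_csv(fh, index=False, float_format="%.6g")


def read_stream_csv(path: str | Path) -> SensorStream:
    """Read a stream CSV written by :meth:`SensorStream.to_csv`."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing stream header")
        meta = dict(tok.split("=", 1) for tok in header[1:].split())
        df = pd.read_csv(fh)
    channels = {c: df[c].to_numpy() for c in df.columns if c != "t"}
    return SensorStream(
        instrument=meta["instrument"],
        rate=float(meta["rate"]),
        t0_offset=float(meta["t0_offset"]),
        channels=channels,
    )
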