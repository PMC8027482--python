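"""Embedded per-skier study tables.

Three small CSVs ship with the package: cohort anthropometrics/physiology
(means ± SD), the per-skier mass-start physiology table (rank, breaks, TTE,
intensities, RPE, blood lactate, peak values, VO2Max, gross efficiency), and
the per-skier kinematics/power table (sub-technique shares, power
decomposition, cycle length/rate).  Two skiers have missing power columns
(instrument failure); those cells are empty and load as NaN.

Each file is integrity-checked against an embedded SHA-256 checksum at load
time so silent edits are caught.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

__all__ = ["load_cohort", "load_physiology", "load_kinematics", "FixtureError"]

_CHECKSUMS = {
    "cohort_characteristics.csv": "58db5ffc2ea6077c4ab25301f4df3ef35dd4e001778f3c52041e710fc3a88795",
    "masstart_physiology.csv": "73b9335a001e2a2032f0b3ccd041de41136b396b8670c41596066be347a240bd",
    "masstart_kinematics.csv": "deb0d998b84b6f0057e8ad125bfa245c2a8ba5cc9fb193dc27c3a299122651d0",
}


class FixtureError(RuntimeError):
    """Raised when an embedded table fails its checksum."""


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("skimass.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureError(f"checksum mismatch for {name}: {digest}")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_cohort() -> pd.DataFrame:
    """Cohort characteristics (variable, mean, sd); 13 male skiers."""
    return _read("cohort_characteristics.csv")


def load_physiology() -> pd.DataFrame:
    """Per-skier mass-start physiology and performance-determining variables.

    One row per skier, ordered by performance rank (1 = best).  Intensity
    columns (``*_ip``) are means over laps 1–3 of the initial part.
    """
    return _read("masstart_physiology.csv")


def load_kinematics() -> pd.DataFrame:
    """Per-skier sub-technique distribution, power split and cycle characteristics.

    ``cl_aos_m`` / ``cr_aos_cpm`` are means over the first three sprint steps.
    Power columns are NaN for the two skiers with missing force data.
    """
    return _read("masstart_kinematics.csv")
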