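"""Statistical analysis: lap drift, segment contrasts, and rank correlations.

Performance analysis follows the study design: Spearman rank correlation
between the mass-start performance ranking (rank 1 = best) and each candidate
variable across all skiers, plus Pearson correlation between sprint
time-to-exhaustion and the same variables within the subgroup that finished
the initial part without breaks.  Correlation magnitudes are labelled on the
conventional bands (trivial < 0.1 ≤ small < 0.3 ≤ moderate < 0.5 ≤ large
< 0.7 ≤ very large < 0.9 ≤ extremely large).

Lap-to-lap drift is lap-7 minus lap-2 means for physiological variables (lap
1 is excluded from the baseline because the response is still rising from
rest) and lap-7 minus lap-1 for kinematic variables, tested with a paired
t-test across skiers.  Segment contrasts use one-way ANOVA with Tukey's HSD,
excluding lap 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from . import fixtures

__all__ = [
    "CorrelationResult",
    "spearman",
    "pearson",
    "magnitude_label",
    "significance_label",
    "lap_drift",
    "segment_contrasts",
    "correlation_battery",
    "reproduce_correlations",
]

_BANDS = (
    (0.1, "trivial"),
    (0.3, "small"),
    (0.5, "moderate"),
    (0.7, "large"),
    (0.9, "very large"),
    (1.0 + 1e-12, "extremely large"),
)


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    p_value: float
    n: int
    method: str
    magnitude: str
    flag: str = ""

    @property
    def defined(self) -> bool:
        return np.isfinite(self.coefficient)


def magnitude_label(r: float) -> str:
    """Magnitude band of a correlation coefficient by absolute value."""
    a = abs(r)
    if a > 1 + 1e-9:
        raise ValueError(f"|r|={a:g} > 1")
    for upper, label in _BANDS:
        if a < upper:
            return label
    return "extremely large"


def significance_label(p: float) -> str:
    """'significant' at α=0.05, 'trend' for 0.05–0.10, else 'ns'."""
    if p < 0.05:
        return "significant"
    if p < 0.10:
        return "trend"
    return "ns"


def _pairwise(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    Missing values are removed pairwise.  Zero variance in either vector
    leaves the coefficient undefined (NaN, flagged).
    """
    x, y = _pairwise(x, y)
    if x.size < 3:
        return CorrelationResult(np.nan, np.nan, int(x.size), "spearman", "", "n<3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            np.nan, np.nan, int(x.size), "spearman", "", "zero variance"
        )
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(
        float(rho), float(p), int(x.size), "spearman", magnitude_label(rho)
    )


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with pairwise deletion of missing values."""
    x, y = _pairwise(x, y)
    if x.size < 3:
        return CorrelationResult(np.nan, np.nan, int(x.size), "pearson", "", "n<3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            np.nan, np.nan, int(x.size), "pearson", "", "zero variance"
        )
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(
        float(r), float(p), int(x.size), "pearson", magnitude_label(r)
    )


def lap_drift(lap_means: pd.DataFrame, kind: str) -> tuple[float, float, np.ndarray]:
    """Lap-to-lap drift across skiers.

    Parameters
    ----------
    lap_means : DataFrame
        One row per skier, one column per lap (labelled 1..L).
    kind : str
        'physiological' (lap L − lap 2 baseline) or 'kinematic'
        (lap L − lap 1 baseline).

    Returns
    -------
    (mean drift, paired-t p-value, per-skier drifts)
    """
    if kind == "physiological":
        base = 2
    elif kind == "kinematic":
        base = 1
    else:
        raise ValueError(f"unknown drift kind {kind!r}")
    last = max(int(c) for c in lap_means.columns)
    cols = {int(c): c for c in lap_means.columns}
    if base not in cols or last not in cols:
        raise ValueError("missing lap columns")
    a = lap_means[cols[last]].to_numpy(dtype=float)
    b = lap_means[cols[base]].to_numpy(dtype=float)
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
        raise ValueError("missing lap means")
    drifts = a - b
    if drifts.size < 2 or np.ptp(drifts) == 0:
        p = 1.0 if np.allclose(drifts, drifts.mean()) and drifts.mean() == 0 else np.nan
        return float(drifts.mean()), float(p), drifts
    t = sps.ttest_rel(a, b)
    return float(drifts.mean()), float(t.pvalue), drifts


def segment_contrasts(segment_means: pd.DataFrame):
    """One-way ANOVA with Tukey HSD across track segments.

    Parameters
    ----------
    segment_means : DataFrame
        One row per skier, one column per segment label (lap 1 already
        excluded upstream).

    Returns
    -------
    (F, p, tukey result) where the Tukey object is the statsmodels
    ``TukeyHSDResults``.
    """
    if segment_means.shape[1] < 2:
        raise ValueError("need at least two segments")
    if segment_means.shape[0] < 2:
        raise ValueError("need at least two skiers")
    groups = [segment_means[c].to_numpy(dtype=float) for c in segment_means.columns]
    f, p = sps.f_oneway(*groups)
    values = np.concatenate(groups)
    labels = np.repeat([str(c) for c in segment_means.columns], segment_means.shape[0])
    tukey = pairwise_tukeyhsd(values, labels, alpha=0.05)
    return float(f), float(p), tukey


def correlation_battery(
    phys: pd.DataFrame, kin: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Spearman battery of performance rank against the summary variables.

    ``phys``/``kin`` follow the column layout of the embedded tables (see
    :mod:`skimass.fixtures`).  The peak-reserve variables are raw differences
    between the sprint peak and the initial-part peak (bpm for HR,
    mL·min⁻¹·kg⁻¹ for VO2); the VO2 variant normalized to VO2Max is also
    reported, with a caveat flag, since the two orderings differ.

    Returns a DataFrame with one row per variable: coefficient, p, n,
    magnitude, significance, caveat.
    """
    rank = phys["rank"]
    variables: dict[str, tuple[pd.Series, str]] = {
        "pct_hrmax_ip": (phys["pct_hrmax_ip"], ""),
        "pct_vo2max_ip": (phys["pct_vo2max_ip"], "tie-precision-sensitive"),
        "vo2_ip": (phys["vo2_ip"], ""),
        "tsi_arm_ip": (phys["tsi_arm_ip"], ""),
        "tsi_leg_ip": (phys["tsi_leg_ip"], ""),
        "rpe_ip": (phys["rpe_ip"], ""),
        "bla_aos": (phys["bla_aos"], ""),
        "vo2max": (phys["vo2max"], ""),
        "ge_oa": (phys["ge_oa"], "tie-precision-sensitive"),
        "ge_g2": (phys["ge_g2"], ""),
        "ge_g3": (phys["ge_g3"], ""),
        "ge_g4": (phys["ge_g4"], ""),
        "hr_peak_reserve": (phys["peak_hr_aos"] - phys["peak_hr_ip"], ""),
        "vo2_peak_reserve": (phys["peak_vo2_aos"] - phys["peak_vo2_ip"], ""),
        "vo2_peak_reserve_pct_max": (
            (phys["peak_vo2_aos"] - phys["peak_vo2_ip"]) / phys["vo2max"] * 100.0,
            "normalized variant; ordering differs from raw difference",
        ),
    }
    if kin is not None:
        for col in (
            "g2_pct",
            "g3_pct",
            "g4_pct",
            "other_pct",
            "p_cycle_w",
            "pct_pole",
            "pct_pole_left",
            "cl_aos_m",
            "cr_aos_cpm",
        ):
            variables[col] = (kin[col], "")
    rows = []
    for name, (series, caveat) in variables.items():
        res = spearman(rank, series)
        rows.append(
            {
                "variable": name,
                "rho": res.coefficient,
                "abs_rho": abs(res.coefficient),
                "p": res.p_value,
                "n": res.n,
                "magnitude": res.magnitude,
                "significance": significance_label(res.p_value)
                if np.isfinite(res.p_value)
                else "",
                "caveat": caveat,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def reproduce_correlations() -> pd.DataFrame:
    """Correlation battery computed from the embedded study tables.

    Loads the per-skier fixtures and returns the Spearman battery together
    with the cohort VO2Max mean as a DataFrame attribute ``vo2max_mean``.
    """
    phys = fixtures.load_physiology()
    kin = fixtures.load_kinematics()
    report = correlation_battery(phys, kin)
    report.attrs["vo2max_mean"] = float(phys["vo2max"].mean())
    return report
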