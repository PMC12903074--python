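"""Analytical method-validation statistics.

Calibration regression, instrument detection limits (LOD = 3σ/S,
LOQ = 10σ/S with σ the intercept standard error of the calibration fit),
Student's-t method detection limit from replicate low-level standards,
matrix-spike recovery with relative standard deviation, and per-group
detection frequency of a monitoring campaign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "QcLimits",
    "SpikeRecovery",
    "CalibrationError",
    "QcError",
    "fit_calibration",
    "sigma_from_replicate_curves",
    "compute_lod_loq",
    "compute_mdl",
    "compute_recovery",
    "detection_frequency",
]


class CalibrationError(ValueError):
    """Calibration data cannot support a valid curve."""


class QcError(ValueError):
    """Invalid QC computation input."""


@dataclass(frozen=True)
class CalibrationCurve:
    levels: tuple[float, ...]
    responses: tuple[float, ...]
    slope: float
    intercept: float
    sigma_intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise CalibrationError(f"r_squared outside [0,1]: {self.r_squared}")


@dataclass(frozen=True)
class QcLimits:
    analyte: str
    lod: float
    loq: float
    mdl: float | None = None


@dataclass(frozen=True)
class SpikeRecovery:
    spike_level: float
    recovery_pct: float
    rsd_pct: float


def fit_calibration(levels: Sequence[float], responses: Sequence[float]) -> CalibrationCurve:
    """Ordinary least-squares calibration fit.

    Requires at least three distinct concentration levels (a seven-point
    curve in routine use). ``sigma_intercept`` is the standard error of the
    fitted intercept, the σ that enters the 3σ/S and 10σ/S limits.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise CalibrationError("levels and responses must have equal length")
    if len(np.unique(x)) < 3:
        raise CalibrationError("need >= 3 distinct calibration levels")
    if np.ptp(x) == 0:
        raise CalibrationError("zero variance in calibration levels")
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 0.0
    return CalibrationCurve(
        levels=tuple(x),
        responses=tuple(y),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        sigma_intercept=float(fit.intercept_stderr),
        r_squared=min(r2, 1.0),
    )


def sigma_from_replicate_curves(curves: Sequence[CalibrationCurve]) -> float:
    """σ as the sample standard deviation of intercepts across replicate curves.

    Alternative reading of "standard deviation of the regression intercepts"
    for labs that run the calibration several times; the default single-curve
    mode uses the intercept standard error instead.
    """
    if len(curves) < 2:
        raise CalibrationError("need >= 2 replicate curves")
    return float(np.std([c.intercept for c in curves], ddof=1))


def compute_lod_loq(curve: CalibrationCurve, analyte: str = "") -> QcLimits:
    """LOD = 3σ/|S| and LOQ = 10σ/|S| from one calibration curve."""
    if curve.slope == 0:
        raise CalibrationError("slope is zero; detection limits undefined")
    s = abs(curve.slope)
    lod = 3.0 * curve.sigma_intercept / s
    loq = 10.0 * curve.sigma_intercept / s
    return QcLimits(analyte=analyte, lod=lod, loq=loq)


def compute_mdl(replicates: Sequence[float], confidence: float = 0.99) -> float:
    """Method detection limit: replicate SD x one-tailed Student's t.

    ``t`` is taken at the given one-tailed confidence with n-1 degrees of
    freedom (t = 3.143 for the conventional seven replicates at 99%).
    """
    x = np.asarray(replicates, dtype=float)
    if x.size < 2:
        raise QcError("need >= 2 replicates for an MDL")
    if not 0.5 < confidence < 1.0:
        raise QcError("confidence must be in (0.5, 1)")
    sd = float(np.std(x, ddof=1))
    t = float(stats.t.ppf(confidence, df=x.size - 1))
    return sd * t


def compute_recovery(
    spiked: Sequence[float], unspiked: float, spike_level: float
) -> SpikeRecovery:
    """Matrix-spike recovery (%) and RSD (%) of the spiked replicates."""
    if spike_level <= 0:
        raise QcError("spike_level must be > 0")
    x = np.asarray(spiked, dtype=float)
    if x.size == 0:
        raise QcError("need spiked measurements")
    mean = float(np.mean(x))
    if mean == 0:
        raise QcError("mean spiked concentration is zero; RSD undefined")
    recovery = 100.0 * (mean - float(unspiked)) / spike_level
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return SpikeRecovery(
        spike_level=float(spike_level), recovery_pct=recovery, rsd_pct=100.0 * sd / mean
    )


def detection_frequency(
    measurements: pd.DataFrame,
    lod: Mapping[str, float] | float,
    group_cols: Sequence[str] = ("state", "setting", "season"),
    level: str = "site",
) -> pd.DataFrame:
    """Percent of sites (or samples) with a detection, per analyte x group.

    At ``level='site'`` (default) a site counts as a detection when the mean
    of its replicate concentrations (non-detects as reported, i.e. zero
    under the default policy) is at or above the analyte LOD; at
    ``level='replicate'`` each row is assessed individually.
    """
    if measurements.empty:
        raise QcError("empty measurement table")
    if level not in ("site", "replicate"):
        raise QcError(f"unknown level {level!r}")
    df = measurements.copy()
    lods = (
        {a: float(lod) for a in df["analyte"].unique()}
        if np.isscalar(lod)
        else dict(lod)
    )
    missing = set(df["analyte"].unique()) - set(lods)
    if missing:
        raise QcError(f"no LOD for analytes: {sorted(missing)}")
    keys = list(group_cols) + ["analyte"]
    if level == "site":
        unit = df.groupby(keys + ["site_id"], sort=True)["concentration_mg_L"].mean()
    else:
        unit = df.set_index(keys)["concentration_mg_L"]
        unit.index = pd.MultiIndex.from_arrays(
            [df[k] for k in keys] + [np.arange(len(df))], names=keys + ["row"]
        )
    unit = unit.reset_index()
    unit["detected"] = [
        c >= lods[a] for c, a in zip(unit["concentration_mg_L"], unit["analyte"])
    ]
    out = (
        unit.groupby(keys, sort=True)["detected"]
        .agg(n_units="size", detection_pct=lambda s: 100.0 * s.mean())
        .reset_index()
    )
    return out
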