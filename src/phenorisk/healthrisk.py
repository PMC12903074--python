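"""Non-carcinogenic human-health risk via the drinking-water ingestion route.

For a groundwater concentration C (mg/L) and an age-group exposure profile
(daily water intake DWI, body weight BW, gastrointestinal absorption AB,
exposure-frequency fraction FOE):

    EDI  = C * DWI * AB * FOE / BW        (mg per kg bw per day)
    DWEL = RfD * BW / (DWI * AB * FOE)    (mg/L)
    RQ_H = C / DWEL  ==  EDI / RfD        (dimensionless)

The two RQ_H routes are algebraically identical; both are evaluated and
required to agree, which is the module's unit-consistency contract (a
literal EDI/DWEL ratio would carry units of kg·L⁻¹·day⁻¹ and cannot be a
risk quotient). FOE enters EDI and DWEL symmetrically and cancels in RQ_H.
Tiers: RQ_H < 0.2 no risk, 0.2 <= RQ_H < 1 potential risk, >= 1 risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExposureProfile",
    "ReferenceDose",
    "HealthRiskResult",
    "HealthRiskError",
    "ADULT",
    "CHILD",
    "compute_edi",
    "compute_dwel",
    "compute_rq_h",
    "classify_health_tier",
    "health_risk_table",
    "summarize_health_risk",
]

FOE_DEFAULT = 350.0 / 365.0  # 350 exposure days per year


class HealthRiskError(ValueError):
    """Invalid exposure parameter or reference dose."""


@dataclass(frozen=True)
class ExposureProfile:
    group: str
    dwi: float  # L/day
    bw: float  # kg
    ab: float = 1.0  # gastrointestinal absorption fraction
    foe: float = FOE_DEFAULT  # exposure-frequency fraction

    def __post_init__(self) -> None:
        if self.dwi <= 0 or self.bw <= 0:
            raise HealthRiskError("dwi and bw must be > 0")
        if not 0 < self.ab <= 1 or not 0 < self.foe <= 1:
            raise HealthRiskError("ab and foe must be in (0, 1]")

    @property
    def intake_rate(self) -> float:
        """L per kg bw per day actually absorbed: DWI·AB·FOE/BW."""
        return self.dwi * self.ab * self.foe / self.bw


ADULT = ExposureProfile(group="adult", dwi=2.0, bw=70.0)
CHILD = ExposureProfile(group="child", dwi=1.0, bw=15.0)


@dataclass(frozen=True)
class ReferenceDose:
    analyte: str
    kind: str  # ADI | TDI | RfD
    value: float  # mg per kg bw per day
    provisional: bool = False

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise HealthRiskError(f"reference dose must be > 0: {self}")
        if self.kind not in ("ADI", "TDI", "RfD"):
            raise HealthRiskError(f"unknown reference-dose kind {self.kind!r}")


@dataclass(frozen=True)
class HealthRiskResult:
    edi: float
    dwel: float
    rq_h: float
    tier: str


def compute_edi(c: float, profile: ExposureProfile) -> float:
    """Estimated daily intake, mg per kg bw per day."""
    if c < 0:
        raise HealthRiskError(f"concentration must be >= 0, got {c}")
    return c * profile.intake_rate


def compute_dwel(rfd: ReferenceDose, profile: ExposureProfile) -> float:
    """Drinking-water equivalent level, mg/L, for one age group."""
    denom = profile.dwi * profile.ab * profile.foe
    if denom == 0:
        raise HealthRiskError("dwi * ab * foe must be > 0")
    return rfd.value * profile.bw / denom


def classify_health_tier(rq_h: float) -> str:
    if rq_h < 0 or not np.isfinite(rq_h):
        raise HealthRiskError(f"invalid rq_h {rq_h}")
    if rq_h >= 1.0:
        return "risk"
    if rq_h >= 0.2:
        return "potential_risk"
    return "no_risk"


def compute_rq_h(c: float, rfd: ReferenceDose, profile: ExposureProfile) -> HealthRiskResult:
    """RQ_H via both routes (C/DWEL and EDI/RfD), asserted identical."""
    edi = compute_edi(c, profile)
    dwel = compute_dwel(rfd, profile)
    rq_conc = c / dwel
    rq_dose = edi / rfd.value
    # atol guards the denormal range where relative error is meaningless
    if not np.isclose(rq_conc, rq_dose, rtol=1e-9, atol=1e-290):
        raise HealthRiskError(
            f"unit-consistency violation: C/DWEL={rq_conc} != EDI/RfD={rq_dose}"
        )
    return HealthRiskResult(
        edi=edi, dwel=dwel, rq_h=rq_conc, tier=classify_health_tier(rq_conc)
    )


def health_risk_table(
    mec: pd.DataFrame,
    reference_doses: Sequence[ReferenceDose],
    profiles: Sequence[ExposureProfile] = (ADULT, CHILD),
) -> pd.DataFrame:
    """EDI/DWEL/RQ_H per group x analyte x MEC grouping cell.

    ``mec`` is the output of :func:`phenorisk.ecorisk.mec_table` (group
    columns + analyte + mec_mg_L). Analytes without a reference dose are
    omitted.
    """
    if mec.empty:
        raise HealthRiskError("empty MEC table")
    rfd_by_analyte = {r.analyte: r for r in reference_doses}
    rows = []
    for rec in mec.to_dict("records"):
        rfd = rfd_by_analyte.get(rec["analyte"])
        if rfd is None:
            continue
        for profile in profiles:
            res = compute_rq_h(rec["mec_mg_L"], rfd, profile)
            rows.append(
                {
                    **{k: v for k, v in rec.items() if k != "mec_mg_L"},
                    "group": profile.group,
                    "c_mg_L": rec["mec_mg_L"],
                    "edi_mg_kg_day": res.edi,
                    "rfd_mg_kg_day": rfd.value,
                    "dwel_mg_L": res.dwel,
                    "rq_h": res.rq_h,
                    "tier": res.tier,
                }
            )
    if not rows:
        raise HealthRiskError("no analyte has a reference dose")
    return pd.DataFrame(rows)


def summarize_health_risk(
    results: pd.DataFrame, by: Sequence[str] = ("group",)
) -> pd.DataFrame:
    """Exceedance fractions against the tier thresholds, per grouping.

    Reports the percent of cells at or above RQ_H = 1 (risk), at or above
    0.2 (any flagged concern), and with EDI above the reference dose.
    """
    if results.empty:
        raise HealthRiskError("empty results table")

    def _summ(sub: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "n": len(sub),
                "pct_rq_ge_1": 100.0 * float((sub["rq_h"] >= 1.0).mean()),
                "pct_rq_ge_0_2": 100.0 * float((sub["rq_h"] >= 0.2).mean()),
                "pct_edi_above_rfd": 100.0
                * float((sub["edi_mg_kg_day"] > sub["rfd_mg_kg_day"]).mean()),
            }
        )

    out = results.groupby(list(by), sort=True).apply(_summ, include_groups=False)
    return out.reset_index()
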