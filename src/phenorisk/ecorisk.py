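"""Ecological risk quotients from toxicity endpoints.

PNEC (predicted no-effect concentration) is a toxicity endpoint divided by
an assessment factor: 100 for acute EC50/LC50 endpoints, 10 for chronic
NOECs. The risk quotient RQ_E = MEC / PNEC compares a measured
environmental concentration to that benchmark and is tiered
(minimal <= 0.1 < medium <= 1 < high) and additionally flagged against
regulatory levels of concern (0.5 acute, 1.0 chronic). Range endpoints
resolve to their lower bound and inequality bounds ("NOEC >= x") use the
stated bound, both marked by a qualifier so the conservatism is traceable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ToxicityRecord",
    "EcoRiskResult",
    "EcoRiskError",
    "ASSESSMENT_FACTORS",
    "LEVELS_OF_CONCERN",
    "derive_pnec",
    "classify_eco_tier",
    "compute_rq_e",
    "mec_table",
    "eco_risk_table",
    "summarize_exceedance",
]

ASSESSMENT_FACTORS = {"acute": 100.0, "chronic": 10.0}
LEVELS_OF_CONCERN = {"acute": 0.5, "chronic": 1.0}
TROPHIC_LEVELS = ("algae", "invertebrate", "fish")
_ACUTE_ENDPOINTS = ("EC50", "LC50")
_CHRONIC_ENDPOINTS = ("NOEC",)


class EcoRiskError(ValueError):
    """Invalid toxicity data or risk-quotient input."""


@dataclass(frozen=True)
class ToxicityRecord:
    analyte: str
    trophic_level: str
    endpoint: str
    value: float  # mg/L; ranges/inequalities resolved to a bound
    toxicity_class: str  # acute | chronic
    qualifier: str | None = None  # range_lower | lower_bound | None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise EcoRiskError(f"nonpositive endpoint value: {self}")
        if self.toxicity_class not in ASSESSMENT_FACTORS:
            raise EcoRiskError(f"unknown toxicity class {self.toxicity_class!r}")
        if self.trophic_level not in TROPHIC_LEVELS:
            raise EcoRiskError(f"unknown trophic level {self.trophic_level!r}")
        expected = (
            _ACUTE_ENDPOINTS if self.toxicity_class == "acute" else _CHRONIC_ENDPOINTS
        )
        if self.endpoint not in expected:
            raise EcoRiskError(
                f"{self.toxicity_class} record must carry one of {expected}, "
                f"got {self.endpoint}"
            )


@dataclass(frozen=True)
class EcoRiskResult:
    mec: float
    pnec: float
    rq_e: float
    tier: str
    loc_exceeded: bool
    toxicity_class: str


def derive_pnec(records: Iterable[ToxicityRecord]) -> pd.DataFrame:
    """One PNEC per analyte x trophic level x class; missing endpoints stay missing.

    Returns columns analyte, trophic_level, class, endpoint, value_mg_L,
    qualifier, af, pnec_mg_L. Duplicate keys raise.
    """
    rows = []
    seen = set()
    for rec in records:
        key = (rec.analyte, rec.trophic_level, rec.toxicity_class)
        if key in seen:
            raise EcoRiskError(f"duplicate toxicity record for {key}")
        seen.add(key)
        af = ASSESSMENT_FACTORS[rec.toxicity_class]
        rows.append(
            {
                "analyte": rec.analyte,
                "trophic_level": rec.trophic_level,
                "class": rec.toxicity_class,
                "endpoint": rec.endpoint,
                "value_mg_L": rec.value,
                "qualifier": rec.qualifier,
                "af": af,
                "pnec_mg_L": rec.value / af,
            }
        )
    if not rows:
        raise EcoRiskError("no toxicity records supplied")
    return pd.DataFrame(rows)


def classify_eco_tier(rq_e: float) -> str:
    """Three-tier classification with strict upper inequalities.

    rq > 1 is high, 0.1 < rq <= 1 medium, rq <= 0.1 minimal; the boundaries
    1.0 and 0.1 fall in the lower tier.
    """
    if rq_e < 0 or not np.isfinite(rq_e):
        raise EcoRiskError(f"invalid rq_e {rq_e}")
    if rq_e > 1.0:
        return "high"
    if rq_e > 0.1:
        return "medium"
    return "minimal"


def compute_rq_e(mec: float, pnec: float, toxicity_class: str = "chronic") -> EcoRiskResult:
    """RQ_E = MEC / PNEC with tier and level-of-concern flag."""
    if pnec <= 0:
        raise EcoRiskError(f"pnec must be > 0, got {pnec}")
    if mec < 0:
        raise EcoRiskError(f"mec must be >= 0, got {mec}")
    if toxicity_class not in LEVELS_OF_CONCERN:
        raise EcoRiskError(f"unknown toxicity class {toxicity_class!r}")
    rq = mec / pnec
    return EcoRiskResult(
        mec=mec,
        pnec=pnec,
        rq_e=rq,
        tier=classify_eco_tier(rq),
        loc_exceeded=rq > LEVELS_OF_CONCERN[toxicity_class],
        toxicity_class=toxicity_class,
    )


def mec_table(
    measurements: pd.DataFrame,
    group_cols: Sequence[str] = ("state", "setting", "season"),
    statistic: str = "mean",
) -> pd.DataFrame:
    """Measured environmental concentration per analyte x group.

    Site means (replicates averaged, non-detects as reported) are the unit;
    ``statistic='mean'`` averages site means within the group,
    ``statistic='max'`` takes the worst site (worst-case mode).
    """
    if measurements.empty:
        raise EcoRiskError("empty measurement table")
    if statistic not in ("mean", "max"):
        raise EcoRiskError(f"unknown MEC statistic {statistic!r}")
    keys = list(group_cols) + ["analyte"]
    site_means = measurements.groupby(keys + ["site_id"], sort=True)[
        "concentration_mg_L"
    ].mean()
    agg = site_means.groupby(keys, sort=True).agg(statistic)
    return agg.rename("mec_mg_L").reset_index()


def eco_risk_table(mec: pd.DataFrame, pnec: pd.DataFrame) -> pd.DataFrame:
    """Cross MEC groups with the PNEC table: one RQ_E row per group x
    trophic level x class for which a PNEC exists (missing endpoints are
    omitted, never imputed)."""
    merged = mec.merge(pnec, on="analyte", how="inner")
    if merged.empty:
        raise EcoRiskError("no analyte overlaps between MEC and PNEC tables")
    results = [
        compute_rq_e(m, p, c)
        for m, p, c in zip(merged["mec_mg_L"], merged["pnec_mg_L"], merged["class"])
    ]
    merged = merged.copy()
    merged["rq_e"] = [r.rq_e for r in results]
    merged["tier"] = [r.tier for r in results]
    merged["loc_exceeded"] = [r.loc_exceeded for r in results]
    return merged


def summarize_exceedance(
    results: pd.DataFrame,
    threshold: float = 1.0,
    site_col: str | None = None,
) -> pd.DataFrame:
    """Percent of RQ_E values above ``threshold``, per class and overall.

    If ``site_col`` names a column, also reports the percent of its distinct
    values (e.g. sites or groups) with at least one exceedance.
    """
    if results.empty:
        raise EcoRiskError("empty results table")
    rows = []
    frames = [("overall", results)] + [
        (cls, sub) for cls, sub in results.groupby("class", sort=True)
    ]
    for label, sub in frames:
        entry = {
            "class": label,
            "n": len(sub),
            "pct_rq_above": 100.0 * float((sub["rq_e"] > threshold).mean()),
        }
        if site_col is not None:
            any_exceed = sub.groupby(site_col)["rq_e"].max() > threshold
            entry["pct_sites_any_exceedance"] = 100.0 * float(any_exceed.mean())
        rows.append(entry)
    return pd.DataFrame(rows)
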