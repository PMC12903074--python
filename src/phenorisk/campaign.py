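"""Synthetic groundwater monitoring campaigns.

The generator emulates a multi-state seasonal monitoring design: several
states, each with a rural and an urban cell, a fixed number of sampling
sites per cell placed in distance bands around a dumpsite, three spatial
replicates per site, and two seasons (rainy/dry). Concentrations of each
analyte follow a lognormal model on the detectable component,

    log C = log_mean(analyte, state, setting)
            + season_effect * [season == dry]
            + site_effect,  site_effect ~ N(0, site_sd^2)
            + e,            e ~ N(0, replicate_sd^2)

mixed with a Bernoulli structural-zero component (an analyte simply absent
at a site). Values below the analyte's limit of detection are censored and
reported per a substitution policy (zero by default). Physicochemical
covariates (pH, EC, TDS) are drawn alongside; EC and TDS are coupled to the
latent site-level contamination of the quinones so that mineralization and
quinone load co-vary, the pattern a leachate plume produces.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "CampaignDesign",
    "GenerativeParams",
    "DesignError",
    "ParameterError",
    "generate_campaign",
    "apply_censoring",
    "write_campaign_csv",
    "read_campaign_csv",
    "CAMPAIGN_COLUMNS",
]

CAMPAIGN_COLUMNS = [
    "state",
    "setting",
    "site_id",
    "season",
    "replicate_id",
    "analyte",
    "concentration_mg_L",
    "censored",
    "ph",
    "ec_uS_cm",
    "tds_mg_L",
]

#: analytes treated as quinones for the EC/TDS coupling
_QUINONES = ("HQ", "BQ")


class DesignError(ValueError):
    """Invalid campaign design (counts, labels)."""


class ParameterError(ValueError):
    """Invalid generative or censoring parameter."""


def _check_unique(name: str, labels: Sequence[str]) -> None:
    if len(labels) == 0:
        raise DesignError(f"{name} must be non-empty")
    if len(set(labels)) != len(labels):
        raise DesignError(f"{name} labels must be unique, got {labels!r}")


@dataclass(frozen=True)
class CampaignDesign:
    """Factorial layout of a monitoring campaign.

    Defaults reproduce the reference design: 3 states x 2 settings x
    10 sites x 3 replicates x 2 seasons x 4 analytes = 1440 measurement
    rows, i.e. 60 field samples per season and state-pair of cells.
    """

    states: tuple[str, ...] = ("Osun", "Oyo", "Lagos")
    settings: tuple[str, ...] = ("rural", "urban")
    n_sites_per_cell: int = 10
    n_replicates: int = 3
    seasons: tuple[str, ...] = ("rainy", "dry")
    analytes: tuple[str, ...] = ("BPA", "HQ", "RE", "BQ")
    distance_bands_m: tuple[float, ...] = (50, 100, 150, 200, 250, 300, 350, 400, 450, 500)

    def __post_init__(self) -> None:
        _check_unique("states", self.states)
        _check_unique("settings", self.settings)
        _check_unique("seasons", self.seasons)
        _check_unique("analytes", self.analytes)
        if self.n_sites_per_cell < 1:
            raise DesignError("n_sites_per_cell must be >= 1")
        if self.n_replicates < 1:
            raise DesignError("n_replicates must be >= 1")
        if len(self.distance_bands_m) == 0:
            raise DesignError("distance_bands_m must be non-empty")

    @property
    def n_rows(self) -> int:
        return (
            len(self.states)
            * len(self.settings)
            * self.n_sites_per_cell
            * self.n_replicates
            * len(self.seasons)
            * len(self.analytes)
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CampaignDesign":
        d = dict(d)
        for key in ("states", "settings", "seasons", "analytes", "distance_bands_m"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _default_log_means() -> dict[str, float]:
    # geometric means ~5, 2, 1.5, 1 mg/L: the reported order of magnitude
    return {
        "BPA": math.log(5.0),
        "HQ": math.log(2.0),
        "RE": math.log(1.5),
        "BQ": math.log(1.0),
    }


@dataclass(frozen=True)
class GenerativeParams:
    """Distributional parameters of the campaign generator.

    ``log_mean`` may be a scalar (all analytes), a mapping keyed by analyte,
    or a mapping keyed by ``(analyte, state, setting)`` tuples for cell-level
    baselines (tuple keys take precedence over analyte keys).
    """

    log_mean: float | Mapping = field(default_factory=_default_log_means)
    season_effect: float = 0.7  # additive dry-season shift, log scale
    site_sd: float = 0.6
    replicate_sd: float = 0.25
    detect_prob_floor: float = 0.15  # P(analyte structurally absent at a site)
    covariate_coupling: float = 1.0  # slope of log EC/TDS on latent quinone load
    seed: int = 2024

    def __post_init__(self) -> None:
        if self.site_sd < 0 or self.replicate_sd < 0:
            raise ParameterError("standard deviations must be >= 0")
        if not 0.0 <= self.detect_prob_floor <= 1.0:
            raise ParameterError("detect_prob_floor must be in [0, 1]")

    def resolve_log_mean(self, analyte: str, state: str, setting: str) -> float:
        lm = self.log_mean
        if isinstance(lm, Mapping):
            if (analyte, state, setting) in lm:
                return float(lm[(analyte, state, setting)])
            if analyte in lm:
                return float(lm[analyte])
            raise ParameterError(f"log_mean has no entry for analyte {analyte!r}")
        return float(lm)

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(self.log_mean, Mapping):
            d["log_mean"] = {
                "|".join(k) if isinstance(k, tuple) else k: float(v)
                for k, v in self.log_mean.items()
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GenerativeParams":
        d = dict(d)
        lm = d.get("log_mean")
        if isinstance(lm, Mapping):
            d["log_mean"] = {
                (tuple(k.split("|")) if "|" in k else k): float(v) for k, v in lm.items()
            }
        return cls(**d)


def apply_censoring(
    values, lod: float, policy: str = "zero"
) -> tuple[np.ndarray, np.ndarray]:
    """Censor concentrations below a limit of detection.

    Returns ``(reported, censored_flags)``. Policies: ``zero`` replaces
    non-detects with 0 (the pipeline default, so summary statistics do not
    overstate the pollution burden), ``half_lod`` with LOD/2, ``as_is``
    keeps the raw value and only flags it.
    """
    if lod <= 0:
        raise ParameterError(f"lod must be > 0, got {lod}")
    if policy not in ("zero", "half_lod", "as_is"):
        raise ParameterError(f"unknown censoring policy {policy!r}")
    vals = np.asarray(values, dtype=float)
    flags = vals < lod
    out = vals.copy()
    if policy == "zero":
        out[flags] = 0.0
    elif policy == "half_lod":
        out[flags] = lod / 2.0
    return out, flags


def _lod_lookup(lod, analytes: Sequence[str]) -> dict[str, float]:
    if lod is None:
        from .registries import load_qc_limits

        table = load_qc_limits().set_index("analyte")["lod_mg_L"]
        return {a: float(table[a]) if a in table.index else 0.0 for a in analytes}
    if isinstance(lod, Mapping):
        return {a: float(lod.get(a, 0.0)) for a in analytes}
    return {a: float(lod) for a in analytes}


def generate_campaign(
    design: CampaignDesign,
    params: GenerativeParams,
    lod=None,
    policy: str = "zero",
) -> pd.DataFrame:
    """Draw one full monitoring campaign as a tidy long table.

    ``lod`` may be None (use the packaged per-analyte limits; unknown
    analytes are not censored), a scalar, or a mapping by analyte. The same
    seed and parameters always produce a byte-identical table.
    """
    lods = _lod_lookup(lod, design.analytes)
    rng = np.random.default_rng(params.seed)
    n_analytes = len(design.analytes)
    dry_label = design.seasons[-1] if len(design.seasons) > 1 else None

    quinones = [a for a in design.analytes if a in _QUINONES] or list(design.analytes)
    qidx = [design.analytes.index(a) for a in quinones]

    rows: list[tuple] = []
    for state in design.states:
        for setting in design.settings:
            for s in range(design.n_sites_per_cell):
                site_id = f"{state[:2].upper()}-{setting[0].upper()}{s + 1:02d}"
                site_eff = rng.normal(0.0, params.site_sd, size=n_analytes)
                absent = rng.random(n_analytes) < params.detect_prob_floor
                latent = float(np.mean(site_eff[qidx]))
                for season in design.seasons:
                    sd_shift = params.season_effect if season == dry_label else 0.0
                    for r in range(design.n_replicates):
                        # one physical water sample per site x season x replicate
                        ph = float(
                            stats.truncnorm.rvs(
                                (4.0 - 6.8) / 0.4,
                                (9.0 - 6.8) / 0.4,
                                loc=6.8,
                                scale=0.4,
                                random_state=rng,
                            )
                        )
                        ec = float(
                            np.exp(
                                math.log(400.0)
                                + params.covariate_coupling * latent
                                + rng.normal(0.0, 0.15)
                            )
                        )
                        tds = float(
                            np.exp(
                                math.log(250.0)
                                + params.covariate_coupling * latent
                                + rng.normal(0.0, 0.15)
                            )
                        )
                        noise = rng.normal(0.0, params.replicate_sd, size=n_analytes)
                        for j, analyte in enumerate(design.analytes):
                            if absent[j]:
                                conc, cens = 0.0, True
                            else:
                                mu = params.resolve_log_mean(analyte, state, setting)
                                conc = math.exp(mu + sd_shift + site_eff[j] + noise[j])
                                cens = False
                                if lods[analyte] > 0 and conc < lods[analyte]:
                                    reported, _ = apply_censoring(
                                        [conc], lods[analyte], policy
                                    )
                                    conc, cens = float(reported[0]), True
                            rows.append(
                                (
                                    state,
                                    setting,
                                    site_id,
                                    season,
                                    f"r{r + 1}",
                                    analyte,
                                    conc,
                                    cens,
                                    ph,
                                    ec,
                                    tds,
                                )
                            )
    df = pd.DataFrame(rows, columns=CAMPAIGN_COLUMNS)
    assert len(df) == design.n_rows
    return df


def write_campaign_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_campaign_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CAMPAIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ParameterError(f"campaign CSV missing columns: {sorted(missing)}")
    return df


def campaign_to_yaml(design: CampaignDesign, params: GenerativeParams) -> str:
    """Serialize a design + parameter pair to YAML."""
    return yaml.safe_dump(
        {"design": design.to_dict(), "params": params.to_dict()}, sort_keys=False
    )


def campaign_from_yaml(text_or_stream) -> tuple[CampaignDesign, GenerativeParams]:
    if isinstance(text_or_stream, str):
        text_or_stream = io.StringIO(text_or_stream)
    d = yaml.safe_load(text_or_stream)
    return CampaignDesign.from_dict(d["design"]), GenerativeParams.from_dict(d["params"])
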