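"""End-to-end orchestration of the monitoring-campaign analysis.

One call runs: campaign simulation (or CSV ingestion) -> detection
frequency -> group-level MEC summaries -> ecological risk quotients ->
age-stratified human-health risk -> two-way ANOVA / Pearson / PCA, and
writes every stage's table plus a JSON run manifest (seed, config hash,
package version) so a run is reproducible from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .campaign import (
    CampaignDesign,
    DesignError,
    GenerativeParams,
    generate_campaign,
    read_campaign_csv,
)
from .ecorisk import derive_pnec, eco_risk_table, mec_table, summarize_exceedance
from .healthrisk import health_risk_table, summarize_health_risk
from .multivariate import (
    StatsError,
    pca_varimax,
    pearson_matrix,
    site_wide_table,
    two_way_anova,
)
from .qc import detection_frequency
from .registries import (
    load_exposure_profiles,
    load_qc_limits,
    load_reference_doses,
    load_toxicity_records,
    validate_registries,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("phenorisk")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    design: CampaignDesign = field(default_factory=CampaignDesign)
    params: GenerativeParams = field(default_factory=GenerativeParams)
    input_csv: str | None = None  # measured campaign instead of simulation
    censoring_policy: str = "zero"
    mec_statistic: str = "mean"  # or "max" for the worst-case mode
    retain: str | int = "kaiser"
    loading_threshold: float = 0.5
    alpha: float = 0.05
    seed: int | None = None  # overrides params.seed when set

    def with_seed(self, seed: int) -> "PipelineConfig":
        cfg = dataclasses.replace(self)
        cfg.seed = seed
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"] = self.design.to_dict()
        d["params"] = self.params.to_dict()
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (DesignError, StatsError, ValueError) as exc:
                raise PipelineError(f"[{name}] {exc}") from exc

        return wrapped

    return deco


@_stage("simulate")
def _stage_measurements(cfg: PipelineConfig) -> pd.DataFrame:
    if cfg.input_csv is not None:
        return read_campaign_csv(cfg.input_csv)
    params = cfg.params
    if cfg.seed is not None:
        params = dataclasses.replace(params, seed=cfg.seed)
    return generate_campaign(cfg.design, params, policy=cfg.censoring_policy)


@_stage("stats")
def _stage_stats(cfg: PipelineConfig, measurements: pd.DataFrame) -> dict:
    out: dict = {}
    # per-state two-way ANOVA: setting x compound-season on replicate rows
    anova_rows = []
    df = measurements.copy()
    df["compound_season"] = df["analyte"] + "_" + df["season"]
    for state, sub in df.groupby("state", sort=True):
        res = two_way_anova(sub["concentration_mg_L"], sub["setting"], sub["compound_season"])
        t = res.table.reset_index(names="effect")
        t.insert(0, "state", state)
        anova_rows.append(t)
    out["anova"] = pd.concat(anova_rows, ignore_index=True)

    wide = site_wide_table(measurements)
    variables = wide.drop(columns=["state", "setting", "site_id"])
    corr = pearson_matrix(variables)
    out["correlation"] = corr.matrix
    out["correlation_tiers"] = corr.tiers
    pca = pca_varimax(variables, retain=cfg.retain, loading_threshold=cfg.loading_threshold)
    out["pca"] = pca
    report = pca.rotated_loadings.copy()
    report.loc["eigenvalue"] = pca.eigenvalues[: report.shape[1]]
    report.loc["pct_variance"] = pca.pct_variance
    report.loc["cumulative_pct"] = pca.cumulative_pct
    out["pca_report"] = report
    return out


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run every stage; return the result tables, optionally writing them.

    Returns a dict with keys ``measurements``, ``detection_frequency``,
    ``mec``, ``pnec``, ``eco_risk``, ``eco_exceedance``, ``health_risk``,
    ``health_summary``, ``anova``, ``correlation``, ``correlation_tiers``,
    ``pca`` (a :class:`~phenorisk.multivariate.PcaResult`), ``pca_report``
    and ``manifest``. With ``outdir`` set, each table is written as CSV and
    the manifest as JSON.
    """
    if len(cfg.design.analytes) == 0:
        raise PipelineError("[config] design has zero analytes")

    toxicity = load_toxicity_records()
    profiles = load_exposure_profiles()
    rfds = load_reference_doses()
    warnings = validate_registries(toxicity, profiles, rfds, cfg.design.analytes)
    for w in warnings:
        log.warning(w)

    measurements = _stage_measurements(cfg)
    log.info("measurements: %d rows", len(measurements))

    qc_limits = load_qc_limits().set_index("analyte")["lod_mg_L"]
    lods = {
        a: float(qc_limits[a]) if a in qc_limits.index else 0.0
        for a in measurements["analyte"].unique()
    }
    detfreq = detection_frequency(measurements, lods)
    mec = mec_table(measurements, statistic=cfg.mec_statistic)

    pnec = derive_pnec(toxicity)
    eco = eco_risk_table(mec, pnec)
    eco_summary = summarize_exceedance(eco, threshold=1.0)
    log.info(
        "eco risk: %.1f%% of chronic RQ values above 1",
        eco_summary.set_index("class").loc["chronic", "pct_rq_above"],
    )

    health = health_risk_table(mec, rfds, profiles)
    health_summary = summarize_health_risk(health)

    stats_out = _stage_stats(cfg, measurements)

    manifest = {
        "package": "phenorisk",
        "version": __version__,
        "seed": cfg.seed if cfg.seed is not None else cfg.params.seed,
        "config_hash": cfg.config_hash(),
        "n_measurements": int(len(measurements)),
        "registry_warnings": warnings,
    }

    results = {
        "measurements": measurements,
        "detection_frequency": detfreq,
        "mec": mec,
        "pnec": pnec,
        "eco_risk": eco,
        "eco_exceedance": eco_summary,
        "health_risk": health,
        "health_summary": health_summary,
        "manifest": manifest,
        **stats_out,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, obj in results.items():
            if name in ("manifest", "pca"):
                continue
            index = name in ("correlation", "correlation_tiers", "pca_report")
            obj.to_csv(outdir / f"{name}.csv", index=index)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
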