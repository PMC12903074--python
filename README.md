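# phenorisk

Risk-assessment pipeline for phenolic contaminants (bisphenol A,
hydroquinone, resorcinol, benzoquinone) in groundwater monitored around
unmanaged waste sites. Field campaigns of this kind sample rural and urban
sites across several states in both rainy and dry seasons; the package
turns such campaigns — real CSVs or synthetic ones with the same
statistical structure — into quality-controlled analytical summaries,
ecological and human-health risk quotients, and multivariate source
diagnostics. It is written for environmental chemists and exposure
scientists who need the whole chain reproducible and testable.

## What it computes

**Analytical QC** (`phenorisk.qc`) — calibration regression with the
detection limits LOD = 3σ/S and LOQ = 10σ/S (σ the intercept standard
error, S the slope), the method detection limit MDL = sd × t(99%, n−1)
from replicate low-level standards, matrix-spike recovery/RSD, and
per-group detection frequency with non-detects treated as zero.

**Ecological risk** (`phenorisk.ecorisk`) — PNEC = endpoint / AF with
assessment factors 100 (acute EC50/LC50) and 10 (chronic NOEC) per
analyte × trophic level (algae, invertebrates, fish), then

    RQ_E = MEC / PNEC

tiered minimal (≤ 0.1) / medium (≤ 1) / high (> 1) and flagged against the
regulatory levels of concern (0.5 acute, 1.0 chronic). Range and
inequality endpoints resolve conservatively to their lower bound.

**Human health** (`phenorisk.healthrisk`) — for adults (2 L/day, 70 kg)
and children (1 L/day, 15 kg), with absorption AB = 1 and exposure
frequency FOE = 350/365:

    EDI  = C·DWI·AB·FOE / BW          DWEL = RfD·BW / (DWI·AB·FOE)
    RQ_H = C / DWEL ≡ EDI / RfD

RQ_H < 0.2 no risk, 0.2–1 potential risk, ≥ 1 risk. The two RQ_H routes
are computed independently and must agree — the module's unit-consistency
contract.

**Multivariate stage** (`phenorisk.multivariate`) — balanced two-way
ANOVA with replication (setting × compound–season), Pearson correlations
tiered strong/moderate/weak at |r| = 0.70/0.50, and correlation-matrix PCA
with KMO and Bartlett's sphericity diagnostics, Kaiser eigenvalue > 1
retention, Kaiser-normalized varimax rotation and the |loading| ≥ 0.5
significance rule.

**Synthetic campaigns** (`phenorisk.campaign`) — a seeded generator for
the reference design (3 states × rural/urban × 10 sites × 3 replicates ×
2 seasons × 4 analytes = 1440 rows) with lognormal concentrations,
dry-season enrichment, structural zeros, LOD censoring, and pH/EC/TDS
covariates coupled to latent quinone contamination.

## Worked example

```python
from phenorisk import PipelineConfig, run_pipeline

results = run_pipeline(PipelineConfig().with_seed(1))
print(results["eco_exceedance"])
print(results["health_summary"])
```

prints

```
     class    n  pct_rq_above
0  overall  276     99.637681
1    acute  144     99.305556
2  chronic  132    100.000000
   group     n  pct_rq_ge_1  pct_rq_ge_0_2  pct_edi_above_rfd
0  adult  48.0    66.666667      95.833333          66.666667
1  child  48.0    81.250000     100.000000          81.250000
```

Under this simulated campaign every chronic ecological risk quotient
exceeds the benchmark of 1 (276 quotients across analytes, trophic levels
and state/setting/season groups), and children exceed the non-cancer risk
threshold in 81% of group-mean exposure cells versus 67% for adults —
children always carry 7/3 the adult intake per kg body weight. The
multivariate stage on the same run gives KMO 0.64, a significant
Bartlett test, and four rotated components explaining 88% of the
variance, with EC and TDS co-loading (≥ 0.5) alongside the quinones — the
leachate-mineralization signature the generator builds in. The scripts in
`examples/` walk through each stage with commentary, and a thin CLI
(`phenorisk simulate|qc|risk-eco|risk-human|stats|run-all`) wraps the same
functions for shell use.

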