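# Methods

## The monitoring model

The package models a seasonal groundwater monitoring campaign near
unmanaged dumpsites as a fully crossed factorial design: states × settings
(rural/urban) × sites × spatial replicates × seasons (rainy/dry) ×
analytes. Three units of analysis are used deliberately at different
stages:

- **replicate rows** are the unit for the two-way ANOVA "with
  replication" (the within-cell error term comes from them);
- **site means** (replicates averaged) are the unit for detection
  frequency, the correlation/PCA table, and the MEC summaries;
- **group means** (site means averaged within analyte × state × setting ×
  season) are the measured environmental concentrations entering the risk
  quotients, with a worst-case `statistic="max"` mode taking the highest
  site mean instead.

This reconciles a 10-sites-per-cell, 3-replicate design (60 field samples
per season and state) with multivariate analyses that operate on 10 site
rows per location.

## Synthetic campaign generator

Concentrations follow a lognormal–Bernoulli mixture. For analyte *a* at
site *s* in season *t*:

    log C = log_mean(a, state, setting) + season_effect·[t = dry]
            + u_s,a + e,     u ~ N(0, site_sd²),  e ~ N(0, replicate_sd²)

with probability `detect_prob_floor` the analyte is structurally absent at
a site (all its rows are zero and censored). Values below the analyte LOD
are censored and substituted per policy: `zero` (default — non-detects are
data and enter summaries as 0, so means never overstate the pollution
burden), `half_lod`, or `as_is` (flag only).

Defaults were chosen once to emulate the conditions such campaigns report:
geometric means ≈ 5 (BPA), 2 (HQ), 1.5 (RE), 1 (BQ) mg/L — the 0.5–20
mg/L order of magnitude — `season_effect = 0.7` (dry-season means roughly
double), `site_sd = 0.6`, `replicate_sd = 0.25`, `detect_prob_floor =
0.15` (detection frequencies in the 50–100% band after LOD censoring).
pH is truncated-normal N(6.8, 0.4²) on [4, 9]. EC (base 400 µS/cm) and
TDS (base 250 mg/L) are lognormal with their log means shifted by
`covariate_coupling` (default 1.0) times the latent mean site effect of
the quinones (HQ, BQ), plus independent 0.15-sd noise. That coupling is
what makes EC, TDS and the quinone variables co-load on one rotated
component — the leachate signature — and is the only deliberately
"mechanistic" element of the generator.

What the generator does **not** emulate: distance-to-source decay
(distance bands are metadata only), inter-analyte correlation beyond the
shared covariate latent, temporal autocorrelation within a season,
measurement error of the physicochemical meter, and any spatial structure
among sites. Tests passing on synthetic campaigns therefore demonstrate
correctness of the statistical machinery under the stated model, not
fidelity to any particular aquifer.

## Analytical QC conventions

- σ in LOD = 3σ/S is the OLS standard error of the intercept from a
  single calibration fit. Where a lab runs replicate curves,
  `sigma_from_replicate_curves` provides the sd-of-intercepts reading
  instead; the single-curve form is the default because one curve per
  analyte is the routine case. LOQ/LOD = 10/3 exactly whenever both come
  from one curve.
- The MDL uses the one-tailed Student's t at 99% confidence with n−1
  degrees of freedom (3.143 for the conventional seven replicates), the
  EPA 40 CFR 136 convention.
- RSD uses the sample (n−1) standard deviation.
- Detection is assessed at site level — mean of replicates at or above
  the LOD — with a replicate-level mode behind a flag. LOD and MDL are
  computed independently; nothing forces the packaged Table-style limits
  to share replicates.

## Risk quotients

- PNEC = endpoint / AF with AF 100 (acute) and 10 (chronic). Missing
  endpoints (resorcinol has no chronic algal NOEC) are omitted from both
  numerators and denominators — never imputed, never counted as
  non-exceedance. Range endpoints ("1–4") resolve to the lower bound and
  inequality endpoints ("≥ 0.066") to the stated bound; both carry a
  `qualifier` so the conservatism is visible downstream.
- Tier boundaries are strict on the upper side: RQ_E exactly 1.0 is
  medium, exactly 0.1 is minimal. Both the three-tier scheme and the
  levels of concern (0.5 acute / 1.0 chronic) are reported side by side.
- RQ_H is dimensionless only if the EDI numerator is expressed as its
  concentration equivalent; the package therefore computes RQ_H = C/DWEL
  and RQ_H = EDI/RfD — algebraically identical with FOE and AB applied
  symmetrically — and raises if they disagree beyond 1e-9 relative. The
  boundary RQ_H = 1.0 classifies as risk (≥ 1).
- Only the ingestion pathway is modelled; non-detects enter exposure as
  zero under the default policy with LOD/2 available as a sensitivity
  switch.

## Multivariate stage

- The ANOVA factor pair is setting (rural/urban) × compound–season
  (4 analytes × 2 seasons = 8 levels), run per state — a modelling choice
  that treats analyte and season as one crossed factor rather than a
  three-way design. Only balanced designs are accepted; the Type I
  decomposition on a balanced design equals the classical SS formulas
  (the test suite checks this against a direct cell/marginal-mean
  oracle). When the within-cell mean square is zero the F ratios are
  reported as NaN and the result is flagged degenerate.
- PCA standardizes variables to z-scores and eigendecomposes the
  correlation matrix, so eigenvalues sum to the number of variables and
  the Kaiser rule retains those above 1. Loadings are eigenvectors scaled
  by √eigenvalue.
- Varimax uses the SVD fixed-point iteration (the algorithm behind R's
  `varimax` and SPSS's rotation) with Kaiser row normalization,
  convergence when the criterion improves by less than 1e-6 relative, a
  100-sweep cap, and a deterministic start at the unrotated solution. The
  rotation matrix is orthogonal and communalities are preserved to 1e-8;
  each rotated component's dominant loading is made positive, and
  components are reordered by explained variance after rotation.
- KMO and Bartlett's sphericity are computed from the anti-image
  (inverse-correlation) matrix and −(n−1−(2p+5)/6)·ln det R respectively;
  no installed statistics package provides them, so they are implemented
  here with closed-form oracles in the tests. An exactly-identity
  correlation matrix makes KMO 0/0 and raises.
- The pipeline's default correlation/PCA table pools all sites (one row
  per site across every state × setting cell). A per-location PCA at 10
  sites against 11 variables has a singular correlation matrix (n ≤ p), so
  pooling is the smallest change that makes the diagnostics well defined;
  per-cell analyses remain available by slicing the wide table.
- p-values use α = 0.05 with no multiple-testing correction; rows with
  censored-as-zero values are retained (zeros are data under the default
  policy), with the censoring policy switchable in the pipeline config.

## Problem sizes and determinism

The test suite and the acceptance script run the reference design (1440
rows), 10⁴-draw identity checks, 50-site parameter-recovery campaigns and
200-observation planted-structure PCA; all complete in seconds. Every
stochastic operation takes an explicit seed (`numpy.random.default_rng`),
the pipeline records the seed and a configuration hash in its manifest,
and identical seeds reproduce every output byte for byte.

## Known limitations

- The generator's parameter recovery tolerances assume uncensored data;
  heavy censoring biases naive log-means, and no censored-likelihood
  estimator is provided.
- The half-LOD substitution ordering (zero ≤ half-LOD ≤ as-measured
  means) holds when the LOD sits in the lower tail of the concentration
  distribution, the regime of the default design; with the LOD near the
  bulk of the distribution the half-LOD mean can exceed the as-measured
  mean.
- Mixture toxicity, species-sensitivity distributions, probabilistic
  exposure and carcinogenic slope factors are out of scope, as are
  oblique rotations and maximum-likelihood factor analysis.
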