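"""Multivariate stage: two-way ANOVA, tiered Pearson correlation, and
correlation-matrix PCA with sampling-adequacy diagnostics and varimax
rotation.

The ANOVA is the classical balanced two-way decomposition with replication
(setting x compound-season in the pipeline); Pearson coefficients are
labelled strong (|r| >= 0.70), moderate (0.50 <= |r| < 0.70) or weak; PCA
operates on the correlation matrix of z-scored variables, retains
components by the Kaiser eigenvalue > 1 rule, rotates them with
Kaiser-normalized varimax, and reports KMO and Bartlett's sphericity test
so the factorability of the data is checked before interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "AnovaResult",
    "CorrelationReport",
    "PcaResult",
    "StatsError",
    "two_way_anova",
    "pearson_matrix",
    "correlation_tier",
    "kmo_statistic",
    "bartlett_sphericity",
    "varimax",
    "pca_varimax",
    "site_wide_table",
]


class StatsError(ValueError):
    """Invalid input to a statistical routine."""


# ---------------------------------------------------------------------------
# two-way ANOVA with replication


@dataclass(frozen=True)
class AnovaResult:
    """Classical sums-of-squares table for a balanced two-factor design."""

    table: pd.DataFrame  # rows: factor_a, factor_b, interaction, residual
    degenerate: bool  # True when the within-cell mean square is zero

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.loc[effect]


def two_way_anova(values, factor_a, factor_b) -> AnovaResult:
    """Two-way ANOVA with replication on a balanced crossed design.

    Requires >= 2 levels per factor, >= 2 replicates per cell, and equal
    cell counts (the monitoring design is balanced by construction;
    unbalanced data are rejected rather than silently reweighted).
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "a": np.asarray(factor_a, dtype=object),
            "b": np.asarray(factor_b, dtype=object),
        }
    )
    if df[["a"]].nunique().iloc[0] < 2 or df[["b"]].nunique().iloc[0] < 2:
        raise StatsError("need >= 2 levels per factor")
    counts = df.groupby(["a", "b"], sort=True).size()
    n_cells = df["a"].nunique() * df["b"].nunique()
    if len(counts) != n_cells:
        raise StatsError("empty cells: the design must be fully crossed")
    if counts.nunique() != 1:
        raise StatsError("unbalanced design (unequal cell counts) is unsupported")
    if int(counts.iloc[0]) < 2:
        raise StatsError("need >= 2 replicates per cell for a within-cell error term")

    fit = ols("y ~ C(a) * C(b)", data=df).fit()
    # Type I == classical decomposition on a balanced design
    aov = sm.stats.anova_lm(fit, typ=1)
    aov = aov.rename(
        index={
            "C(a)": "factor_a",
            "C(b)": "factor_b",
            "C(a):C(b)": "interaction",
            "Residual": "residual",
        }
    )
    table = aov.rename(
        columns={"sum_sq": "sum_of_squares", "F": "f_statistic", "PR(>F)": "p_value"}
    )
    table["mean_square"] = table["sum_of_squares"] / table["df"]
    degenerate = bool(np.isclose(table.loc["residual", "mean_square"], 0.0))
    if degenerate:
        table.loc[table.index != "residual", ["f_statistic", "p_value"]] = np.nan
    table = table[["sum_of_squares", "df", "mean_square", "f_statistic", "p_value"]]
    return AnovaResult(table=table, degenerate=degenerate)


# ---------------------------------------------------------------------------
# Pearson correlation with tier labels


def correlation_tier(r: float) -> str:
    if np.isnan(r):
        return "undefined"
    a = abs(r)
    if a >= 0.70:
        return "strong"
    if a >= 0.50:
        return "moderate"
    return "weak"


@dataclass(frozen=True)
class CorrelationReport:
    matrix: pd.DataFrame
    tiers: pd.DataFrame

    @property
    def variables(self) -> list[str]:
        return list(self.matrix.columns)


def pearson_matrix(data: pd.DataFrame) -> CorrelationReport:
    """Pairwise product-moment correlations with tier labels.

    Zero-variance variables yield NaN correlations flagged ``undefined``
    for all their pairs rather than an exception, so one degenerate column
    does not take down the whole report.
    """
    if len(data) < 3:
        raise StatsError("need >= 3 observations for a correlation matrix")
    r = data.corr(method="pearson")
    # pandas leaves a 1.0 diagonal even for constant columns; make those NaN
    const = data.std(ddof=1) == 0
    for v in data.columns[const]:
        r.loc[v, :] = np.nan
        r.loc[:, v] = np.nan
    tiers = r.copy().astype(object)
    for i in r.index:
        for j in r.columns:
            tiers.loc[i, j] = "" if i == j else correlation_tier(r.loc[i, j])
    return CorrelationReport(matrix=r, tiers=tiers)


# ---------------------------------------------------------------------------
# sampling adequacy


def _as_corr(matrix) -> np.ndarray:
    R = np.asarray(matrix, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise StatsError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise StatsError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise StatsError("correlation matrix must have a unit diagonal")
    return R


def kmo_statistic(matrix) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over off-diagonal pairs,
    where q are the anti-image partial correlations obtained from the
    inverse correlation matrix. Identity input (no correlation at all) is
    a 0/0 form and raises.
    """
    R = _as_corr(matrix)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise StatsError(
            "singular correlation matrix; drop collinear variables or regularize"
        ) from exc
    d = 1.0 / np.sqrt(np.diag(Rinv))
    partial = -Rinv * np.outer(d, d)
    off = ~np.eye(R.shape[0], dtype=bool)
    ssr = float(np.sum(R[off] ** 2))
    ssq = float(np.sum(partial[off] ** 2))
    if ssr + ssq == 0:
        raise StatsError("KMO undefined for an identity correlation matrix")
    return ssr / (ssr + ssq)


def bartlett_sphericity(matrix, n: int) -> tuple[float, int, float]:
    """Bartlett's test of sphericity against R = I.

    chi2 = -(n - 1 - (2p + 5)/6) * ln det(R), df = p(p-1)/2. Requires more
    observations than variables and a positive-definite matrix.
    """
    R = _as_corr(matrix)
    p = R.shape[0]
    if n <= p:
        raise StatsError("need more observations than variables")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise StatsError("correlation matrix is not positive definite")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    dof = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, dof))
    return float(chi2), int(dof), pval


# ---------------------------------------------------------------------------
# PCA with varimax rotation


def varimax(
    loadings,
    kaiser_normalize: bool = True,
    tol: float = 1e-6,
    max_sweeps: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loading matrix (variables x components).

    Maximizes the variance of squared loadings under an orthogonal rotation,
    with Kaiser row normalization (rows scaled to unit communality before
    rotating, unscaled after). Deterministic: starts at the identity
    rotation and iterates the SVD fixed-point update until the criterion
    changes by less than ``tol`` (relative) or ``max_sweeps`` is reached.
    Returns ``(rotated_loadings, rotation_matrix)``.
    """
    L = np.asarray(loadings, dtype=float)
    if L.ndim != 2:
        raise StatsError("loadings must be 2-D")
    p, k = L.shape
    if k == 1:
        return L.copy(), np.eye(1)
    h = np.sqrt(np.sum(L**2, axis=1))
    if kaiser_normalize:
        if np.any(h == 0):
            raise StatsError("zero-communality row; cannot Kaiser-normalize")
        W = L / h[:, None]
    else:
        W = L.copy()
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_sweeps):
        Lr = W @ R
        u, s, vt = np.linalg.svd(
            W.T @ (Lr**3 - Lr @ np.diag(np.sum(Lr**2, axis=0)) / p)
        )
        R = u @ vt
        d_new = float(np.sum(s))
        if d_old > 0 and d_new < d_old * (1.0 + tol):
            break
        d_old = d_new
    out = W @ R
    if kaiser_normalize:
        out = out * h[:, None]
    # sign convention: dominant loading of each component is positive
    for j in range(k):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
            R[:, j] = -R[:, j]
    return out, R


@dataclass(frozen=True)
class PcaResult:
    eigenvalues: np.ndarray  # all p, descending
    loadings: pd.DataFrame  # unrotated, variables x retained components
    rotated_loadings: pd.DataFrame
    pct_variance: np.ndarray  # per retained component, after rotation
    cumulative_pct: np.ndarray
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    significant: pd.DataFrame  # |rotated loading| >= threshold
    n_observations: int


def pca_varimax(
    data: pd.DataFrame,
    retain: str | int = "kaiser",
    loading_threshold: float = 0.5,
) -> PcaResult:
    """Correlation-matrix PCA with Kaiser retention and varimax rotation.

    Variables are z-scored internally; eigenvalues therefore sum to the
    number of variables and the Kaiser rule retains those above 1.
    Loadings are eigenvectors scaled by sqrt(eigenvalue); percent variance
    after rotation is the column sum of squared rotated loadings over p.
    """
    if data.shape[1] < 2:
        raise StatsError("need >= 2 variables")
    n = len(data)
    if n <= 2:
        raise StatsError("need more than 2 observations")
    sd = data.std(ddof=1)
    if (sd == 0).any():
        bad = list(data.columns[sd == 0])
        raise StatsError(f"constant variables cannot enter PCA: {bad}")
    R = np.corrcoef(((data - data.mean()) / sd).to_numpy(), rowvar=False)
    p = R.shape[0]
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)

    if retain == "kaiser":
        k = int(np.sum(evals > 1.0))
    else:
        k = int(retain)
    if k < 1:
        raise StatsError("retention rule keeps zero components")
    k = min(k, p)
    load = evecs[:, :k] * np.sqrt(evals[:k])
    rotated, _ = varimax(load)
    pct = 100.0 * np.sum(rotated**2, axis=0) / p
    # order rotated components by explained variance, descending
    order_r = np.argsort(pct)[::-1]
    rotated, pct = rotated[:, order_r], pct[order_r]

    cols = [f"PC{i + 1}" for i in range(k)]
    idx = list(data.columns)
    kmo = kmo_statistic(R)
    chi2, dof, pval = bartlett_sphericity(R, n)
    rotated_df = pd.DataFrame(rotated, index=idx, columns=cols)
    return PcaResult(
        eigenvalues=evals,
        loadings=pd.DataFrame(load, index=idx, columns=cols),
        rotated_loadings=rotated_df,
        pct_variance=pct,
        cumulative_pct=np.cumsum(pct),
        kmo=kmo,
        bartlett_chi2=chi2,
        bartlett_df=dof,
        bartlett_p=pval,
        significant=rotated_df.abs() >= loading_threshold,
        n_observations=n,
    )


# ---------------------------------------------------------------------------
# wide site table for correlation / PCA


def site_wide_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """One row per site: analyte-season mean concentrations plus mean
    physicochemical covariates, the layout the correlation and PCA stages
    consume. Column names are ``<analyte>_<R|D>`` using the first letter of
    the season label, capitalized."""
    if measurements.empty:
        raise StatsError("empty measurement table")
    df = measurements.copy()
    df["var"] = df["analyte"] + "_" + df["season"].str[0].str.upper()
    site_keys = ["state", "setting", "site_id"]
    conc = (
        df.groupby(site_keys + ["var"], sort=True)["concentration_mg_L"]
        .mean()
        .unstack("var")
    )
    phys = (
        df.drop_duplicates(site_keys + ["season", "replicate_id"])
        .groupby(site_keys, sort=True)[["ph", "ec_uS_cm", "tds_mg_L"]]
        .mean()
        .rename(columns={"ec_uS_cm": "EC", "tds_mg_L": "TDS", "ph": "pH"})
    )
    return conc.join(phys).reset_index()
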