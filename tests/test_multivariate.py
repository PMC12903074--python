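"""Two-way ANOVA, tiered Pearson correlation, KMO/Bartlett diagnostics and
varimax-rotated PCA."""

import math

import numpy as np
import pandas as pd
import pytest

from phenorisk import (
    CampaignDesign,
    GenerativeParams,
    bartlett_sphericity,
    generate_campaign,
    kmo_statistic,
    pca_varimax,
    pearson_matrix,
    site_wide_table,
    two_way_anova,
    varimax,
)
from phenorisk.multivariate import StatsError, correlation_tier


# ---------------------------------------------------------------------------
# brute-force two-way ANOVA oracle: cell/marginal mean decomposition


def anova_oracle(y, a, b):
    """Classical balanced decomposition computed directly from means."""
    df = pd.DataFrame({"y": np.asarray(y, float), "a": a, "b": b})
    grand = df["y"].mean()
    A = sorted(df["a"].unique())
    B = sorted(df["b"].unique())
    n = len(df) // (len(A) * len(B))
    ma = df.groupby("a")["y"].mean()
    mb = df.groupby("b")["y"].mean()
    mab = df.groupby(["a", "b"])["y"].mean()
    ss_a = n * len(B) * sum((ma[i] - grand) ** 2 for i in A)
    ss_b = n * len(A) * sum((mb[j] - grand) ** 2 for j in B)
    ss_ab = n * sum(
        (mab[(i, j)] - ma[i] - mb[j] + grand) ** 2 for i in A for j in B
    )
    ss_w = sum(
        (row.y - mab[(row.a, row.b)]) ** 2 for row in df.itertuples()
    )
    df_a, df_b = len(A) - 1, len(B) - 1
    df_ab = df_a * df_b
    df_w = len(df) - len(A) * len(B)
    return {
        "factor_a": (ss_a, df_a, ss_a / df_a / (ss_w / df_w)),
        "factor_b": (ss_b, df_b, ss_b / df_b / (ss_w / df_w)),
        "interaction": (ss_ab, df_ab, ss_ab / df_ab / (ss_w / df_w)),
        "residual": (ss_w, df_w, None),
    }


def _design(n_a, n_b, n_rep, values):
    a = np.repeat([f"a{i}" for i in range(n_a)], n_b * n_rep)
    b = np.tile(np.repeat([f"b{j}" for j in range(n_b)], n_rep), n_a)
    return values, a, b


class TestTwoWayAnova:
    @pytest.mark.parametrize("shape", [(2, 2, 2), (2, 3, 2), (2, 3, 3), (3, 3, 3)])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, shape, seed):
        n_a, n_b, n_rep = shape
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 10, size=n_a * n_b * n_rep).astype(float)
        y, a, b = _design(n_a, n_b, n_rep, y)
        if np.ptp(y) == 0:  # degenerate draw; covered elsewhere
            y[0] += 1.0
        res = two_way_anova(y, a, b)
        oracle = anova_oracle(y, a, b)
        total = sum(v[0] for v in oracle.values())
        assert res.table["sum_of_squares"].sum() == pytest.approx(total, rel=1e-10)
        for effect, (ss, dof, f) in oracle.items():
            row = res.table.loc[effect]
            assert row["sum_of_squares"] == pytest.approx(ss, rel=1e-9, abs=1e-9)
            assert row["df"] == dof
            if f is not None:
                assert row["f_statistic"] == pytest.approx(f, rel=1e-9, abs=1e-9)
        # p-values come from the F distribution
        from scipy import stats as sps

        fa = res.table.loc["factor_a"]
        assert fa["p_value"] == pytest.approx(
            sps.f.sf(fa["f_statistic"], fa["df"], res.table.loc["residual", "df"]),
            rel=1e-9,
        )

    def test_additive_cell_means_have_zero_interaction(self):
        # 2x2, zero noise, additive means -> SS_AB = 0
        means = {("a0", "b0"): 1.0, ("a0", "b1"): 3.0, ("a1", "b0"): 2.0, ("a1", "b1"): 4.0}
        rows = [(v + d, a, b) for (a, b), v in means.items() for d in (0.01, -0.01)]
        y, a, b = zip(*rows)
        res = two_way_anova(y, a, b)
        assert res.table.loc["interaction", "sum_of_squares"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_data_flagged_degenerate(self):
        y, a, b = _design(2, 2, 3, np.full(12, 5.0))
        res = two_way_anova(y, a, b)
        assert res.degenerate
        assert res.table["sum_of_squares"].sum() == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(res.table.loc["factor_a", "f_statistic"])

    def test_design_validation(self):
        y, a, b = _design(2, 2, 2, np.arange(8.0))
        with pytest.raises(StatsError):  # unbalanced
            two_way_anova(y[:-1], a[:-1], b[:-1])
        with pytest.raises(StatsError):  # single replicate
            two_way_anova(*_design(2, 2, 1, np.arange(4.0)))
        with pytest.raises(StatsError):  # one level
            two_way_anova(*_design(1, 2, 3, np.arange(6.0)))


class TestPearson:
    def test_perfect_line_is_strong(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "y": 2 * x + 1})
        rep = pearson_matrix(df)
        assert rep.matrix.loc["x", "y"] == pytest.approx(1.0)
        assert rep.tiers.loc["x", "y"] == "strong"

    @pytest.mark.parametrize(
        "r, tier",
        [(0.70, "strong"), (0.699, "moderate"), (0.50, "moderate"),
         (0.499, "weak"), (-0.85, "strong"), (0.0, "weak")],
    )
    def test_tier_boundaries_inclusive(self, r, tier):
        assert correlation_tier(r) == tier

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        df = pd.DataFrame({"x": x, "y": y})
        r0 = pearson_matrix(df).matrix.loc["x", "y"]
        r_pos = pearson_matrix(pd.DataFrame({"x": 3 * x + 7, "y": y})).matrix.loc["x", "y"]
        r_neg = pearson_matrix(pd.DataFrame({"x": -2 * x + 1, "y": y})).matrix.loc["x", "y"]
        assert r_pos == pytest.approx(r0, rel=1e-12)
        assert r_neg == pytest.approx(-r0, rel=1e-12)

    def test_independent_variables_are_weak(self):
        rng = np.random.default_rng(42)
        df = pd.DataFrame(rng.normal(size=(2000, 3)), columns=list("abc"))
        rep = pearson_matrix(df)
        off = rep.matrix.values[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.1
        assert (rep.tiers.loc["a", "b"]) == "weak"

    def test_zero_variance_column_flagged_undefined(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        rep = pearson_matrix(df)
        assert np.isnan(rep.matrix.loc["x", "c"])
        assert rep.tiers.loc["x", "c"] == "undefined"

    def test_too_few_observations(self):
        with pytest.raises(StatsError):
            pearson_matrix(pd.DataFrame({"x": [1.0, 2.0], "y": [3.0, 4.0]}))


class TestKmo:
    def test_two_variable_closed_form(self):
        # p = 2: the partial correlation equals r, so KMO = r^2/(2 r^2) = 0.5
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert kmo_statistic(R) == pytest.approx(0.5, rel=1e-12)

    def test_near_identity_is_near_zero(self):
        R = np.eye(4)
        R[0, 1] = R[1, 0] = 1e-4
        assert kmo_statistic(R) < 0.51  # p=2-like structure on one pair
        R2 = np.eye(4) + 0.0
        with pytest.raises(StatsError):  # exactly identity: 0/0
            kmo_statistic(R2)

    def test_compound_symmetry_against_closed_form_inverse(self):
        p, rho = 4, 0.8
        R = (1 - rho) * np.eye(p) + rho * np.ones((p, p))
        # closed-form inverse of a compound-symmetry matrix
        alpha = 1.0 / (1 - rho)
        beta = -rho / ((1 - rho) * (1 + (p - 1) * rho))
        Rinv = alpha * np.eye(p) + beta * np.ones((p, p))
        np.testing.assert_allclose(Rinv, np.linalg.inv(R), atol=1e-12)
        diag = np.diag(Rinv)
        partial = -Rinv[0, 1] / math.sqrt(diag[0] * diag[1])
        n_off = p * (p - 1)
        expected = (n_off * rho**2) / (n_off * rho**2 + n_off * partial**2)
        assert kmo_statistic(R) == pytest.approx(expected, rel=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 5))
        X[:, 1] += X[:, 0]
        X[:, 3] += 0.5 * X[:, 2]
        R = np.corrcoef(X, rowvar=False)
        perm = [3, 0, 4, 1, 2]
        assert kmo_statistic(R[np.ix_(perm, perm)]) == pytest.approx(
            kmo_statistic(R), rel=1e-10
        )

    def test_singular_matrix_raises(self):
        R = np.ones((3, 3))
        with pytest.raises(StatsError):
            kmo_statistic(R)


class TestBartlett:
    def test_identity_gives_zero_statistic(self):
        chi2, dof, p = bartlett_sphericity(np.eye(5), n=100)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert dof == 10
        assert p == pytest.approx(1.0)

    def test_two_variable_closed_form(self):
        # det R = 1 - r^2; chi2 = -(n - 1 - (2p+5)/6) ln det
        r, n = 0.9, 30
        R = np.array([[1.0, r], [r, 1.0]])
        chi2, dof, p = bartlett_sphericity(R, n)
        assert chi2 == pytest.approx(-(29 - 9 / 6) * math.log(1 - 0.81), rel=1e-12)
        assert dof == 1
        assert p < 0.001

    def test_monotone_in_correlation_strength(self):
        chis = []
        for r in (0.1, 0.3, 0.5, 0.7, 0.9):
            R = np.array([[1.0, r], [r, 1.0]])
            chis.append(bartlett_sphericity(R, 30)[0])
        assert chis == sorted(chis)

    def test_requires_more_observations_than_variables(self):
        with pytest.raises(StatsError):
            bartlett_sphericity(np.eye(5), n=5)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 4))
        X[:, 1] += X[:, 0]
        R = np.corrcoef(X, rowvar=False)
        perm = [2, 0, 3, 1]
        assert bartlett_sphericity(R[np.ix_(perm, perm)], 50)[0] == pytest.approx(
            bartlett_sphericity(R, 50)[0], rel=1e-10
        )


class TestVarimax:
    def _random_loadings(self, seed, p=8, k=3):
        rng = np.random.default_rng(seed)
        L = rng.normal(size=(p, k)) * np.array([1.0, 0.7, 0.5])
        return L

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_preserves_communalities_and_orthogonality(self, seed):
        L = self._random_loadings(seed)
        rotated, R = varimax(L)
        np.testing.assert_allclose(R.T @ R, np.eye(R.shape[1]), atol=1e-8)
        np.testing.assert_allclose(
            np.sum(rotated**2, axis=1), np.sum(L**2, axis=1), atol=1e-8
        )

    def test_criterion_does_not_decrease(self):
        def criterion(L):
            s = L**2
            return float(np.sum(s**2) - np.sum(s, axis=0) ** 2 @ np.ones(L.shape[1]) / L.shape[0])

        L = self._random_loadings(7)
        h = np.sqrt((L**2).sum(axis=1))
        rotated, _ = varimax(L)
        assert criterion(rotated / h[:, None]) >= criterion(L / h[:, None]) - 1e-10

    def test_sign_convention_dominant_loading_positive(self):
        rotated, _ = varimax(self._random_loadings(5))
        for j in range(rotated.shape[1]):
            assert rotated[np.argmax(np.abs(rotated[:, j])), j] > 0

    def test_single_component_is_identity(self):
        L = np.array([[0.9], [0.8], [-0.7]])
        rotated, R = varimax(L)
        np.testing.assert_allclose(rotated, L)
        assert R.shape == (1, 1)


def _block_data(n=200, noise=0.3, seed=0):
    """Three orthogonal latent factors, each driving a disjoint 3-variable block."""
    rng = np.random.default_rng(seed)
    F = rng.normal(size=(n, 3))
    X = np.empty((n, 9))
    for j in range(9):
        X[:, j] = F[:, j // 3] + noise * rng.normal(size=n)
    return pd.DataFrame(X, columns=[f"v{j}" for j in range(9)])


class TestPca:
    def test_eigenvalues_sum_to_variable_count(self):
        df = _block_data()
        res = pca_varimax(df, retain=3)
        assert res.eigenvalues.sum() == pytest.approx(9.0, rel=1e-10)

    def test_exactly_uncorrelated_pair_is_isotropic(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        y = y - np.polyval(np.polyfit(x, y, 1), x)  # exact sample r = 0
        df = pd.DataFrame({"x": x, "y": y})
        res = pca_varimax(df, retain=2)
        np.testing.assert_allclose(res.eigenvalues, [1.0, 1.0], atol=1e-10)
        # rotation of an isotropic solution is identity up to sign/permutation
        np.testing.assert_allclose(
            np.abs(res.rotated_loadings.to_numpy()), np.eye(2), atol=1e-8
        )
        # no eigenvalue exceeds 1: the Kaiser rule retains nothing
        with pytest.raises(StatsError):
            pca_varimax(df, retain="kaiser")

    def test_planted_three_block_structure_recovered(self):
        df = _block_data(seed=11)
        res = pca_varimax(df, retain="kaiser")
        L = res.rotated_loadings
        assert L.shape[1] == 3
        for blk in range(3):
            cols = [f"v{3 * blk + i}" for i in range(3)]
            # the block loads >= 0.5 together on exactly one rotated component
            hits = [
                c for c in L.columns if (L.loc[cols, c].abs() >= 0.5).all()
            ]
            assert len(hits) == 1
        assert res.cumulative_pct[-1] > 70.0

    def test_constant_variable_rejected(self):
        df = _block_data()
        df["const"] = 1.0
        with pytest.raises(StatsError):
            pca_varimax(df)

    def test_diagnostics_reported(self):
        df = _block_data()
        res = pca_varimax(df, retain=3)
        assert 0.5 < res.kmo <= 1.0
        assert res.bartlett_df == 36
        assert res.bartlett_p < 1e-6
        assert res.significant.shape == res.rotated_loadings.shape


class TestCampaignStats:
    def test_site_wide_table_layout(self, default_campaign):
        wide = site_wide_table(default_campaign)
        assert len(wide) == 60  # 3 states x 2 settings x 10 sites
        for col in ("BPA_R", "BPA_D", "HQ_R", "HQ_D", "pH", "EC", "TDS"):
            assert col in wide.columns

    def test_ec_tds_coload_with_quinones(self, default_campaign):
        # the generator couples EC/TDS to latent quinone contamination, so
        # one rotated component must carry EC, TDS and quinone variables
        wide = site_wide_table(default_campaign)
        res = pca_varimax(wide.drop(columns=["state", "setting", "site_id"]))
        L = res.rotated_loadings
        found = False
        for c in L.columns:
            if L.loc["EC", c] >= 0.5 and L.loc["TDS", c] >= 0.5:
                quinone_hits = sum(
                    abs(L.loc[v, c]) >= 0.5 for v in ("HQ_R", "HQ_D", "BQ_R", "BQ_D")
                )
                if quinone_hits >= 2:
                    found = True
        assert found
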