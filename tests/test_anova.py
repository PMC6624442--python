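"""Within-subject ANOVA: SS decomposition, effect sizes, sphericity."""

import numpy as np
import pytest
from scipy import stats

import illusim as il
from illusim.anova import (
    EPSILON_METHODS,
    corrected_p,
    orthonormal_contrast,
    partial_eta_squared,
    sphericity_epsilon,
)


def projection_ss(wide):
    """Independent SS oracle: orthogonal projections via Kronecker products.

    y is vectorised subject-major; each stratum's SS is y' P y with P a
    Kronecker product of centering (C) and averaging (J) matrices.
    """
    n, a, b = wide.shape
    y = wide.reshape(-1)

    def J(k):
        return np.full((k, k), 1.0 / k)

    def C(k):
        return np.eye(k) - J(k)

    def ss(ms, ma, mb):
        p = np.kron(np.kron(ms, ma), mb)
        return float(y @ p @ y)

    return {
        "shadow": ss(J(n), C(a), J(b)),
        "orientation": ss(J(n), J(a), C(b)),
        "interaction": ss(J(n), C(a), C(b)),
        "subject": ss(C(n), J(a), J(b)),
        "shadow_x_subject": ss(C(n), C(a), J(b)),
        "orientation_x_subject": ss(C(n), J(a), C(b)),
        "interaction_x_subject": ss(C(n), C(a), C(b)),
    }


@pytest.fixture(scope="module")
def random_table():
    rng = np.random.default_rng(314)
    wide = rng.normal(100, 2, size=(6, 2, 5))
    return il.PSETable.from_wide(wide, angles=[-60, -30, 0, 30, 60])


class TestDecomposition:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_projection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        wide = rng.normal(100, 2, size=(6, 2, 5))
        res = il.two_way_rm_anova(wide)
        oracle = projection_ss(wide)
        for effect, err_key in [
            ("shadow", "shadow_x_subject"),
            ("orientation", "orientation_x_subject"),
            ("interaction", "interaction_x_subject"),
        ]:
            eff = res[effect]
            assert eff.ss_effect == pytest.approx(
                oracle[effect], rel=1e-10, abs=1e-10
            )
            assert eff.ss_error == pytest.approx(
                oracle[err_key], rel=1e-10, abs=1e-10
            )
        assert res.ss_subject == pytest.approx(oracle["subject"], rel=1e-10)

    def test_total_ss_is_conserved(self, random_table):
        res = il.two_way_rm_anova(random_table)
        parts = res.ss_subject + sum(
            res[e].ss_effect + res[e].ss_error
            for e in ("shadow", "orientation", "interaction")
        )
        assert parts == pytest.approx(res.ss_total, rel=1e-8)

    def test_two_level_f_equals_squared_paired_t(self, random_table):
        """For a 2-level within factor, F is the square of the paired t."""
        wide = random_table.to_wide()
        res = il.two_way_rm_anova(random_table)
        shadow_means = wide.mean(axis=2)  # (subjects, 2)
        t, p = stats.ttest_rel(shadow_means[:, 1], shadow_means[:, 0])
        assert res["shadow"].f_stat == pytest.approx(t**2, rel=1e-10)
        assert res["shadow"].p_uncorrected == pytest.approx(p, rel=1e-10)

    def test_matches_pingouin(self, random_table):
        """Cross-check against an independent implementation."""
        pg = pytest.importorskip("pingouin")
        out = pg.rm_anova(
            data=random_table.frame, dv="pse", within=["shadow", "angle"],
            subject="subject", detailed=True,
        ).set_index("Source")
        res = il.two_way_rm_anova(random_table)
        for mine, theirs in [
            ("shadow", "shadow"),
            ("orientation", "angle"),
            ("interaction", "shadow * angle"),
        ]:
            assert res[mine].f_stat == pytest.approx(out.loc[theirs, "F"])
            assert res[mine].p_uncorrected == pytest.approx(
                out.loc[theirs, "p_unc"]
            )

    def test_identical_cells_give_degenerate_zero_f(self):
        wide = np.full((6, 2, 5), 100.0)
        res = il.two_way_rm_anova(wide)
        for e in ("shadow", "orientation", "interaction"):
            assert res[e].ss_effect == 0.0
            assert res[e].f_stat == 0.0
            assert res[e].degenerate


class TestPartialEtaSquared:
    @pytest.mark.parametrize(
        "f, df1, df2, expected",
        [
            (35.45, 1, 19, 0.651),
            (126.89, 1, 19, 0.870),
            (0.0, 4, 76, 0.0),
        ],
    )
    def test_from_f_and_dfs(self, f, df1, df2, expected):
        assert round(partial_eta_squared(f, df1, df2), 3) == expected

    def test_equals_ss_ratio(self, random_table):
        res = il.two_way_rm_anova(random_table)
        for e in ("shadow", "orientation", "interaction"):
            eff = res[e]
            from_f = partial_eta_squared(eff.f_stat, eff.df1, eff.df2)
            from_ss = eff.ss_effect / (eff.ss_effect + eff.ss_error)
            assert from_f == pytest.approx(from_ss, rel=1e-12)

    def test_rejects_negative_input(self):
        with pytest.raises(ValueError):
            partial_eta_squared(-1.0, 1, 19)


class TestSphericityEpsilon:
    @pytest.mark.parametrize("method", EPSILON_METHODS)
    def test_two_levels_always_one(self, method):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(12, 2))
        assert sphericity_epsilon(data, method) == 1.0

    def test_compound_symmetry_gives_gg_one(self):
        """Equal variances + equal covariances satisfy sphericity exactly."""
        rng = np.random.default_rng(1)
        k, n = 5, 40
        z = rng.normal(size=(n, k))
        z -= z.mean(axis=0)
        # whiten so the sample covariance is exactly the identity
        cov = np.cov(z, rowvar=False)
        z = z @ np.linalg.inv(np.linalg.cholesky(cov)).T
        rho, var = 0.4, 2.0
        cs = var * ((1 - rho) * np.eye(k) + rho * np.ones((k, k)))
        data = z @ np.linalg.cholesky(cs).T
        assert sphericity_epsilon(data, "gg") == pytest.approx(1.0, abs=1e-10)

    def test_gg_matches_eigenvalue_oracle(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(20, 5)) @ rng.normal(size=(5, 5))
        contrast = orthonormal_contrast(5)
        s = contrast.T @ np.cov(data, rowvar=False) @ contrast
        lam = np.linalg.eigvalsh(s)
        oracle = lam.sum() ** 2 / (4 * (lam**2).sum())
        assert sphericity_epsilon(data, "gg") == pytest.approx(
            oracle, rel=1e-10
        )

    def test_gg_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        data = rng.normal(size=(20, 5)) @ rng.normal(size=(5, 5))
        theirs = pg.epsilon(pd.DataFrame(data), correction="gg")
        assert sphericity_epsilon(data, "gg") == pytest.approx(theirs)

    @pytest.mark.parametrize("method", EPSILON_METHODS)
    def test_bounds(self, method):
        rng = np.random.default_rng(11)
        for _ in range(20):
            k = int(rng.integers(3, 7))
            data = rng.normal(size=(15, k)) @ rng.normal(size=(k, k))
            eps = sphericity_epsilon(data, method)
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_hf_and_cm_coincide_for_single_group(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(20, 5)) @ rng.normal(size=(5, 5))
        assert sphericity_epsilon(data, "hf") == sphericity_epsilon(data, "cm")

    def test_rejects_single_level(self):
        with pytest.raises(ValueError):
            sphericity_epsilon(np.ones((10, 1)))


class TestCorrectedP:
    def test_epsilon_one_is_uncorrected(self):
        f, df1, df2 = 2.5, 4, 76
        assert corrected_p(f, df1, df2, 1.0) == pytest.approx(
            stats.f.sf(f, df1, df2)
        )

    def test_zero_f_gives_p_one(self):
        assert corrected_p(0.0, 4, 76, 0.9) == pytest.approx(1.0)

    def test_rejects_out_of_range_epsilon(self):
        with pytest.raises(ValueError):
            corrected_p(1.0, 4, 76, 0.0)
        with pytest.raises(ValueError):
            corrected_p(1.0, 4, 76, 1.2)

    def test_shrinking_dfs_weakens_evidence(self):
        f, df1, df2 = 2.0, 4, 76
        ps = [corrected_p(f, df1, df2, e) for e in (1.0, 0.8, 0.6, 0.4)]
        assert ps == sorted(ps)
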