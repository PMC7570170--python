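import numpy as np
import pytest

from diallelkit import anova, griffing
from diallelkit.errors import DesignError, EstimationError
from diallelkit.io import EntryMeanTable, means_to_entry_table, per_environment_means
from diallelkit.traits import add_trait_columns


def random_table(p, rng, trait="hmf"):
    parents = [f"P{i}" for i in range(p)]
    return EntryMeanTable(trait, parents, rng.normal(25, 8, (p, p)))


def constrained_ls_oracle(x):
    """Fit mu, g, s, r by least squares with explicit zero-sum constraints.

    Builds the full design over the p^2 cells with parameters
    (mu, g_1..g_p, s_ij for i<=j, r_ij for i<j) and solves the KKT system
    with constraints sum(g)=0 and sum_j s_ij = 0 for each i.  Completely
    independent of the closed forms under test.
    """
    p = x.shape[0]
    g_ix = {i: 1 + i for i in range(p)}
    s_ix, k = {}, 1 + p
    for i in range(p):
        for j in range(i, p):
            s_ix[(i, j)] = k
            k += 1
    r_ix = {}
    for i in range(p):
        for j in range(i + 1, p):
            r_ix[(i, j)] = k
            k += 1
    nparam = k
    X = np.zeros((p * p, nparam))
    y = np.zeros(p * p)
    row = 0
    for i in range(p):
        for j in range(p):
            X[row, 0] = 1.0
            X[row, g_ix[i]] += 1.0
            X[row, g_ix[j]] += 1.0
            X[row, s_ix[(min(i, j), max(i, j))]] += 1.0
            if i < j:
                X[row, r_ix[(i, j)]] += 1.0
            elif j < i:
                X[row, r_ix[(j, i)]] -= 1.0
            y[row] = x[i, j]
            row += 1
    C = np.zeros((1 + p, nparam))
    C[0, 1 : 1 + p] = 1.0  # sum g = 0
    for i in range(p):  # sum_j s_ij = 0 (over all j incl. j = i)
        for j in range(p):
            C[1 + i, s_ix[(min(i, j), max(i, j))]] += 1.0
    KKT = np.block(
        [[X.T @ X, C.T], [C, np.zeros((C.shape[0], C.shape[0]))]]
    )
    rhs = np.concatenate([X.T @ y, np.zeros(C.shape[0])])
    sol = np.linalg.solve(KKT, rhs)[:nparam]
    mu = sol[0]
    g = sol[1 : 1 + p]
    s = np.zeros((p, p))
    for (i, j), ix in s_ix.items():
        s[i, j] = s[j, i] = sol[ix]
    r = np.zeros((p, p))
    for (i, j), ix in r_ix.items():
        r[i, j] = sol[ix]
        r[j, i] = -sol[ix]
    return mu, g, s, r


class TestEffects:
    def test_constant_table_gives_only_grand_effect(self):
        t = EntryMeanTable("hmf", list("ABCD"), np.full((4, 4), 17.5))
        eff = griffing.estimate_effects(t)
        assert eff.mu == pytest.approx(17.5)
        for arr in (eff.gca, eff.sca, eff.reciprocal, eff.maternal, eff.nonmaternal):
            assert np.allclose(arr, 0.0, atol=1e-12)

    def test_additive_table_yields_pure_gca(self):
        a = np.array([3.0, -1.0, 5.0, 9.0])
        x = a[:, None] + a[None, :] + 20.0
        eff = griffing.estimate_effects(EntryMeanTable("hf", list("ABCD"), x))
        assert np.allclose(eff.gca, a - a.mean(), atol=1e-12)
        assert np.allclose(eff.sca, 0.0, atol=1e-12)
        assert np.allclose(eff.reciprocal, 0.0, atol=1e-12)

    @pytest.mark.parametrize("p", [3, 4, 5])
    def test_closed_forms_match_constrained_ls_oracle(self, p):
        rng = np.random.default_rng(100 + p)
        t = random_table(p, rng)
        eff = griffing.estimate_effects(t)
        mu, g, s, r = constrained_ls_oracle(t.values)
        assert eff.mu == pytest.approx(mu, abs=1e-10)
        np.testing.assert_allclose(eff.gca, g, atol=1e-10)
        np.testing.assert_allclose(eff.sca, s, atol=1e-10)
        np.testing.assert_allclose(eff.reciprocal, r, atol=1e-10)

    def test_zero_sum_and_reconstruction_on_many_random_tables(self):
        """Effect constraints and exact cell reconstruction hold on 1000
        random mean tables (the decomposition is saturated)."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = int(rng.integers(3, 9))
            t = random_table(p, rng)
            eff = griffing.estimate_effects(t)
            assert abs(eff.gca.sum()) < 1e-10
            assert np.abs(eff.sca.sum(axis=1)).max() < 1e-10
            assert np.allclose(eff.sca, eff.sca.T, atol=1e-12)
            assert np.allclose(eff.reciprocal, -eff.reciprocal.T, atol=1e-12)
            assert abs(eff.maternal.sum()) < 1e-10
            assert np.abs(eff.reconstruct() - t.values).max() < 1e-9

    def test_incomplete_or_tiny_table_rejected(self):
        vals = np.full((3, 3), 10.0)
        vals[0, 1] = np.nan
        with pytest.raises(DesignError, match="missing"):
            griffing.estimate_effects(EntryMeanTable("hmf", list("ABC"), vals))
        with pytest.raises(DesignError):
            griffing.estimate_effects(
                EntryMeanTable("hmf", list("AB"), np.full((2, 2), 1.0))
            )

    def test_gca_standard_error_matches_closed_form(self):
        """SE(g_i) = sqrt((p-1)/(2 p^2) * sigma2) on the mean basis."""
        rng = np.random.default_rng(9)
        p = 6
        t = random_table(p, rng)
        eff = griffing.estimate_effects(t, error_ms=12.0, n_obs_per_cell=4, error_df=50)
        expected = np.sqrt((p - 1) / (2 * p**2) * 12.0 / 4)
        np.testing.assert_allclose(eff.se_gca, expected, rtol=1e-12)

    def test_permuting_parent_labels_permutes_gca(self):
        rng = np.random.default_rng(8)
        t = random_table(5, rng)
        perm = rng.permutation(5)
        t2 = EntryMeanTable(
            t.trait, [t.parents[i] for i in perm], t.values[np.ix_(perm, perm)]
        )
        e1 = griffing.estimate_effects(t)
        e2 = griffing.estimate_effects(t2)
        np.testing.assert_allclose(e2.gca, e1.gca[perm], atol=1e-10)


class TestPartition:
    def test_df_partition_for_eight_parents(self):
        dfs = griffing.component_df(8)
        assert dfs == {
            "GCA": 7,
            "SCA": 28,
            "Reciprocal": 28,
            "Maternal": 7,
            "NonMaternal": 21,
        }

    def test_additive_noise_free_two_env_data(self):
        a = np.array([4.0, 0.0, -4.0, 2.0, -2.0])
        x = 30.0 + a[:, None] + a[None, :]
        t = EntryMeanTable("hmf", list("ABCDE"), x)
        per_env = [
            EntryMeanTable("hmf", list("ABCDE"), x.copy()),
            EntryMeanTable("hmf", list("ABCDE"), x.copy()),
        ]
        out = griffing.partition_anova(
            t, per_env, error_ms=1.0, error_df=10, n_obs_per_cell=4, n_reps=2
        )
        ss = out.table.set_index("source")["ss"]
        assert ss["SCA"] == pytest.approx(0.0, abs=1e-9)
        assert ss["Reciprocal"] == pytest.approx(0.0, abs=1e-9)
        for comp in ("GCA", "SCA", "Reciprocal", "Maternal", "NonMaternal"):
            assert ss[f"{comp} x Env"] == pytest.approx(0.0, abs=1e-9)

    def test_partition_closes_on_stage_one_genotype_ss(self, default_trial):
        """SS(GCA) + SS(SCA) + SS(Reciprocal) equals the genotype SS of the
        combined ANOVA, and Maternal + NonMaternal equals Reciprocal."""
        trial, _ = default_trial
        trial = add_trait_columns(trial)
        aov = anova.fit_combined_anova(trial, "hmf")
        means = means_to_entry_table(trial, "hmf")
        per_env = per_environment_means(trial, "hmf")
        out = griffing.partition_anova(
            means, per_env, error_ms=aov.error_ms, error_df=aov.error_df,
            n_obs_per_cell=4, n_reps=2,
        )
        ss = out.table.set_index("source")["ss"]
        geno = float(aov.row("Genotype")["ss"])
        assert ss["GCA"] + ss["SCA"] + ss["Reciprocal"] == pytest.approx(
            geno, rel=1e-8
        )
        assert ss["Maternal"] + ss["NonMaternal"] == pytest.approx(
            ss["Reciprocal"], rel=1e-8
        )
        gxe = float(aov.row("Genotype x Env")["ss"])
        inter = ss["GCA x Env"] + ss["SCA x Env"] + ss["Reciprocal x Env"]
        assert inter == pytest.approx(gxe, rel=1e-8)


class TestVarianceComponents:
    def test_baker_ratio_from_published_additive_dominance_split(self):
        vc = griffing.components_from_variances(sigma2_a=173.39, sigma2_d=62.84)
        assert round(vc.baker_ratio, 2) == 0.73

    def test_gca_sca_ratio(self):
        vc = griffing.components_from_variances(sigma2_a=94.85, sigma2_d=27.10)
        assert round(vc.gca_sca_ratio, 2) == 1.75

    def test_heritabilities(self):
        h2, _ = griffing.heritabilities(
            griffing.components_from_variances(
                sigma2_a=173.39, sigma2_d=62.84, sigma2_p=378.44
            )
        )
        assert round(h2, 2) == 0.46
        _, H2 = griffing.heritabilities(
            griffing.components_from_variances(
                sigma2_a=94.85, sigma2_d=27.10, sigma2_p=169.53
            )
        )
        assert round(H2, 2) == 0.72

    def test_pure_additive_degenerate_cases(self):
        vc = griffing.components_from_variances(sigma2_a=10.0, sigma2_d=0.0)
        assert vc.baker_ratio == pytest.approx(1.0)
        assert vc.h2 == pytest.approx(vc.H2)
        vc = griffing.components_from_variances(
            sigma2_a=10.0, sigma2_d=0.0, sigma2_p=10.0
        )
        assert vc.h2 == pytest.approx(1.0)
        assert vc.H2 == pytest.approx(1.0)

    def test_nonpositive_phenotypic_variance_rejected(self):
        with pytest.raises(EstimationError):
            griffing.components_from_variances(sigma2_a=0.0, sigma2_d=0.0, sigma2_p=0.0)

    def test_negative_components_are_clamped_with_flag(self, default_trial):
        trial, _ = default_trial
        trial = add_trait_columns(trial)
        means = means_to_entry_table(trial, "hmf")
        out = griffing.partition_anova(means, n_obs_per_cell=4)
        with pytest.warns(UserWarning, match="clamped"):
            # absurdly large error MS forces negative SCA/REC components
            vc = griffing.estimate_variance_components(out, error_ms=1e6)
        assert vc.sigma2_sca == 0.0
        assert "sigma2_SCA" in vc.clamped

    def test_baker_ratio_invariant_to_parent_relabeling(self, default_trial):
        trial, _ = default_trial
        trial = add_trait_columns(trial)
        means = means_to_entry_table(trial, "hmf")
        rng = np.random.default_rng(1)
        perm = rng.permutation(means.p)
        permuted = EntryMeanTable(
            means.trait,
            [means.parents[i] for i in perm],
            means.values[np.ix_(perm, perm)],
        )
        vcs = []
        for t in (means, permuted):
            out = griffing.partition_anova(t, n_obs_per_cell=4)
            vcs.append(griffing.estimate_variance_components(out, error_ms=100.0))
        assert vcs[0].baker_ratio == pytest.approx(vcs[1].baker_ratio, abs=1e-12)
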