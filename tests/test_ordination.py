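import subprocess

import numpy as np
import pandas as pd
import pytest

import scfa_micromap as sm
from scfa_micromap.errors import ConfigError, DesignError
from scfa_micromap.ordination import dense_cca_eigenvalues
from conftest import random_relative_table


def design(rng, n, cols):
    return pd.DataFrame(rng.normal(size=(n, len(cols))), columns=cols)


class TestCCAAgainstDenseOracle:
    def test_eigenvalues_match_generalized_eigenproblem(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            table = random_relative_table(rng, 10, 6)
            X = design(rng, 10, ["a", "b"])
            res = sm.pcca(table, X)
            oracle = dense_cca_eigenvalues(table, X)
            assert np.abs(res.eigenvalues - oracle[: len(res.eigenvalues)]).max() < 1e-8
            assert res.constrained_inertia == pytest.approx(oracle[:2].sum(), abs=1e-8)

    def test_inertia_partition_conserved_with_conditions(self):
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            table = random_relative_table(rng, 12, 8)
            X = design(rng, 12, ["a", "b", "c"])
            Z = design(rng, 12, ["z"])
            res = sm.pcca(table, X, Z)
            total = res.conditional_inertia + res.constrained_inertia + res.residual_inertia
            assert total == pytest.approx(res.total_inertia, abs=1e-8)


def test_matches_vegan_reference_implementation(tmp_path):
    """Eigenvalues, inertia partition, species scores (up to axis sign) and
    the permutation pseudo-F agree with vegan's cca()."""
    rng = np.random.default_rng(0)
    table = random_relative_table(rng, 10, 6)
    X = design(rng, 10, ["a", "b"])
    Z = design(rng, 10, ["z"])
    res = sm.pcca(table, X, Z)
    test = sm.pcca_permutation_test(table, X, Z, n_perm=49, seed=1)
    pd.DataFrame(table.values, columns=table.feature_ids).to_csv(
        tmp_path / "Y.tsv", sep="\t", index=False
    )
    X.assign(z=Z["z"]).to_csv(tmp_path / "X.tsv", sep="\t", index=False)
    script = f"""
    Y <- read.delim("{tmp_path}/Y.tsv"); X <- read.delim("{tmp_path}/X.tsv")
    suppressMessages(library(vegan))
    m <- cca(Y ~ a + b + Condition(z), data = X)
    sp <- scores(m, display = "species", scaling = 2, choices = 1:2)
    cat(sprintf("%.15g", c(m$CCA$eig, m$pCCA$tot.chi, m$tot.chi)), "\n")
    cat(sprintf("%.15g", c(sp[1, ], sp[6, ])), "\n")
    cat(sprintf("%.15g", anova(m, permutations = 49)$F[1]), "\n")
    """
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True
    ).stdout.splitlines()
    eig1, eig2, cond, tot = map(float, out[0].split())
    assert res.eigenvalues == pytest.approx([eig1, eig2], abs=1e-8)
    assert res.conditional_inertia == pytest.approx(cond, abs=1e-8)
    assert res.total_inertia == pytest.approx(tot, abs=1e-8)
    sp_vals = np.array(list(map(float, out[1].split())))
    mine = np.concatenate([res.species_scores.iloc[0], res.species_scores.iloc[5]])
    assert np.abs(np.abs(mine) - np.abs(sp_vals)).max() < 1e-6
    assert test.pseudo_F == pytest.approx(float(out[2]), abs=1e-8)


class TestPccaStructure:
    def test_condition_identical_to_constraint_removes_all_inertia(self, rng):
        table = random_relative_table(rng, 10, 6)
        X = design(rng, 10, ["a"])
        res = sm.pcca(table, X, X.rename(columns={"a": "z"}))
        assert res.constrained_inertia <= 1e-8 * res.total_inertia
        assert res.n_axes == 0

    def test_no_conditions_equals_plain_cca(self, rng):
        table = random_relative_table(rng, 12, 7)
        X = design(rng, 12, ["a", "b"])
        empty = pd.DataFrame(index=X.index)
        res1 = sm.pcca(table, X)
        res2 = sm.pcca(table, X, empty)
        assert np.allclose(res1.eigenvalues, res2.eigenvalues, atol=1e-12)
        assert res1.conditional_inertia == res2.conditional_inertia == 0.0

    def test_constrained_inertia_invariant_to_reparameterization(self, rng):
        table = random_relative_table(rng, 15, 8)
        X = design(rng, 15, ["a", "b", "c"])
        A = np.array([[2.0, 0.5, 0.0], [0.0, 1.0, -1.0], [1.0, 0.0, 3.0]])
        X2 = pd.DataFrame(X.to_numpy() @ A, columns=["p", "q", "r"])
        r1, r2 = sm.pcca(table, X), sm.pcca(table, X2)
        assert r1.constrained_inertia == pytest.approx(r2.constrained_inertia, abs=1e-8)
        assert np.allclose(r1.eigenvalues, r2.eigenvalues, atol=1e-8)

    def test_full_rank_constraints_recover_total_ca_structure(self, rng):
        # n-1 independent constraints span the centered sample space, so the
        # constrained inertia equals the full correspondence-analysis inertia.
        table = random_relative_table(rng, 8, 10)
        X = design(rng, 8, [f"x{j}" for j in range(7)])
        res = sm.pcca(table, X)
        assert res.constrained_inertia == pytest.approx(res.total_inertia, abs=1e-8)

    def test_collinear_constraints_named(self, rng):
        table = random_relative_table(rng, 10, 5)
        X = design(rng, 10, ["a", "b"])
        X["twice_a"] = 2 * X["a"]
        with pytest.raises(DesignError, match="twice_a"):
            sm.pcca(table, X)

    def test_sign_convention_dominant_constraint_positive(self, rng):
        table = random_relative_table(rng, 14, 9)
        X = design(rng, 14, ["a", "b"])
        res = sm.pcca(table, X)
        for k in range(res.n_axes):
            col = res.biplot_scores.iloc[:, k]
            assert col.iloc[np.argmax(np.abs(col))] > 0


class TestPermutationTest:
    def test_p_floor_when_no_permutation_exceeds(self):
        cfg = sm.GeneratorConfig(
            n_per_group=(("HV", 40), ("IBS-C", 40), ("IBS-D", 40)), seed=0
        )
        table, meta, _ = sm.generate_cohort(cfg)
        filtered, _ = sm.filter_high_abundant(table, meta)
        res = sm.pcca_permutation_test(
            filtered.to_relative(),
            meta.data[["acetate", "butyrate", "propionate"]].astype(float),
            meta.data[["transit"]].astype(float),
            n_perm=99,
            seed=5,
        )
        assert res.p_value == pytest.approx(1.0 / 100.0)

    def test_n_perm_zero_is_config_error(self, rng):
        table = random_relative_table(rng, 10, 5)
        with pytest.raises(ConfigError):
            sm.pcca_permutation_test(table, design(rng, 10, ["a"]), n_perm=0)

    def test_null_p_values_roughly_uniform(self):
        """Constraints independent of the community: p should be uniform."""
        from scipy import stats

        pvals = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            table = random_relative_table(rng, 20, 10)
            X = design(rng, 20, ["a", "b"])
            res = sm.pcca_permutation_test(table, X, n_perm=99, seed=seed + 500)
            pvals.append(res.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
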