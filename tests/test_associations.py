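from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import scfa_micromap as sm
from scfa_micromap.errors import CoverageError, DesignError


def meta_from(groups, **cols):
    ids = [f"s{i}" for i in range(len(groups))]
    return sm.CohortMetadata(pd.DataFrame({"group": groups, **cols}, index=ids))


class TestKruskalDunn:
    def test_h_matches_exact_enumeration_with_ties(self):
        """For n = 6 with ties, the permutation distribution of H computed
        by exhaustive enumeration gives the exact p; our tie-corrected H
        matches scipy and the enumerated reference."""
        values = [1.0, 2.0, 2.0, 3.0, 1.0, 3.0]
        groups = ["HV", "HV", "IBS-C", "IBS-C", "IBS-D", "IBS-D"]
        meta = meta_from(groups, trait=values)
        res = sm.kruskal_dunn(meta, "trait")
        H_scipy, _ = stats.kruskal(values[:2], values[2:4], values[4:])
        assert res.kw_H == pytest.approx(H_scipy, abs=1e-12)
        # exact permutation p for H >= observed
        vals = np.array(values)
        count = total = 0
        for perm in set(permutations(range(6))):
            v = vals[list(perm)]
            H, _ = stats.kruskal(v[:2], v[2:4], v[4:])
            count += H >= res.kw_H - 1e-12
            total += 1
        assert count / total > 0.5  # observed arrangement is unremarkable
        assert res.kw_p > 0.1

    def test_identical_groups_give_high_p(self):
        meta = meta_from(
            ["HV"] * 3 + ["IBS-C"] * 3 + ["IBS-D"] * 3,
            trait=[1.0, 2.0, 3.0] * 3,
        )
        res = sm.kruskal_dunn(meta, "trait")
        assert res.kw_p > 0.9
        # tie-corrected H: scipy agrees
        H, _ = stats.kruskal([1, 2, 3], [1, 2, 3], [1, 2, 3])
        assert res.kw_H == pytest.approx(H, abs=1e-12)

    def test_bonferroni_is_raw_times_pair_count(self):
        rng = np.random.default_rng(0)
        meta = meta_from(
            ["HV"] * 8 + ["IBS-C"] * 8 + ["IBS-D"] * 8, trait=rng.normal(size=24)
        )
        res = sm.kruskal_dunn(meta, "trait")
        assert len(res.pairwise) == 3
        for row in res.pairwise.itertuples():
            assert row.p_bonferroni == pytest.approx(min(1.0, row.p_raw * 3))

    def test_degenerate_constant_trait_flagged(self):
        meta = meta_from(["HV"] * 3 + ["IBS-D"] * 3, trait=[5.0] * 6)
        res = sm.kruskal_dunn(meta, "trait")
        assert res.degenerate and res.kw_p == 1.0

    def test_missing_values_excluded_per_endpoint(self):
        meta = meta_from(
            ["HV"] * 4 + ["IBS-D"] * 4,
            trait=[1.0, 2.0, np.nan, 3.0, 7.0, 8.0, 9.0, np.nan],
        )
        res = sm.kruskal_dunn(meta, "trait")
        H, p = stats.kruskal([1, 2, 3], [7, 8, 9])
        assert res.kw_H == pytest.approx(H, abs=1e-12)

    def test_type_one_error_calibrated(self):
        rej = 0
        n_sims = 200
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            meta = meta_from(
                ["HV"] * 8 + ["IBS-C"] * 8 + ["IBS-D"] * 8, trait=rng.normal(size=24)
            )
            rej += sm.kruskal_dunn(meta, "trait").kw_p < 0.05
        assert 0.02 <= rej / n_sims <= 0.09


def alr_of(values, ids):
    frame = pd.DataFrame(values, index=[f"s{i}" for i in range(len(values))], columns=ids)
    return sm.ALRTable(frame, reference_id="ref", pseudocount=0.0)


class TestAdjustedFeatureModel:
    def test_two_groups_no_covariates_reproduces_t_test(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=20)
        meta = meta_from(["HV"] * 10 + ["IBS-D"] * 10)
        res = sm.adjusted_feature_model(alr_of(y[:, None], ["f"]), meta, [], ("IBS-D", "HV"))
        t, p = stats.ttest_ind(y[10:], y[:10])
        assert res[0].estimate == pytest.approx(y[10:].mean() - y[:10].mean(), abs=1e-10)
        assert res[0].p == pytest.approx(p, abs=1e-10)

    def test_matches_statsmodels_with_covariates(self):
        import statsmodels.api as smf

        rng = np.random.default_rng(2)
        n = 30
        groups = ["HV"] * 10 + ["IBS-C"] * 10 + ["IBS-D"] * 10
        age = rng.normal(40, 10, n)
        y = rng.normal(size=n) + 0.05 * age
        meta = meta_from(groups, age=age)
        res = sm.adjusted_feature_model(alr_of(y[:, None], ["f"]), meta, ["age"], ("IBS-D", "HV"))
        X = pd.DataFrame(
            {
                "intercept": 1.0,
                "g_ibsc": [g == "IBS-C" for g in groups],
                "g_ibsd": [g == "IBS-D" for g in groups],
                "age": age,
            },
            dtype=float,
        )
        fit = smf.OLS(y, X).fit()
        assert res[0].estimate == pytest.approx(fit.params["g_ibsd"], abs=1e-10)
        assert res[0].se == pytest.approx(fit.bse["g_ibsd"], abs=1e-10)
        assert res[0].p == pytest.approx(fit.pvalues["g_ibsd"], abs=1e-10)

    def test_group_shift_recovered(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            n = 60
            groups = ["HV"] * 30 + ["IBS-D"] * 30
            shift = np.where(np.arange(n) >= 30, 1.0, 0.0)
            y = shift + rng.normal(0, 0.5, n)
            meta = meta_from(groups)
            res = sm.adjusted_feature_model(alr_of(y[:, None], ["f"]), meta, [], ("IBS-D", "HV"))
            hits += 0.7 <= res[0].estimate <= 1.3
        assert hits / 40 >= 0.95

    def test_covariate_confounding_removed(self):
        """A purely covariate-driven feature shows no group effect once the
        covariate enters the model."""
        from scipy.stats import kstest

        pvals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            groups = ["HV"] * 20 + ["IBS-D"] * 20
            age = np.concatenate([rng.normal(30, 5, 20), rng.normal(45, 5, 20)])
            y = 0.1 * age + rng.normal(0, 0.5, 40)
            meta = meta_from(groups, age=age)
            res = sm.adjusted_feature_model(alr_of(y[:, None], ["f"]), meta, ["age"], ("IBS-D", "HV"))
            pvals.append(res[0].p)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_noise_identical_groups_flagged(self):
        y = np.ones(10)
        meta = meta_from(["HV"] * 5 + ["IBS-D"] * 5)
        res = sm.adjusted_feature_model(alr_of(y[:, None], ["f"]), meta, [], ("IBS-D", "HV"))
        assert res[0].estimate == 0.0 and res[0].p == 1.0

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(3)
        age = rng.normal(40, 10, 20)
        meta = meta_from(["HV"] * 10 + ["IBS-D"] * 10, age=age, age2=2 * age)
        with pytest.raises(DesignError):
            sm.adjusted_feature_model(
                alr_of(rng.normal(size=(20, 1)), ["f"]), meta, ["age", "age2"], ("IBS-D", "HV")
            )


class TestGMMAssociate:
    def make_ko(self, y_by_ko, groups):
        ids = [f"s{i}" for i in range(len(groups))]
        frame = pd.DataFrame(y_by_ko, index=ids)
        return sm.AbundanceTable(frame, kind="counts"), meta_from(groups)

    def test_planted_group_effect_detected(self, toy_gmm):
        rng = np.random.default_rng(5)
        groups = ["HV"] * 30 + ["IBS-D"] * 30
        shift = np.where(np.arange(60) >= 30, 1.0, 0.0)
        ko, meta = self.make_ko(
            {
                "K00001": shift + rng.normal(0, 0.3, 60) + 1.0,
                "K01026": rng.normal(1.0, 0.3, 60),
            },
            groups,
        )
        res = sm.gmm_associate(ko, toy_gmm, meta, [], contrast=("IBS-D", "HV"))
        by_ko = res.set_index("ko_id")
        assert bool(by_ko.loc["K00001", "significant"])
        assert set(res.module_id) == {"MF0001", "MF0002"}

    def test_trait_mode_reports_planted_sign(self, toy_gmm):
        rng = np.random.default_rng(6)
        acetate = rng.normal(8, 2, 50)
        ko, meta = self.make_ko(
            {"K00001": 0.5 * acetate + rng.normal(0, 0.5, 50) + 1.0},
            ["HV"] * 25 + ["IBS-D"] * 25,
        )
        meta.data["acetate"] = acetate
        res = sm.gmm_associate(ko, toy_gmm, meta, [], scfa="acetate")
        assert res.set_index("ko_id").loc["K00001", "estimate"] > 0

    def test_no_overlap_is_coverage_error(self, toy_gmm):
        rng = np.random.default_rng(7)
        ko, meta = self.make_ko({"K99999": rng.random(10)}, ["HV"] * 5 + ["IBS-D"] * 5)
        with pytest.raises(CoverageError):
            sm.gmm_associate(ko, toy_gmm, meta, [], contrast=("IBS-D", "HV"))

    def test_exactly_one_mode_required(self, toy_gmm):
        rng = np.random.default_rng(8)
        ko, meta = self.make_ko({"K00001": rng.random(10)}, ["HV"] * 5 + ["IBS-D"] * 5)
        with pytest.raises(DesignError):
            sm.gmm_associate(ko, toy_gmm, meta, [])
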