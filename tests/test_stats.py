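"""Cohort statistics: Z-scoring, comparisons, regression, ROC, OR/RR,
two-step clustering, risk stratification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from hydromorph import stats
from hydromorph.stats import NormativeTable, TwoByTwoTable


@pytest.fixture
def norm_table():
    return NormativeTable(pd.DataFrame({
        "measure": ["fsas_max_mm", "ihf_max_mm"],
        "age_min_days": [0, 0],
        "age_max_days": [1000, 1000],
        "mean": [2.0, 2.0],
        "sd": [0.5, 0.5],
    }))


def cohort_row(fsas=2.0, ihf=2.0, age=100):
    return pd.DataFrame({"age_days": [age], "fsas_max_mm": [fsas], "ihf_max_mm": [ihf]})


class TestZscoreClassify:
    def test_at_mean_not_enlarged(self, norm_table):
        df = stats.zscore_classify(cohort_row(2.0, 2.0), norm_table)
        assert df["z_fsas"].iloc[0] == 0.0
        assert df["enlarged_fsas"].iloc[0] == 0

    def test_three_sd_enlarged(self, norm_table):
        df = stats.zscore_classify(cohort_row(fsas=3.5), norm_table)
        assert df["z_fsas"].iloc[0] == pytest.approx(3.0)
        assert df["enlarged_fsas"].iloc[0] == 1

    def test_boundary_exactly_196_not_enlarged(self, norm_table):
        df = stats.zscore_classify(cohort_row(fsas=2.0 + 1.96 * 0.5), norm_table)
        assert df["z_fsas"].iloc[0] == pytest.approx(1.96)
        assert df["enlarged_fsas"].iloc[0] == 0

    def test_missing_bracket_names_measure_and_age(self, norm_table):
        with pytest.raises(KeyError, match="fsas_max_mm.*2000"):
            stats.zscore_classify(cohort_row(age=2000), norm_table)


class TestAbnormalityScore:
    @pytest.mark.parametrize("f,i,score,group", [
        (1, 0, 1, "enlarged"), (0, 0, 0, "normal"), (1, 1, 2, "enlarged"),
    ])
    def test_score_and_group(self, f, i, score, group):
        df = pd.DataFrame({"enlarged_fsas": [f], "enlarged_ihf": [i]})
        out = stats.abnormality_score(df)
        assert out["abnormality_score"].iloc[0] == score
        assert out["quantified_group"].iloc[0] == group

    def test_unset_flags_rejected(self):
        with pytest.raises(ValueError):
            stats.abnormality_score(pd.DataFrame({"enlarged_fsas": [1]}))

    def test_order_independence(self, norm_table):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "age_days": rng.integers(10, 900, 20),
            "fsas_max_mm": rng.normal(2.5, 1.0, 20),
            "ihf_max_mm": rng.normal(2.5, 1.0, 20),
        })
        a = stats.abnormality_score(stats.zscore_classify(df, norm_table))
        shuffled = df.sample(frac=1, random_state=1)
        b = stats.abnormality_score(stats.zscore_classify(shuffled, norm_table))
        merged = a.join(b, how="inner", lsuffix="_a", rsuffix="_b")
        assert (merged["abnormality_score_a"] == merged["abnormality_score_b"]).all()
        # idempotence: re-running the chain changes nothing
        again = stats.abnormality_score(stats.zscore_classify(a, norm_table))
        assert (again["abnormality_score"] == a["abnormality_score"]).all()


class TestCompareGroups:
    def test_fisher_on_printed_complication_counts(self):
        # 13/23 events vs 0/11: the exact test lands near 0.002
        _, p = stats.compare_groups(method="fisher",
                                    table=[[13, 10], [0, 11]])
        assert p == pytest.approx(0.002, abs=5e-4)

    def test_fisher_equal_proportions_p_one(self):
        _, p = stats.compare_groups(method="fisher", table=[[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c, d = rng.integers(0, 10, 4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p = stats.compare_groups(method="fisher", table=[[a, b], [c, d]])
            # enumerate the hypergeometric support, summing tables at most
            # as probable as the observed one
            n1, n0, m1 = a + b, c + d, a + c
            probs = []
            for x in range(max(0, m1 - n0), min(n1, m1) + 1):
                probs.append((x, sps.hypergeom.pmf(x, n1 + n0, m1, n1)))
            p_obs = sps.hypergeom.pmf(a, n1 + n0, m1, n1)
            p_enum = sum(pr for _, pr in probs if pr <= p_obs * (1 + 1e-9))
            assert p == pytest.approx(p_enum, rel=1e-6)

    def test_mannwhitney_matches_full_permutation(self):
        x = [1.2, 3.4, 2.2]
        y = [0.5, 4.1, 2.9, 1.1]
        _, p = stats.compare_groups(x, y, method="mannwhitney")
        pool = x + y
        mu = len(x) * len(y) / 2
        u_obs = sps.mannwhitneyu(x, y).statistic
        us = []
        for comb in itertools.combinations(range(7), 3):
            xx = [pool[i] for i in comb]
            yy = [pool[i] for i in range(7) if i not in comb]
            us.append(sps.mannwhitneyu(xx, yy).statistic)
        p_perm = np.mean([abs(u - mu) >= abs(u_obs - mu) - 1e-9 for u in us])
        assert p == pytest.approx(p_perm)

    def test_chi2_is_pearson_without_correction(self):
        tab = [[12, 11], [6, 5]]
        _, p = stats.compare_groups(method="chi2", table=tab)
        assert p == pytest.approx(0.897, abs=1e-3)

    def test_degenerate_t_rejected(self):
        with pytest.raises(ValueError):
            stats.compare_groups([1.0, 1.0], [1.0, 1.0], method="t")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            stats.compare_groups([1], [2], method="wilcoxon")


class TestFitLinear:
    def test_exact_linear_fit(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x1": rng.normal(size=50), "x2": rng.normal(size=50)})
        df["y"] = 2 * df.x1 - 3 * df.x2 + 1
        res = stats.fit_linear(df, "y", ["x1", "x2"])
        assert res.adjusted_r2 == pytest.approx(1.0)
        assert set(res.retained) == {"x1", "x2"}

    def test_duplicated_predictor_pruned(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x1": rng.normal(size=50)})
        df["x1_copy"] = df.x1
        df["y"] = df.x1 + rng.normal(size=50)
        res = stats.fit_linear(df, "y", ["x1", "x1_copy"])
        assert res.dropped_collinear == ["x1_copy"]
        assert res.retained == ["x1"]

    def test_noise_predictor_eliminated(self):
        eliminated = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({
                "signal": rng.normal(size=200),
                "noise": rng.normal(size=200),
            })
            df["y"] = 3 * df.signal + rng.normal(size=200)
            # strict removal criterion: a null predictor survives backward
            # elimination only when its p-value falls below p-to-remove
            res = stats.fit_linear(df, "y", ["signal", "noise"],
                                   backward_alpha=0.01)
            eliminated += "noise" in res.eliminated
        assert eliminated >= 95

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"x": [1, 2, 3], "y": [1, 2, 3]})
        with pytest.raises(ValueError):
            stats.fit_linear(df, "y", ["x", "x", "x"])


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = stats.roc_auc([1, 2, 10, 11], [0, 0, 1, 1])
        assert auc == 1.0

    def test_concordant_pair_counting(self):
        auc, _ = stats.roc_auc([1, 2, 3, 4], [0, 1, 0, 1])
        assert auc == pytest.approx(0.75)

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        y[0], y[1] = 0, 1
        a1, _ = stats.roc_auc(s, y)
        a2, _ = stats.roc_auc(np.exp(3 * s), y)
        assert a1 == pytest.approx(a2)

    def test_equals_mannwhitney_u_identity_and_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(1)
        s = rng.normal(size=60) + np.r_[np.zeros(30), np.ones(30)]
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        auc, _ = stats.roc_auc(s, y)
        u = sps.mannwhitneyu(s[y == 1], s[y == 0], alternative="two-sided").statistic
        assert auc == pytest.approx(u / (30 * 30))
        assert auc == pytest.approx(roc_auc_score(y, s))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stats.roc_auc([1, 2], [1, 1])


class TestLogisticOr:
    def test_known_or_recovered(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 2, 5000)
        eta = -1.0 + np.log(3.0) * x
        y = (rng.uniform(size=5000) < 1 / (1 + np.exp(-eta))).astype(int)
        res = stats.logistic_or(y, x)
        assert 2.4 <= res.odds_ratio <= 3.75
        assert res.ci_low < res.odds_ratio < res.ci_high

    def test_degenerate_exposure_rejected(self):
        with pytest.raises(ValueError):
            stats.logistic_or([0, 1, 0, 1], [0, 0, 0, 0])

    def test_complete_separation_rejected(self):
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        x = y.astype(float)
        with pytest.raises(ValueError):
            stats.logistic_or(y, x)


class TestRiskRatio:
    def test_closed_form(self):
        rr = stats.risk_ratio(TwoByTwoTable(10, 10, 2, 18))
        assert rr.risk_ratio == pytest.approx(5.0)

    def test_equal_risks_ci_straddles_one(self):
        rr = stats.risk_ratio(TwoByTwoTable(5, 15, 5, 15))
        assert rr.risk_ratio == pytest.approx(1.0)
        assert rr.ci_low < 1.0 < rr.ci_high

    @given(st.integers(1, 30), st.integers(1, 30), st.integers(1, 30), st.integers(1, 30))
    @settings(deadline=None, max_examples=50)
    def test_ci_matches_closed_form(self, a, b, c, d):
        rr = stats.risk_ratio(TwoByTwoTable(a, b, c, d))
        lnrr = np.log((a / (a + b)) / (c / (c + d)))
        se = np.sqrt(b / (a * (a + b)) + d / (c * (c + d)))
        assert rr.ci_low == pytest.approx(np.exp(lnrr - 1.959963984540054 * se))
        assert rr.ci_high == pytest.approx(np.exp(lnrr + 1.959963984540054 * se))

    def test_zero_event_cell_continuity_corrected(self):
        rr = stats.risk_ratio(TwoByTwoTable(5, 15, 0, 20))
        assert rr.continuity_corrected
        assert np.isfinite(rr.ci_high)

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError):
            stats.risk_ratio(TwoByTwoTable(0, 0, 2, 4))


class TestTwostepCluster:
    def make_blobs(self, n=200, sep=6.0, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1, (n // 2, 2)),
                       rng.normal(sep, 1, (n // 2, 2))])
        labels = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        return pd.DataFrame(X, columns=["f1", "f2"]), labels

    def test_planted_partition_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        df, truth = self.make_blobs()
        res = stats.twostep_cluster(df, ["f1", "f2"], max_k=4)
        assert res.n_clusters == 2
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_identical_points_single_cluster(self):
        df = pd.DataFrame({"f1": np.ones(20), "f2": np.ones(20)})
        res = stats.twostep_cluster(df, ["f1", "f2"], max_k=4)
        assert res.n_clusters == 1

    def test_input_order_only_permutes_labels(self):
        from sklearn.metrics import adjusted_rand_score
        df, truth = self.make_blobs(seed=3)
        res1 = stats.twostep_cluster(df, ["f1", "f2"], max_k=4)
        perm = np.random.default_rng(9).permutation(len(df))
        res2 = stats.twostep_cluster(df.iloc[perm].reset_index(drop=True),
                                     ["f1", "f2"], max_k=4)
        assert adjusted_rand_score(res1.labels[perm], res2.labels) == 1.0

    def test_invalid_max_k_rejected(self):
        df, _ = self.make_blobs(n=10)
        with pytest.raises(ValueError):
            stats.twostep_cluster(df, ["f1", "f2"], max_k=0)


class TestRiskStratify:
    def test_null_association_rr_near_one(self):
        rng = np.random.default_rng(0)
        n = 4000
        df = pd.DataFrame({"complication": rng.integers(0, 2, n),
                           "f": rng.normal(size=n)})
        labels = rng.integers(1, 3, n)
        res = stats.risk_stratify(df, labels, "complication")
        assert 0.9 <= res.rr.risk_ratio <= 1.1

    def test_zero_event_cluster_flagged(self):
        df = pd.DataFrame({"complication": [1, 1, 0, 0, 0, 0],
                           "f": [1, 1, 1, 0, 0, 0]})
        labels = np.array([1, 1, 1, 2, 2, 2])
        res = stats.risk_stratify(df, labels, "complication")
        assert res.rr.continuity_corrected

    def test_single_cluster_informative_message(self):
        df = pd.DataFrame({"complication": [0, 1], "f": [1.0, 2.0]})
        res = stats.risk_stratify(df, np.array([1, 1]), "complication")
        assert res.table is None
        assert "single cluster" in res.message
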