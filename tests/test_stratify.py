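"""Normalisation, hierarchical clustering and clinical group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathassoc.stratify import (
    cluster_patients,
    compare_groups_clinical,
    normalize_prs,
    prs_case_control_tests,
)


def clinical_frame(ids, status, **cols):
    return pd.DataFrame({"sample_id": ids, "status": status, **cols})


class TestNormalize:
    def test_hand_z_scores(self):
        scores = pd.DataFrame(
            {"a": [1.0, 3.0, 5.0], "b": [2.0, 2.0, 8.0]},
            index=pd.Index(["c1", "c2", "x1"], name="sample_id"),
        )
        clin = clinical_frame(["c1", "c2", "x1"], ["control", "control", "case"])
        out = normalize_prs(scores, clin)
        # controls a: mean 2, sd(ddof=1) sqrt(2); b: mean 2, sd 0 -> dropped
        assert list(out.columns) == ["a"]
        assert out["a"].to_numpy() == pytest.approx(
            (np.array([1, 3, 5]) - 2) / np.sqrt(2)
        )

    def test_standardized_controls_unchanged(self, rng):
        ctrl = rng.standard_normal(400)
        ctrl = (ctrl - ctrl.mean()) / ctrl.std(ddof=1)
        scores = pd.DataFrame(
            {"a": ctrl}, index=pd.Index([f"s{i}" for i in range(400)], name="sample_id")
        )
        clin = clinical_frame(scores.index, ["control"] * 400)
        out = normalize_prs(scores, clin)
        assert np.allclose(out["a"], scores["a"], atol=1e-12)

    def test_all_constant_rejected(self):
        scores = pd.DataFrame(
            {"a": [1.0, 1.0]}, index=pd.Index(["c1", "c2"], name="sample_id")
        )
        clin = clinical_frame(["c1", "c2"], ["control", "control"])
        with pytest.raises(ValueError, match="zero control variance"):
            normalize_prs(scores, clin)


class TestClustering:
    def blobs(self, rng, centers, n_per=30, sd=0.3):
        X, labels = [], []
        for i, c in enumerate(centers):
            X.append(rng.normal(c, sd, size=(n_per, len(c))))
            labels += [i] * n_per
        X = np.vstack(X)
        idx = pd.Index([f"p{i}" for i in range(len(X))], name="sample_id")
        return pd.DataFrame(X, index=idx), np.array(labels)

    def test_k_one_single_cluster(self, rng):
        X, _ = self.blobs(rng, [np.zeros(3)])
        out = cluster_patients(X, k=1)
        assert set(out["cluster"]) == {1}

    def test_k_larger_than_n_rejected(self, rng):
        X, _ = self.blobs(rng, [np.zeros(2)], n_per=3)
        with pytest.raises(ValueError):
            cluster_patients(X, k=5)

    def test_nonfinite_rejected(self, rng):
        X, _ = self.blobs(rng, [np.zeros(2)])
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            cluster_patients(X, k=2)

    def test_separated_blobs_recovered_exactly(self, rng):
        from sklearn.metrics import adjusted_rand_score

        centers = [np.r_[6 * np.eye(4)[i]] for i in range(4)]
        X, truth = self.blobs(rng, centers)
        out = cluster_patients(X, k=4)
        assert adjusted_rand_score(truth, out["cluster"]) == 1.0

    def test_permutation_equivariance(self, rng):
        from sklearn.metrics import adjusted_rand_score

        centers = [np.r_[5 * np.eye(3)[i]] for i in range(3)]
        X, _ = self.blobs(rng, centers)
        out1 = cluster_patients(X, k=3).set_index("sample_id")["cluster"]
        perm = rng.permutation(len(X))
        out2 = cluster_patients(X.iloc[perm], k=3).set_index("sample_id")["cluster"]
        joined = pd.concat([out1, out2.reindex(out1.index)], axis=1)
        assert adjusted_rand_score(joined.iloc[:, 0], joined.iloc[:, 1]) == 1.0

    def test_labels_ordered_by_size(self, rng):
        X1, _ = self.blobs(rng, [np.zeros(2)], n_per=50, sd=0.2)
        X2, _ = self.blobs(rng, [np.full(2, 8.0)], n_per=10, sd=0.2)
        X2.index = pd.Index([f"q{i}" for i in range(10)], name="sample_id")
        X = pd.concat([X2, X1])  # small blob first in input order
        out = cluster_patients(X, k=2)
        counts = out.groupby("cluster").size()
        assert counts[1] == 50 and counts[2] == 10


class TestGroupComparisons:
    def test_bonferroni_threshold_35_tests(self, rng):
        ids = [f"s{i}" for i in range(60)]
        clin = clinical_frame(
            ids, ["case"] * 60, damage_index=rng.poisson(1.0, 60)
        )
        groups = pd.Series(
            ["pos"] * 30 + ["neg"] * 30, index=pd.Index(ids, name="sample_id")
        )
        out = compare_groups_clinical(groups, clin, ["damage_index"], family_size=35)
        thr = out["bonferroni_threshold"].iloc[0]
        assert float(f"{thr:.3g}") == 0.00143

    def test_hand_chi_square(self):
        # 2x2 table (20/80 vs 40/60): chi-square 9.524 without correction
        ids = [f"s{i}" for i in range(200)]
        flag = [True] * 20 + [False] * 80 + [True] * 40 + [False] * 60
        clin = clinical_frame(ids, ["case"] * 200, ab=flag)
        groups = pd.Series(
            ["g1"] * 100 + ["g2"] * 100, index=pd.Index(ids, name="sample_id")
        )
        out = compare_groups_clinical(groups, clin, ["ab"])
        row = out.iloc[0]
        assert row["test"] == "chi_square"
        assert row["statistic"] == pytest.approx(9.524, abs=5e-4)
        assert row["p_value"] == pytest.approx(stats.chi2.sf(9.5238, 1), abs=1e-4)

    def test_identical_distributions_not_significant(self, rng):
        ids = [f"s{i}" for i in range(100)]
        vals = np.tile(rng.poisson(2, 50), 2)
        clin = clinical_frame(ids, ["case"] * 100, damage_index=vals)
        groups = pd.Series(
            ["a"] * 50 + ["b"] * 50, index=pd.Index(ids, name="sample_id")
        )
        out = compare_groups_clinical(groups, clin, ["damage_index"])
        assert not out["significant"].iloc[0]

    def test_constant_variable_reports_p_one(self):
        ids = ["s1", "s2", "s3", "s4"]
        clin = clinical_frame(ids, ["case"] * 4, damage_index=[2, 2, 2, 2])
        groups = pd.Series(["a", "a", "b", "b"], index=pd.Index(ids, name="sample_id"))
        out = compare_groups_clinical(groups, clin, ["damage_index"])
        assert out["p_value"].iloc[0] == 1.0
        assert out["note"].iloc[0] == "constant variable"

    def test_three_groups_use_kruskal(self, rng):
        ids = [f"s{i}" for i in range(90)]
        clin = clinical_frame(ids, ["case"] * 90, damage_index=rng.poisson(2, 90))
        groups = pd.Series(
            ["a"] * 30 + ["b"] * 30 + ["c"] * 30, index=pd.Index(ids, name="sample_id")
        )
        out = compare_groups_clinical(groups, clin, ["damage_index"])
        assert out["test"].iloc[0] == "kruskal_wallis"

    def test_small_cells_use_fisher(self):
        ids = [f"s{i}" for i in range(20)]
        flag = [True] * 1 + [False] * 9 + [True] * 5 + [False] * 5
        clin = clinical_frame(ids, ["case"] * 20, ab=flag)
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=pd.Index(ids, name="sample_id"))
        out = compare_groups_clinical(groups, clin, ["ab"])
        assert out["test"].iloc[0] == "fisher_exact"

    def test_empty_group_rejected(self):
        ids = ["s1", "s2"]
        clin = clinical_frame(ids, ["case"] * 2, damage_index=[1, 2])
        groups = pd.Series(["a", "a"], index=pd.Index(ids, name="sample_id"))
        with pytest.raises(ValueError, match="groups"):
            compare_groups_clinical(groups, clin, ["damage_index"])


def test_prs_case_control_tests(null_cohort, rng):
    scores = pd.DataFrame(
        rng.standard_normal((null_cohort["genotypes"].n_samples, 3)),
        columns=["a", "b", "c"],
        index=pd.Index(null_cohort["genotypes"].sample_ids, name="sample_id"),
    )
    out = prs_case_control_tests(scores, null_cohort["clinical"])
    assert len(out) == 3
    assert out["bonferroni_threshold"].iloc[0] == pytest.approx(0.05 / 3)
    assert (out["p_value"] > 0.001).all()  # null scores
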