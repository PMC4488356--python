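import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from chemores import data_io
from chemores.deg_detection import PermutationConfig, detect_degs
from chemores.errors import InputError
from chemores.subgrouping import (
    correlation_distance,
    cut_clusters,
    hierarchical_cluster,
    median_center,
    summarize_subgroups,
)
from chemores.synthetic_data import SyntheticConfig, generate_cohort


class TestMedianCenter:
    def test_single_gene_hand_example(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        out = median_center(m)
        # gene centering gives [-1,0,1]; each 1-entry column then centers to 0
        assert np.allclose(out.values, 0.0)

    def test_double_centered_matrix_is_fixed_point(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(6, 5)))
        for _ in range(100):  # iterate to a genuinely double-centered matrix
            nxt = median_center(m)
            if np.allclose(nxt.values, m.values, atol=1e-13):
                break
            m = nxt
        assert np.allclose(median_center(m).values, m.values, atol=1e-12)

    def test_gene_medians_zero_after_first_pass(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(8, 7)))
        step1 = m.sub(m.median(axis=1), axis=0)
        assert np.allclose(step1.median(axis=1), 0.0, atol=1e-12)


class TestCorrelationDistance:
    def test_identical_columns_distance_zero(self):
        m = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        d = correlation_distance(m)
        assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_columns_distance_two(self):
        m = pd.DataFrame({"a": [1.0, 2, 3], "b": [-1.0, -2, -3]})
        assert correlation_distance(m).loc["a", "b"] == pytest.approx(2.0)

    def test_hand_pearson(self):
        m = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 4]})
        d = correlation_distance(m)
        assert d.loc["a", "b"] == pytest.approx(1 - 0.981981, abs=1e-5)

    def test_constant_column_named_in_error(self):
        m = pd.DataFrame({"a": [1.0, 2, 3], "bad": [2.0, 2, 2]})
        with pytest.raises(InputError, match="bad"):
            correlation_distance(m)


class TestUpgma:
    def test_three_point_hand_example(self):
        d = pd.DataFrame(
            [[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]],
            index=list("xyz"), columns=list("xyz"),
        )
        Z = hierarchical_cluster(d)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == pytest.approx(0.1)
        assert Z[1, 2] == pytest.approx(0.9)  # average of the two 0.9 distances

    def test_identical_samples_merge_first_at_zero(self):
        d = pd.DataFrame(
            [[0.0, 0.0, 0.5], [0.0, 0.0, 0.5], [0.5, 0.5, 0.0]],
        )
        Z = hierarchical_cluster(d)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_n_minus_one_merges(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 10))
        D = np.abs(X - X.T)
        np.fill_diagonal(D, 0.0)
        Z = hierarchical_cluster(pd.DataFrame(D))
        assert Z.shape[0] == 9

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(InputError):
            hierarchical_cluster(d)


class TestCutClusters:
    @staticmethod
    def _tree(n=6, seed=0):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.normal(size=(12, n)), columns=[f"s{i}" for i in range(n)])
        d = correlation_distance(m)
        return hierarchical_cluster(d), list(m.columns), d

    def test_k_equals_n_gives_singletons(self):
        Z, ids, _ = self._tree()
        model = cut_clusters(Z, ids, k=len(ids))
        assert model.k == len(ids)
        assert model.assignment.nunique() == len(ids)

    def test_k_one_single_cluster(self):
        Z, ids, _ = self._tree()
        model = cut_clusters(Z, ids, k=1)
        assert model.k == 1
        assert (model.assignment == 1).all()

    def test_k_beyond_n_rejected(self):
        Z, ids, _ = self._tree()
        with pytest.raises(InputError):
            cut_clusters(Z, ids, k=len(ids) + 1)

    def test_hierarchy_respected_between_k_and_k_minus_1(self):
        Z, ids, _ = self._tree(n=10, seed=3)
        a4 = cut_clusters(Z, ids, k=4).assignment
        a3 = cut_clusters(Z, ids, k=3).assignment
        # every k=4 cluster maps into exactly one k=3 cluster
        for sub in a4.unique():
            assert a3[a4 == sub].nunique() == 1

    def test_order_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(15, 8)), columns=[f"s{i}" for i in range(8)])
        m.iloc[:, 4:] += 3.0
        d1 = correlation_distance(m)
        model1 = cut_clusters(hierarchical_cluster(d1), m.columns, k=2)
        perm = rng.permutation(8)
        mp = m.iloc[:, perm]
        d2 = correlation_distance(mp)
        model2 = cut_clusters(hierarchical_cluster(d2), mp.columns, k=2)
        joined = pd.concat([model1.assignment, model2.assignment], axis=1)
        assert adjusted_rand_score(joined.iloc[:, 0], joined.iloc[:, 1]) == 1.0


class TestRecovery:
    def test_planted_subgroups_recovered_at_k4(self):
        cfg = SyntheticConfig(seed=5)
        expr, ann, truth = generate_cohort(cfg)
        z = data_io.zscore_normalize(expr)
        degs = detect_degs(z, ann, PermutationConfig(n_permutations=500, seed=5))
        sig = sorted(degs.index[degs["significant"]])
        d = correlation_distance(median_center(z.loc[sig]))
        model = cut_clusters(hierarchical_cluster(d), z.columns, k=4)
        ari = adjusted_rand_score(
            [truth.sample_subgroup[s] for s in model.assignment.index],
            model.assignment.values,
        )
        assert ari >= 0.9

    def test_strong_effect_gives_perfect_recovery(self):
        """Clustering the planted feature genes at a 4-sd shift is error-free."""
        cfg = SyntheticConfig(seed=6, effect_size=4.0)
        expr, ann, truth = generate_cohort(cfg)
        z = data_io.zscore_normalize(expr)
        feats = sorted(
            truth.de_genes | set().union(*truth.sensitive_marker_genes.values())
        )
        d = correlation_distance(median_center(z.loc[feats]))
        model = cut_clusters(hierarchical_cluster(d), z.columns, k=4)
        ari = adjusted_rand_score(
            [truth.sample_subgroup[s] for s in model.assignment.index],
            model.assignment.values,
        )
        assert ari == 1.0


class TestSummaries:
    def test_majority_and_tie_rules(self):
        assignment = pd.Series(
            [1] * 11 + [2] * 6, index=[f"s{i}" for i in range(17)], name="subgroup"
        )
        ann = pd.DataFrame(
            {"response": ["NOCR"] * 7 + ["CR"] * 4 + ["NOCR"] * 3 + ["CR"] * 3},
            index=assignment.index,
        )
        from chemores.subgrouping import SubgroupModel

        model = SubgroupModel(assignment=assignment, k=2)
        with pytest.warns(RuntimeWarning):  # 3-3 tie in subgroup 2
            summary = summarize_subgroups(model, ann)
        assert bool(summary.loc[1, "resistant"])  # 7 NOCR vs 4 CR
        assert not bool(summary.loc[2, "resistant"])  # tie -> sensitive

    def test_all_cr_subgroup(self):
        assignment = pd.Series([1, 1, 1], index=["a", "b", "c"], name="subgroup")
        ann = pd.DataFrame({"response": ["CR"] * 3}, index=assignment.index)
        from chemores.subgrouping import SubgroupModel

        summary = summarize_subgroups(SubgroupModel(assignment=assignment, k=1), ann)
        assert summary.loc[1, "dominant_response"] == "CR"
        assert not bool(summary.loc[1, "resistant"])

    def test_unannotated_sample_rejected(self):
        assignment = pd.Series([1, 1], index=["a", "b"], name="subgroup")
        ann = pd.DataFrame({"response": ["CR"]}, index=["a"])
        from chemores.subgrouping import SubgroupModel

        with pytest.raises(InputError):
            summarize_subgroups(SubgroupModel(assignment=assignment, k=1), ann)
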