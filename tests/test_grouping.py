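import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from iprp.cohort_io import ClinicalTable, ExpressionMatrix
from iprp.grouping import (
    GroupingError,
    assign_joint_groups,
    clustering_association_test,
    consensus_cluster,
    deg_screen,
    label_clusters_by_survival,
)


def _blob_expression(rng, centers, n_per, n_genes=8, sd=0.5):
    """Genes x samples matrix with one Gaussian blob per center."""
    cols, blocks, labels = [], [], []
    for ci, c in enumerate(centers):
        blocks.append(rng.normal(c, sd, size=(n_genes, n_per)))
        cols += [f"c{ci}_s{j}" for j in range(n_per)]
        labels += [ci] * n_per
    data = pd.DataFrame(np.hstack(blocks), index=[f"G{i}" for i in range(n_genes)], columns=cols)
    return ExpressionMatrix(data), np.array(labels)


class TestConsensusCluster:
    def test_two_separated_blobs_give_binary_consensus(self):
        rng = np.random.default_rng(0)
        expr, truth = _blob_expression(rng, centers=[0.0, 6.0], n_per=20)
        res = consensus_cluster(expr, k_range=(2, 3), n_resamples=30, seed=1)
        cm = res.consensus_matrices[2]
        off = cm[np.triu_indices_from(cm, k=1)]
        assert np.all((off < 0.05) | (off > 0.95))

    def test_determinism(self):
        rng = np.random.default_rng(1)
        expr, _ = _blob_expression(rng, centers=[0.0, 5.0, 10.0], n_per=15)
        r1 = consensus_cluster(expr, k_range=(2, 3, 4), n_resamples=25, seed=7)
        r2 = consensus_cluster(expr, k_range=(2, 3, 4), n_resamples=25, seed=7)
        assert r1.labels.equals(r2.labels)
        assert r1.cdf_areas == r2.cdf_areas

    def test_three_planted_blobs_recovered(self):
        rng = np.random.default_rng(2)
        expr, truth = _blob_expression(rng, centers=[0.0, 5.0, 10.0], n_per=30)
        res = consensus_cluster(expr, k_range=(2, 3, 4, 5), n_resamples=50, seed=3)
        assert res.chosen_k == 3
        assert adjusted_rand_score(truth, res.labels.to_numpy()) > 0.9

    def test_bad_k_range_rejected(self):
        rng = np.random.default_rng(3)
        expr, _ = _blob_expression(rng, centers=[0.0, 4.0], n_per=10)
        with pytest.raises(GroupingError):
            consensus_cluster(expr, k_range=(1, 2))


class TestSurvivalLabelling:
    def _clin(self, times, events, ids):
        return ClinicalTable(
            pd.DataFrame({"os_time": times, "os_event": events},
                         index=pd.Index(ids, name="sample_id"))
        )

    def test_long_survivor_cluster_is_favorable(self):
        ids = [f"s{i}" for i in range(40)]
        labels = pd.Series([1] * 20 + [2] * 20, index=ids)
        times = np.r_[np.full(20, 2000.0), np.linspace(30, 300, 20)]
        events = np.r_[np.zeros(20, int), np.ones(20, int)]
        out = label_clusters_by_survival(labels, self._clin(times, events, ids))
        assert out.favorability[1] == "favorable"
        assert out.favorability[2] == "unfavorable"

    def test_identical_survival_flags_tie(self):
        ids = [f"s{i}" for i in range(40)]
        labels = pd.Series([1] * 20 + [2] * 20, index=ids)
        times = np.tile(np.linspace(100, 1000, 20), 2)
        events = np.ones(40, int)
        out = label_clusters_by_survival(labels, self._clin(times, events, ids))
        assert out.logrank_p > 0.9
        assert out.tied

    def test_planted_hazard_separation_significant(self):
        rng = np.random.default_rng(4)
        n = 400
        ids = [f"s{i}" for i in range(n)]
        group = rng.integers(0, 2, n)
        lp = np.log(3.0) * group
        T = 1000 * (-np.log(rng.uniform(size=n)) / np.exp(lp))
        out = label_clusters_by_survival(
            pd.Series(group + 1, index=ids), self._clin(T, np.ones(n, int), ids)
        )
        assert out.logrank_p < 0.01
        assert out.favorability[1] == "favorable"


class TestJointGroups:
    def test_assignments(self):
        ids = ["a", "b", "c"]
        la = pd.Series([1, 1, 2], index=ids)
        lb = pd.Series([1, 2, 2], index=ids)
        fav_a = {1: "favorable", 2: "unfavorable"}
        fav_b = {1: "favorable", 2: "unfavorable"}
        joint = assign_joint_groups(la, lb, fav_a, fav_b)
        assert joint.labels.tolist() == ["FF", "other", "UU"]

    def test_all_unfavorable(self):
        ids = ["a", "b"]
        la = pd.Series([1, 1], index=ids)
        joint = assign_joint_groups(la, la, {1: "unfavorable"}, {1: "unfavorable"})
        assert joint.counts == {"UU": 2}

    def test_mismatched_universes_rejected(self):
        la = pd.Series([1], index=["a"])
        lb = pd.Series([1], index=["b"])
        with pytest.raises(GroupingError):
            assign_joint_groups(la, lb, {1: "favorable"}, {1: "favorable"})


class TestAssociationTest:
    def test_identical_balanced_labelings(self):
        ids = [f"s{i}" for i in range(100)]
        labels = pd.Series([1] * 50 + [2] * 50, index=ids)
        chi2, p = clustering_association_test(labels, labels)
        # perfect association in a balanced 2x2 table: chi2 = n
        assert chi2 == pytest.approx(100.0)
        assert p < 1e-10

    def test_no_association_balanced_table(self):
        ids = [f"s{i}" for i in range(100)]
        l1 = pd.Series(([1] * 25 + [2] * 25) * 2, index=ids)
        l2 = pd.Series([1] * 50 + [2] * 50, index=ids)
        chi2, _ = clustering_association_test(l1, l2)
        assert chi2 == pytest.approx(0.0)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(5)
        ids = [f"s{i}" for i in range(200)]
        pvals = []
        for _ in range(100):
            l1 = pd.Series(rng.integers(0, 2, 200), index=ids)
            l2 = pd.Series(rng.integers(0, 2, 200), index=ids)
            pvals.append(clustering_association_test(l1, l2)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_single_category_rejected(self):
        ids = ["a", "b"]
        l1 = pd.Series([1, 1], index=ids)
        l2 = pd.Series([1, 2], index=ids)
        with pytest.raises(GroupingError):
            clustering_association_test(l1, l2)


class TestDegScreen:
    def _expr_and_labels(self, rng, shift):
        n = 50
        ids = [f"ff{i}" for i in range(n)] + [f"uu{i}" for i in range(n)]
        labels = pd.Series(["FF"] * n + ["UU"] * n, index=ids)
        flat = rng.normal(7, 0.3, 2 * n)
        shifted = np.r_[rng.normal(7 + shift, 0.3, n), rng.normal(7, 0.3, n)]
        small = np.r_[rng.normal(7.5, 0.3, n), rng.normal(7, 0.3, n)]
        data = pd.DataFrame([flat, shifted, small],
                            index=["FLAT", "SHIFT2", "SHIFT05"], columns=ids)
        return ExpressionMatrix(data), labels

    def test_threshold_semantics(self):
        rng = np.random.default_rng(6)
        expr, labels = self._expr_and_labels(rng, shift=2.0)
        degs = deg_screen(expr, labels)
        by_gene = {d.gene_id: d for d in degs}
        assert "SHIFT2" in by_gene and by_gene["SHIFT2"].direction == "up"
        assert "FLAT" not in by_gene
        assert "SHIFT05" not in by_gene  # significant p but |log2FC| <= 1

    def test_fdr_at_least_p_and_direction_sign(self):
        rng = np.random.default_rng(7)
        expr, labels = self._expr_and_labels(rng, shift=-2.0)
        degs = deg_screen(expr, labels)
        for d in degs:
            assert d.fdr >= d.p_value
            assert (d.direction == "up") == (d.log2_fc > 0)

    def test_invariant_to_sample_and_gene_order(self):
        rng = np.random.default_rng(8)
        expr, labels = self._expr_and_labels(rng, shift=2.0)
        base = {d.gene_id for d in deg_screen(expr, labels)}
        perm_cols = list(rng.permutation(expr.sample_ids))
        shuffled = ExpressionMatrix(expr.data[perm_cols].iloc[::-1])
        assert {d.gene_id for d in deg_screen(shuffled, labels)} == base

    def test_small_group_refused(self):
        ids = ["a", "b", "c", "d"]
        labels = pd.Series(["FF", "FF", "UU", "UU"], index=ids)
        expr = ExpressionMatrix(pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["G"], columns=ids))
        with pytest.raises(GroupingError, match=">= 3"):
            deg_screen(expr, labels)
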