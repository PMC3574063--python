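import itertools

import numpy as np
import pytest
from scipy import stats

from homclust.evaluation import (
    FamilyLabels,
    davies_bouldin_index,
    dunn_index,
    evaluate,
    family_scores,
    goodman_kruskal_index,
    jaccard_index,
    rand_index,
    roc50,
    roc_auc,
    wilcoxon_signed_rank,
)
from homclust.kernels import Kernel
from homclust.spectral import Clustering


def clustering(labels, ids=None):
    labels = np.asarray(labels)
    ids = ids or [f"p{i}" for i in range(len(labels))]
    return Clustering(list(ids), labels, k=int(labels.max()) + 1)


def block_kernel_and_truth():
    sizes = [4, 3, 3]
    n = sum(sizes)
    K = np.full((n, n), 0.05)
    labels = np.repeat(np.arange(3), sizes)
    for b in range(3):
        K[np.ix_(labels == b, labels == b)] = 0.9
    np.fill_diagonal(K, 1.0)
    ids = [f"p{i}" for i in range(n)]
    truth = FamilyLabels({sid: f"fam{l}" for sid, l in zip(ids, labels)})
    return Kernel(ids, K), clustering(labels, ids), truth


class TestFamilyScores:
    def test_block_structure_ranks_members_first(self):
        kernel, cl, truth = block_kernel_and_truth()
        scores = family_scores(kernel, cl, truth, "fam0")
        members = set(truth.members("fam0"))
        worst_member = min(scores[s] for s in members)
        best_nonmember = max(v for s, v in scores.items() if s not in members)
        assert worst_member > best_nonmember

    def test_matches_mean_similarity_oracle(self, rng):
        kernel, cl, truth = block_kernel_and_truth()
        kernel = Kernel(kernel.ids, kernel.values + rng.uniform(0, 0.01, kernel.values.shape))
        kernel.values[:] = (kernel.values + kernel.values.T) / 2
        scores = family_scores(kernel, cl, truth, "fam1")
        # oracle: the matched cluster is the one holding fam1's members
        members = truth.members("fam1")
        predicted = cl.label_map[members[0]]
        for sid, got in scores.items():
            others = [
                kernel.values[kernel.ids.index(sid), kernel.ids.index(t)]
                for t in cl.members(predicted)
                if t != sid
            ]
            assert got == pytest.approx(np.mean(others), abs=1e-12)

    def test_singleton_predicted_cluster_scores_zero(self):
        ids = ["a", "b"]
        kernel = Kernel(ids, np.eye(2))
        cl = clustering([0, 1], ids)
        truth = FamilyLabels({"a": "f1", "b": "f2"})
        scores = family_scores(kernel, cl, truth, "f1")
        assert scores["a"] == 0.0

    def test_empty_family_rejected(self):
        kernel, cl, truth = block_kernel_and_truth()
        with pytest.raises(ValueError, match="no members"):
            family_scores(kernel, cl, truth, "ghost")


class TestRocAuc:
    def test_perfect_and_inverted(self):
        scores = {"p1": 3.0, "p2": 2.0, "n1": 1.0, "n2": 0.0}
        assert roc_auc(scores, {"p1", "p2"}) == 1.0
        assert roc_auc(scores, {"n1", "n2"}) == 0.0

    def test_worked_pair_count(self):
        scores = {"p1": 3.0, "p2": 1.0, "n1": 2.0, "n2": 0.0}
        assert roc_auc(scores, {"p1", "p2"}) == pytest.approx(0.75)

    def test_needs_both_classes(self):
        with pytest.raises(ValueError):
            roc_auc({"a": 1.0}, {"a"})

    def test_matches_pairwise_oracle_with_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 20))
            scores = {f"s{i}": float(np.round(rng.uniform(0, 1), 1)) for i in range(n)}
            n_pos = int(rng.integers(1, n))
            positives = set(list(scores)[:n_pos])
            p = [v for k, v in scores.items() if k in positives]
            q = [v for k, v in scores.items() if k not in positives]
            wins = sum((a > b) + 0.5 * (a == b) for a in p for b in q)
            assert roc_auc(scores, positives) == pytest.approx(wins / (len(p) * len(q)))


def roc50_oracle(scores, positives, max_fp=50):
    """Independent curve construction: walk the ranked list, accumulate TPs
    seen before each of the first min(N, max_fp) false positives."""
    ranked = sorted(scores, key=lambda s: (-scores[s], s))
    n_neg = sum(1 for s in scores if s not in positives)
    budget = min(n_neg, max_fp)
    tp = 0
    area = 0
    seen_fp = 0
    for sid in ranked:
        if sid in positives:
            tp += 1
        else:
            seen_fp += 1
            area += tp
            if seen_fp == budget:
                break
    return area / (len(positives) * budget)


class TestRoc50:
    def test_few_negatives_equals_full_auc(self, rng):
        scores = {f"s{i}": float(v) for i, v in enumerate(rng.uniform(0, 1, 20))}
        positives = set(list(scores)[:8])  # only 12 negatives: truncation inactive
        assert roc50(scores, positives) == pytest.approx(roc_auc(scores, positives))

    def test_perfect_ranking(self):
        scores = {f"p{i}": 10.0 + i for i in range(5)}
        scores.update({f"n{i}": float(i) / 100.0 for i in range(100)})
        assert roc50(scores, {f"p{i}" for i in range(5)}) == 1.0

    def test_interleaved_matches_curve_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(60, 150))
            scores = {f"s{i}": float(v) for i, v in enumerate(rng.uniform(0, 1, n))}
            positives = set(list(scores)[: int(rng.integers(3, 20))])
            assert roc50(scores, positives) == pytest.approx(
                roc50_oracle(scores, positives)
            )


def wilcoxon_oracle_greater(diffs):
    """Full 2^n sign enumeration of the exact one-sided p-value."""
    d = np.asarray([x for x in diffs if x != 0.0])
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= w_obs - 1e-9:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_identical_samples(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0 and res.statistic == 0.0 and res.all_zero

    def test_three_positive_diffs_one_sided(self):
        res = wilcoxon_signed_rank([2.0, 3.0, 4.0], [1.0, 1.0, 1.0], "greater")
        assert res.p_value == pytest.approx(0.125)
        assert res.statistic == 6.0

    def test_exact_path_matches_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 11))
            a = rng.normal(size=n)
            b = a - rng.normal(scale=1.0, size=n)
            res = wilcoxon_signed_rank(a, b, "greater")
            assert res.p_value == pytest.approx(wilcoxon_oracle_greater(a - b))

    def test_exact_two_sided_matches_scipy(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 12))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            res = wilcoxon_signed_rank(a, b)
            ref = stats.wilcoxon(a, b, alternative="two-sided", method="exact")
            assert res.p_value == pytest.approx(ref.pvalue)

    def test_approximate_path_close_to_exact(self, rng):
        a = rng.normal(size=14)
        b = a - rng.normal(scale=1.0, size=14)
        approx = wilcoxon_signed_rank(a, b, "greater", exact_max_n=12)
        exact = wilcoxon_signed_rank(a, b, "greater", exact_max_n=20)
        assert approx.p_value == pytest.approx(exact.p_value, abs=0.02)
        assert not approx.exact and exact.exact

    def test_median_difference_reported(self):
        res = wilcoxon_signed_rank([3.0, 5.0, 9.0], [1.0, 1.0, 1.0])
        assert res.median_diff == 4.0


def pair_agreement_oracle(l1, l2):
    n = len(l1)
    agree = together_both = together_any = 0
    total = 0
    for i, j in itertools.combinations(range(n), 2):
        total += 1
        same1, same2 = l1[i] == l1[j], l2[i] == l2[j]
        agree += same1 == same2
        together_both += same1 and same2
        together_any += same1 or same2
    rand = agree / total
    jac = together_both / together_any if together_any else 1.0
    return rand, jac


class TestPartitionIndices:
    def test_identical_partitions(self):
        c = clustering([0, 0, 1, 1])
        assert rand_index(c, c) == 1.0
        assert jaccard_index(c, c) == 1.0

    def test_fully_disagreeing_three_points(self):
        c1 = clustering([0, 0, 1])
        c2 = clustering([0, 1, 1])
        assert rand_index(c1, c2) == pytest.approx(1.0 / 3.0)

    def test_label_permutation_invariant(self, rng):
        labels = rng.integers(0, 3, size=10)
        labels[:3] = [0, 1, 2]
        c1 = clustering(labels)
        c2 = clustering((labels + 1) % 3)
        assert rand_index(c1, c2) == 1.0

    def test_no_coclustered_pairs_degenerate(self):
        c1 = clustering(np.arange(4))
        c2 = clustering(np.arange(4))
        assert jaccard_index(c1, c2) == 1.0

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 9))
            l1 = rng.integers(0, 3, size=n)
            l2 = rng.integers(0, 3, size=n)
            l1[0] = l2[0] = 0
            c1 = clustering(np.unique(l1, return_inverse=True)[1])
            c2 = clustering(np.unique(l2, return_inverse=True)[1])
            rand_o, jac_o = pair_agreement_oracle(l1, l2)
            assert rand_index(c1, c2) == pytest.approx(rand_o)
            assert jaccard_index(c1, c2) == pytest.approx(jac_o)


class TestGeometricIndices:
    def test_dunn_hand_case(self):
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        assert dunn_index(pts, clustering([0, 0, 1, 1])) == pytest.approx(9.0)

    def test_dunn_decreases_as_clusters_approach(self):
        cl = clustering([0, 0, 1, 1])
        far = np.array([[0.0], [1.0], [10.0], [11.0]])
        near = np.array([[0.0], [1.0], [5.0], [6.0]])
        assert dunn_index(near, cl) < dunn_index(far, cl)

    def test_dunn_degenerate_rejected(self):
        pts = np.zeros((4, 1))
        with pytest.raises(ValueError, match="degenerate"):
            dunn_index(pts, clustering([0, 0, 1, 1]))

    def test_davies_bouldin_hand_case(self):
        pts = np.array([[0.0], [2.0], [10.0], [12.0]])
        assert davies_bouldin_index(pts, clustering([0, 0, 1, 1])) == pytest.approx(0.2)

    def test_davies_bouldin_increases_as_clusters_approach(self):
        cl = clustering([0, 0, 1, 1])
        far = np.array([[0.0], [2.0], [10.0], [12.0]])
        near = np.array([[0.0], [2.0], [5.0], [7.0]])
        assert davies_bouldin_index(near, cl) > davies_bouldin_index(far, cl)

    def test_davies_bouldin_matches_sklearn(self, rng):
        from sklearn.metrics import davies_bouldin_score

        pts = rng.normal(size=(20, 3))
        labels = rng.integers(0, 3, size=20)
        labels[:3] = [0, 1, 2]
        got = davies_bouldin_index(pts, clustering(labels))
        assert got == pytest.approx(davies_bouldin_score(pts, labels))

    def test_goodman_kruskal_extremes(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        assert goodman_kruskal_index(pts, clustering([0, 0, 1, 1])) == 1.0
        # crossed diagonals: every within distance (14.1) beats every between (10)
        crossed = np.array([[0.0, 0.0], [10.0, 10.0], [10.0, 0.0], [0.0, 10.0]])
        assert goodman_kruskal_index(crossed, clustering([0, 0, 1, 1])) == -1.0

    def test_goodman_kruskal_matches_quadruple_oracle(self, rng):
        from scipy.spatial.distance import pdist, squareform

        for _ in range(30):
            n = int(rng.integers(4, 9))
            pts = rng.normal(size=(n, 2))
            labels = rng.integers(0, 2, size=n)
            labels[:2] = [0, 1]
            D = squareform(pdist(pts))
            within, between = [], []
            for i, j in itertools.combinations(range(n), 2):
                (within if labels[i] == labels[j] else between).append(D[i, j])
            if not within or not between:
                continue
            s_plus = sum(w < b for w in within for b in between)
            s_minus = sum(w > b for w in within for b in between)
            expected = (s_plus - s_minus) / (s_plus + s_minus)
            got = goodman_kruskal_index(pts, clustering(labels))
            assert got == pytest.approx(expected)


class TestEvaluate:
    def test_perfect_block_case(self):
        kernel, cl, truth = block_kernel_and_truth()
        report = evaluate(kernel, cl, truth)
        assert report.mean_roc == 1.0
        assert report.mean_roc50 == 1.0
        assert report.indices["rand"] == 1.0
        assert report.indices["jaccard"] == 1.0

    def test_means_are_arithmetic_means(self):
        kernel, cl, truth = block_kernel_and_truth()
        report = evaluate(kernel, cl, truth)
        assert report.mean_roc == pytest.approx(
            np.mean(list(report.per_family_roc.values()))
        )
        assert report.mean_roc50 == pytest.approx(
            np.mean(list(report.per_family_roc50.values()))
        )

    def test_random_labels_near_chance(self, rng):
        kernel, cl, truth = block_kernel_and_truth()
        aucs = []
        for _ in range(80):
            ids = list(kernel.ids)
            scores = {sid: float(v) for sid, v in zip(ids, rng.uniform(0, 1, len(ids)))}
            aucs.append(roc_auc(scores, set(truth.members("fam0"))))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.07)

    def test_kernel_row_space_indices(self):
        kernel, cl, truth = block_kernel_and_truth()
        emb_report = evaluate(kernel, cl, truth)
        row_report = evaluate(kernel, cl, truth, index_space="kernel_rows")
        # both spaces separate perfect blocks cleanly, but distances differ
        assert row_report.indices["goodman_kruskal"] == 1.0
        assert row_report.indices["dunn"] != emb_report.indices["dunn"]

    def test_unlabeled_id_rejected(self):
        kernel, cl, truth = block_kernel_and_truth()
        del truth.mapping[kernel.ids[0]]
        with pytest.raises(ValueError, match="lack a family label"):
            evaluate(kernel, cl, truth)
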