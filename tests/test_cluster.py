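"""DTW k-means, the strict hierarchy, nesting, retrieval and summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom
from sklearn.metrics import adjusted_rand_score

from trajsubtype.cluster import (TrajectoryEmbedding, assign,
                                 feature_separation_ranking, fit_dtw_kmeans,
                                 fit_hierarchy, inertia_curve, knn_similar,
                                 label_trajectory_curves, nesting_score)
from trajsubtype.dtw import dtw_distance


def _blob_embeddings(rng, centers, n_per, L=2, noise=0.1):
    """Variable-length trajectories around constant-level centers."""
    out, labels = [], []
    for c_idx, level in enumerate(centers):
        for i in range(n_per):
            T = int(rng.integers(3, 7))
            Z = np.full((L, T), float(level)) + rng.normal(0, noise, (L, T))
            out.append(TrajectoryEmbedding(f"c{c_idx}_p{i:02d}", Z))
            labels.append(c_idx)
    return out, labels


class TestKMeans:
    def test_k1_inertia_is_total_squared_distance(self):
        rng = np.random.default_rng(0)
        embs, _ = _blob_embeddings(rng, [0.0], 6)
        res = fit_dtw_kmeans(embs, 1, n_init=2, seed=0)
        manual = sum(dtw_distance(e.Z, res.centroids[0]) ** 2 for e in embs)
        assert res.inertia == pytest.approx(manual)
        assert set(res.labels) == {0}

    def test_duplicates_co_assigned(self):
        rng = np.random.default_rng(1)
        embs, _ = _blob_embeddings(rng, [0.0, 5.0], 4)
        dup = [TrajectoryEmbedding(e.patient_id + "_dup", e.Z.copy())
               for e in embs]
        res = fit_dtw_kmeans(embs + dup, 2, n_init=3, seed=1)
        n = len(embs)
        np.testing.assert_array_equal(res.labels[:n], res.labels[n:])

    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(2)
        embs, labels = _blob_embeddings(rng, [0.0, 6.0], 10)
        res = fit_dtw_kmeans(embs, 2, n_init=5, seed=2)
        assert adjusted_rand_score(labels, res.labels) == 1.0

    def test_inertia_non_increasing_within_restart(self):
        rng = np.random.default_rng(3)
        embs, _ = _blob_embeddings(rng, [0.0, 2.0, 4.0], 8, noise=0.6)
        res = fit_dtw_kmeans(embs, 3, n_init=4, seed=3)
        hist = np.asarray(res.inertia_history)
        assert np.all(np.diff(hist) <= 1e-9)

    def test_k_larger_than_n_raises(self):
        rng = np.random.default_rng(4)
        embs, _ = _blob_embeddings(rng, [0.0], 3)
        with pytest.raises(ValueError):
            fit_dtw_kmeans(embs, 4)


def test_inertia_curve_decreases_overall():
    rng = np.random.default_rng(5)
    embs, _ = _blob_embeddings(rng, [0.0, 3.0, 6.0], 6, noise=0.3)
    curve = inertia_curve(embs, k_min=2, k_max=5, n_init=3, seed=0)
    ks, inertias = zip(*curve)
    assert ks == (2, 3, 4, 5)
    # non-increasing up to restart noise (1% tolerance)
    for a, b in zip(inertias[:-1], inertias[1:]):
        assert b <= a * 1.01


class TestHierarchy:
    @pytest.fixture()
    def nested_embs(self):
        rng = np.random.default_rng(6)
        # branch level at 0 vs 6; leaves offset within branch
        embs, labels = [], []
        spec = [("mild", 0.0, [-0.8, 0.8]), ("severe", 6.0, [-1.0, 0.0, 1.0])]
        for branch, center, offs in spec:
            for l_idx, off in enumerate(offs):
                for i in range(8):
                    T = int(rng.integers(3, 7))
                    Z = np.full((2, T), center + off) \
                        + rng.normal(0, 0.15, (2, T))
                    pid = f"{branch}{l_idx}_{i}"
                    embs.append(TrajectoryEmbedding(pid, Z))
                    labels.append((branch, f"{branch}{l_idx}"))
        sev = {e.patient_id: float(e.Z.mean()) for e in embs}
        return embs, labels, sev

    def test_strict_nesting_and_branch_naming(self, nested_embs):
        embs, labels, sev = nested_embs
        tree = fit_hierarchy(embs, sev, seed=0)
        assert [b.name for b in tree.branches] == ["mild", "severe"]
        assert len(tree.branches[0].leaves) == 2
        assert len(tree.branches[1].leaves) == 3
        # severe branch has higher mean severity score
        mean_sev = {b.name: np.mean([sev[i] for i in b.member_ids])
                    for b in tree.branches}
        assert mean_sev["severe"] > mean_sev["mild"]
        # leaves partition branches exactly
        for b in tree.branches:
            leaf_ids = sorted(pid for l in b.leaves for pid in l.member_ids)
            assert leaf_ids == sorted(b.member_ids)

    def test_assignment_consistent_and_fixed_points(self, nested_embs):
        embs, labels, sev = nested_embs
        tree = fit_hierarchy(embs, sev, seed=0)
        table = assign(embs, tree, provenance="train")
        # every leaf assignment lies inside its branch
        b_of_l = tree.branch_of_leaf()
        for r in table.rows:
            assert b_of_l[r["leaf"]] == r["branch"]
        # a branch centroid trajectory is assigned to that branch
        for b in tree.branches:
            probe = assign([TrajectoryEmbedding("probe", b.centroid)], tree)
            assert probe.rows[0]["branch"] == b.name
        # recovery of the planted two-level structure
        true_branch = {e.patient_id: lab[0]
                       for e, lab in zip(embs, labels)}
        true_leaf = {e.patient_id: lab[1] for e, lab in zip(embs, labels)}
        pred_branch = table.branch_of()
        ids = list(true_branch)
        assert adjusted_rand_score([true_branch[i] for i in ids],
                                   [pred_branch[i] for i in ids]) == 1.0
        assert adjusted_rand_score(
            [true_leaf[i] for i in ids],
            [table.leaf_of()[i] for i in ids]) > 0.9

    def test_tree_round_trip(self, nested_embs, tmp_path):
        embs, _, sev = nested_embs
        tree = fit_hierarchy(embs, sev, seed=0)
        path = tmp_path / "tree.json"
        tree.save(path)
        back = type(tree).load(path)
        assert back.leaf_names() == tree.leaf_names()
        for b1, b2 in zip(tree.branches, back.branches):
            np.testing.assert_allclose(b1.centroid, b2.centroid)

    def test_small_branch_raises(self):
        rng = np.random.default_rng(7)
        embs, _ = _blob_embeddings(rng, [0.0, 9.0], 2)
        sev = {e.patient_id: float(e.Z.mean()) for e in embs}
        with pytest.raises(ValueError):
            fit_hierarchy(embs, sev, branching=(2, (2, 3)), seed=0)


class TestNestingScore:
    def test_perfect_nesting_is_one(self):
        coarse = {f"p{i}": i % 2 for i in range(100)}
        # fine clusters constructed strictly inside coarse ones
        fine = {pid: coarse[pid] * 10 + (i % 3)
                for i, pid in enumerate(coarse)}
        assert nesting_score(coarse, fine) == 1.0

    def test_single_flip_costs_one_percent(self):
        coarse = {f"p{i}": i % 2 for i in range(100)}
        fine = {pid: c * 10 for pid, c in coarse.items()}
        coarse["p0"] = 1 - coarse["p0"]
        assert nesting_score(coarse, fine) == pytest.approx(0.99)

    def test_random_assignments_match_enumerated_baseline(self):
        # independent coarse (2 balanced) vs fine (5 balanced) assignments:
        # per fine cluster of size m the majority-match count is
        # max(K, m-K) with K ~ Binomial(m, 1/2); the expected score follows
        # by enumeration of the binomial pmf.
        n, k_fine = 2000, 5
        m = n // k_fine
        ks = np.arange(m + 1)
        pmf = binom.pmf(ks, m, 0.5)
        exp_major = float((pmf * np.maximum(ks, m - ks)).sum())
        expected = exp_major / m
        var_major = float((pmf * np.maximum(ks, m - ks) ** 2).sum()) \
            - exp_major ** 2
        sd_score = np.sqrt(k_fine * var_major) / n
        rng = np.random.default_rng(8)
        coarse = {f"p{i}": int(rng.integers(2)) for i in range(n)}
        fine = {f"p{i}": i % k_fine for i in range(n)}
        score = nesting_score(coarse, fine)
        assert abs(score - expected) < 4 * sd_score

    def test_mismatched_patients_raise(self):
        with pytest.raises(ValueError):
            nesting_score({"a": 0}, {"b": 0})


class TestKnn:
    def test_identity_retrieval_and_full_ranking(self):
        rng = np.random.default_rng(9)
        embs, _ = _blob_embeddings(rng, [0.0, 4.0], 10)
        query = embs[3].Z.copy()
        out = knn_similar(query, embs, k=3)
        assert out[0][0] == embs[3].patient_id
        assert out[0][1] == 0.0
        full = knn_similar(query, embs, k=len(embs))
        assert len(full) == len(embs)
        dists = [d for _, d in full]
        assert dists == sorted(dists)

    def test_matches_brute_force_ranking(self):
        rng = np.random.default_rng(10)
        embs, _ = _blob_embeddings(rng, [0.0, 2.0], 10)
        query = rng.normal(size=(2, 4))
        out = knn_similar(query, embs, k=5)
        brute = sorted(((dtw_distance(query, e.Z), e.patient_id)
                        for e in embs))[:5]
        assert [(pid, pytest.approx(d)) for d, pid in brute] \
            == [(pid, pytest.approx(d)) for pid, d in out]

    def test_k_exceeds_train_raises(self):
        rng = np.random.default_rng(11)
        embs, _ = _blob_embeddings(rng, [0.0], 2)
        with pytest.raises(ValueError):
            knn_similar(embs[0].Z, embs, k=5)


class TestCurvesAndRanking:
    def test_single_member_cluster_curve_is_its_probabilities(self):
        probs = {"a": np.array([[0.2], [0.4], [0.9]])}
        df = label_trajectory_curves({"a": "c1"}, probs, ["lab"])
        np.testing.assert_allclose(df["mean"], [0.2, 0.4, 0.9])
        assert (df["n_members"] == 1).all()

    def test_constant_probabilities_flat_curve(self):
        probs = {p: np.full((4, 2), 0.5) for p in ("a", "b", "c")}
        df = label_trajectory_curves({p: "c1" for p in probs}, probs,
                                     ["l1", "l2"])
        assert (df["mean"] == 0.5).all()
        assert (df["n_members"] == 3).all()

    def test_feature_ranking_formula_and_invariance(self):
        # two clusters with means 0 and 1 -> population std 0.5
        df_model = pd.DataFrame({"f_sep": [0.0, 1.0], "f_flat": [0.3, 0.3]},
                                index=["c1", "c2"])
        out = feature_separation_ranking([df_model])
        sep = out.set_index("feature")["separation"]
        assert sep["f_sep"] == pytest.approx(0.5)
        assert sep["f_flat"] == 0.0
        assert list(out["feature"]) == ["f_sep", "f_flat"]
        # permuting the feature columns does not change the ranking
        out2 = feature_separation_ranking([df_model[["f_flat", "f_sep"]]])
        assert list(out2["feature"]) == ["f_sep", "f_flat"]

    def test_across_model_error_bars(self):
        m1 = pd.DataFrame({"f": [0.0, 1.0]}, index=["c1", "c2"])
        m2 = pd.DataFrame({"f": [0.0, 2.0]}, index=["c1", "c2"])
        out = feature_separation_ranking([m1, m2])
        row = out.set_index("feature").loc["f"]
        assert row["separation"] == pytest.approx(0.75)   # mean of 0.5, 1.0
        assert row["across_model_sd"] == pytest.approx(0.25)
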