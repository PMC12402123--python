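"""DTW k-means subtyping with a strict two-level hierarchy.

Patient trajectories live in the model's latent space as (L, T_i) matrices
of posterior means.  Subtyping fits k-means with DTW distance and DBA
centroids on the training embeddings only; held-out patients are projected
by nearest-centroid assignment.  The final partition is strictly
hierarchical: a 2-way root split (labelled mild/severe by mean predicted
severity), each branch re-clustered into its own leaves, so leaves nest in
branches by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .dtw import dba_barycenter, dtw_distance, resample_to_length

__all__ = [
    "TrajectoryEmbedding", "KMeansResult", "ClusterTree", "AssignmentTable",
    "fit_dtw_kmeans", "inertia_curve", "fit_hierarchy", "assign",
    "nesting_score", "knn_similar", "label_trajectory_curves",
    "feature_separation_ranking",
]


@dataclass
class TrajectoryEmbedding:
    patient_id: str
    Z: np.ndarray               # (L, T)


def _dtw_many(members: list[np.ndarray], centroid: np.ndarray) -> np.ndarray:
    """DTW distances from every member to one centroid, batched DP.

    The j-recurrence is sequential but the member axis vectorizes, which is
    what makes k-means over hundreds of patients cheap despite the exact
    (windowless) DTW.
    """
    n = len(members)
    B = centroid.shape[1]
    lengths = np.array([m.shape[1] for m in members])
    T_max = lengths.max()
    cost = np.zeros((n, T_max, B))
    for idx, m in enumerate(members):
        cost[idx, :m.shape[1]] = cdist(m.T, centroid.T, metric="sqeuclidean")
    out = np.empty(n)
    prev = np.empty((n, B))
    for i in range(T_max):
        row = np.empty((n, B))
        if i == 0:
            row[:, 0] = cost[:, 0, 0]
            for j in range(1, B):
                row[:, j] = row[:, j - 1] + cost[:, 0, j]
        else:
            row[:, 0] = prev[:, 0] + cost[:, i, 0]
            for j in range(1, B):
                best = np.minimum(np.minimum(prev[:, j], prev[:, j - 1]),
                                  row[:, j - 1])
                row[:, j] = best + cost[:, i, j]
        done = lengths == i + 1
        if done.any():
            out[done] = row[done, B - 1]
        prev = row
    return np.sqrt(out)


def _distance_matrix(members, centroids) -> np.ndarray:
    return np.stack([_dtw_many(members, c) for c in centroids], axis=1)


@dataclass
class KMeansResult:
    centroids: list[np.ndarray]
    labels: np.ndarray          # (n,) cluster index per input embedding
    inertia: float
    inertia_history: list[float] = field(default_factory=list)


def _kmeanspp_init(members, k, rng) -> list[int]:
    n = len(members)
    chosen = [int(rng.integers(n))]
    d2 = _dtw_many(members, members[chosen[0]])**2
    for _ in range(1, k):
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        nxt = int(rng.choice(n, p=probs))
        chosen.append(nxt)
        d2 = np.minimum(d2, _dtw_many(members, members[nxt])**2)
    return chosen


def fit_dtw_kmeans(embeddings: list[TrajectoryEmbedding], k: int,
                   n_init: int = 10, max_iter: int = 50,
                   seed: int = 0) -> KMeansResult:
    """Best-of-``n_init`` DTW k-means with DBA centroid refinement.

    Centroid lengths are the median member length, re-derived as membership
    changes; inertia (sum of squared assigned DTW distances) is guarded to be
    non-increasing within a restart — a centroid update that would raise it
    is rolled back and the restart stops.
    """
    if k > len(embeddings):
        raise ValueError(f"k={k} exceeds number of embeddings {len(embeddings)}")
    members = [np.asarray(e.Z, float) for e in embeddings]
    rng = np.random.default_rng(seed)
    best: KMeansResult | None = None

    for _ in range(n_init):
        centroids = [members[i].copy() for i in _kmeanspp_init(members, k, rng)]
        labels = None
        inertia = np.inf
        history: list[float] = []
        for _it in range(max_iter):
            dist = _distance_matrix(members, centroids)
            new_labels = dist.argmin(axis=1)
            new_inertia = float((dist[np.arange(len(members)),
                                      new_labels]**2).sum())
            if new_inertia > inertia + 1e-9:       # DBA overshoot: roll back
                break
            converged = labels is not None and np.array_equal(
                new_labels, labels)
            labels, inertia = new_labels, new_inertia
            history.append(inertia)
            if converged:
                break
            prev_centroids = [c.copy() for c in centroids]
            for c_idx in range(k):
                mask = labels == c_idx
                if not mask.any():                 # empty cluster: reseed
                    far = int(dist[np.arange(len(members)), labels].argmax())
                    centroids[c_idx] = members[far].copy()
                    continue
                sub = [m for m, keep in zip(members, mask) if keep]
                B = int(np.median([m.shape[1] for m in sub]))
                centroids[c_idx] = dba_barycenter(
                    sub, B, init=prev_centroids[c_idx], n_iter=1)
        if best is None or inertia < best.inertia:
            best = KMeansResult(centroids=[c.copy() for c in centroids],
                                labels=labels.copy(), inertia=inertia,
                                inertia_history=history)
    return best


def inertia_curve(embeddings, k_min: int = 2, k_max: int = 15,
                  n_init: int = 10, seed: int = 0) -> list[tuple[int, float]]:
    """Inertia of the best restart for each k in [k_min, k_max]."""
    if len(embeddings) < k_max:
        raise ValueError("need at least k_max embeddings")
    out = []
    for k in range(k_min, k_max + 1):
        res = fit_dtw_kmeans(embeddings, k, n_init=n_init, seed=seed + k)
        out.append((k, res.inertia))
    return out


# ---------------------------------------------------------------------------
# Strict hierarchy
# ---------------------------------------------------------------------------

@dataclass
class LeafNode:
    name: str                   # e.g. "severe_1"
    centroid: np.ndarray
    member_ids: list[str]
    inertia: float


@dataclass
class BranchNode:
    name: str                   # "mild" or "severe"
    centroid: np.ndarray
    leaves: list[LeafNode]
    member_ids: list[str]
    inertia: float


@dataclass
class ClusterTree:
    branches: list[BranchNode]

    def leaf_names(self) -> list[str]:
        return [l.name for b in self.branches for l in b.leaves]

    def branch_of_leaf(self) -> dict:
        return {l.name: b.name for b in self.branches for l in b.leaves}

    def to_dict(self) -> dict:
        return {"branches": [
            {"name": b.name, "centroid": b.centroid.tolist(),
             "member_ids": b.member_ids, "inertia": b.inertia,
             "leaves": [
                 {"name": l.name, "centroid": l.centroid.tolist(),
                  "member_ids": l.member_ids, "inertia": l.inertia}
                 for l in b.leaves]}
            for b in self.branches]}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterTree":
        return cls([BranchNode(
            name=b["name"], centroid=np.asarray(b["centroid"]),
            member_ids=list(b["member_ids"]), inertia=b["inertia"],
            leaves=[LeafNode(name=l["name"],
                             centroid=np.asarray(l["centroid"]),
                             member_ids=list(l["member_ids"]),
                             inertia=l["inertia"]) for l in b["leaves"]])
            for b in d["branches"]])

    @classmethod
    def load(cls, path) -> "ClusterTree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class AssignmentTable:
    rows: list[dict]            # patient_id, branch, leaf, dists, provenance

    def branch_of(self) -> dict:
        return {r["patient_id"]: r["branch"] for r in self.rows}

    def leaf_of(self) -> dict:
        return {r["patient_id"]: r["leaf"] for r in self.rows}

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.rows)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def fit_hierarchy(embeddings: list[TrajectoryEmbedding],
                  severity_scores: dict,
                  branching: tuple = (2, (2, 3)),
                  n_init: int = 10, seed: int = 0) -> ClusterTree:
    """Root 2-way split, then per-branch leaf k-means.

    ``severity_scores`` maps patient id to the mean model-predicted severity
    probability; the root cluster with the higher mean score is labelled
    "severe" and receives the larger leaf count of ``branching[1]``.
    """
    n_root, leaf_counts = branching
    if n_root != 2 or len(leaf_counts) != 2:
        raise ValueError("branching must be (2, (mild_leaves, severe_leaves))")
    root = fit_dtw_kmeans(embeddings, n_root, n_init=n_init, seed=seed)
    ids = [e.patient_id for e in embeddings]

    mean_sev = []
    for c_idx in range(n_root):
        member_ids = [pid for pid, lab in zip(ids, root.labels)
                      if lab == c_idx]
        mean_sev.append(np.mean([severity_scores[pid] for pid in member_ids]))
    severe_idx = int(np.argmax(mean_sev))
    names = {severe_idx: "severe", 1 - severe_idx: "mild"}
    counts = {severe_idx: max(leaf_counts), 1 - severe_idx: min(leaf_counts)}

    branches = []
    for c_idx in range(n_root):
        member_mask = root.labels == c_idx
        sub = [e for e, keep in zip(embeddings, member_mask) if keep]
        k_leaf = counts[c_idx]
        if len(sub) < k_leaf:
            raise ValueError(
                f"branch {names[c_idx]!r} has {len(sub)} members, "
                f"fewer than its {k_leaf} leaves")
        leaf_fit = fit_dtw_kmeans(sub, k_leaf, n_init=n_init,
                                  seed=seed + 7 + c_idx)
        leaves = []
        for l_idx in range(k_leaf):
            l_ids = [e.patient_id for e, lab in zip(sub, leaf_fit.labels)
                     if lab == l_idx]
            l_inertia = float(sum(
                dtw_distance(e.Z, leaf_fit.centroids[l_idx])**2
                for e, lab in zip(sub, leaf_fit.labels) if lab == l_idx))
            leaves.append(LeafNode(
                name=f"{names[c_idx]}_{l_idx}",
                centroid=leaf_fit.centroids[l_idx],
                member_ids=[e.patient_id for e, lab in
                            zip(sub, leaf_fit.labels) if lab == l_idx],
                inertia=l_inertia))
        branches.append(BranchNode(
            name=names[c_idx], centroid=root.centroids[c_idx],
            leaves=leaves,
            member_ids=[e.patient_id for e in sub],
            inertia=float(sum(dtw_distance(e.Z, root.centroids[c_idx])**2
                              for e in sub))))
    branches.sort(key=lambda b: b.name)       # deterministic order: mild first
    tree = ClusterTree(branches)
    _assert_strict(tree)
    return tree


def _assert_strict(tree: ClusterTree) -> None:
    for b in tree.branches:
        leaf_union = [pid for l in b.leaves for pid in l.member_ids]
        if sorted(leaf_union) != sorted(b.member_ids):
            raise AssertionError(
                f"leaves of branch {b.name!r} do not partition its members")


def assign(embeddings: list[TrajectoryEmbedding],
           tree: ClusterTree, provenance: str = "out_of_sample"
           ) -> AssignmentTable:
    """Nearest-branch-then-nearest-leaf assignment; never refits centroids."""
    rows = []
    for e in embeddings:
        b_d = [dtw_distance(e.Z, b.centroid) for b in tree.branches]
        b_idx = int(np.argmin(b_d))
        branch = tree.branches[b_idx]
        l_d = [dtw_distance(e.Z, l.centroid) for l in branch.leaves]
        l_idx = int(np.argmin(l_d))
        rows.append({
            "patient_id": e.patient_id,
            "branch": branch.name,
            "leaf": branch.leaves[l_idx].name,
            "branch_distance": float(b_d[b_idx]),
            "leaf_distance": float(l_d[l_idx]),
            "provenance": provenance,
        })
    table = AssignmentTable(rows)
    branch_of_leaf = tree.branch_of_leaf()
    for r in rows:
        if branch_of_leaf[r["leaf"]] != r["branch"]:
            raise AssertionError("leaf assignment crosses branches")
    return table


def nesting_score(flat_coarse: dict, flat_fine: dict) -> float:
    """Fraction of patients whose coarse label matches their fine cluster's
    majority coarse parent."""
    if set(flat_coarse) != set(flat_fine):
        raise ValueError("assignments must cover the same patients")
    from collections import Counter
    parent = {}
    by_fine: dict = {}
    for pid, f in flat_fine.items():
        by_fine.setdefault(f, []).append(pid)
    for f, pids in by_fine.items():
        parent[f] = Counter(flat_coarse[pid] for pid in pids).most_common(1)[0][0]
    hits = sum(flat_coarse[pid] == parent[flat_fine[pid]]
               for pid in flat_coarse)
    return hits / len(flat_coarse)


def knn_similar(query: np.ndarray, train: list[TrajectoryEmbedding],
                k: int = 3) -> list[tuple[str, float]]:
    """The k training trajectories closest to ``query`` by DTW, ascending;
    distance ties break by ascending patient id."""
    if k > len(train):
        raise ValueError("k exceeds number of training embeddings")
    scored = sorted(((dtw_distance(query, e.Z), e.patient_id) for e in train))
    return [(pid, d) for d, pid in scored[:k]]


def label_trajectory_curves(assignments: dict, label_probs: dict,
                            label_names: list[str]):
    """Per-cluster mean label curves over follow-up visit index.

    ``label_probs`` maps patient id to a (T_i, P) array of model-inferred
    probabilities (or values); the curve at index j averages over cluster
    members that have a j-th visit, with the member count attached.
    """
    import pandas as pd
    rows = []
    clusters = sorted(set(assignments.values()))
    for cl in clusters:
        pids = [pid for pid, c in assignments.items() if c == cl]
        max_T = max(label_probs[pid].shape[0] for pid in pids)
        for j in range(max_T):
            having = [pid for pid in pids if label_probs[pid].shape[0] > j]
            vals = np.stack([label_probs[pid][j] for pid in having])
            for p_idx, name in enumerate(label_names):
                rows.append({"cluster": cl, "follow_up": j, "label": name,
                             "mean": float(vals[:, p_idx].mean()),
                             "n_members": len(having)})
    return pd.DataFrame(rows)


def feature_separation_ranking(cluster_means_per_model: list):
    """Rank features by how strongly they separate clusters.

    Input: one DataFrame per model, indexed by cluster, one column per
    feature, holding the per-cluster mean value (or class probability).
    For each feature and model the population standard deviation of the
    cluster means is computed; features are ranked by the mean of this
    spread across models, with the across-model standard deviation as the
    error bar.
    """
    import pandas as pd
    if not cluster_means_per_model:
        raise ValueError("need at least one model summary")
    per_model = pd.DataFrame(
        {i: df.std(axis=0, ddof=0)
         for i, df in enumerate(cluster_means_per_model)})
    out = pd.DataFrame({
        "feature": per_model.index,
        "separation": per_model.mean(axis=1).to_numpy(),
        "across_model_sd": per_model.std(axis=1, ddof=0).to_numpy(),
    }).sort_values("separation", ascending=False, kind="mergesort")
    return out.reset_index(drop=True)
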