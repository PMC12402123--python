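"""Latent-space visualization exports and the decision-support report.

UMAP is used strictly as a visualization aid: the projector is fitted on
training visits only, test visits are transformed into the same 2-d space,
and none of its output feeds back into clustering or metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import ClusterTree, TrajectoryEmbedding, assign, knn_similar
from .model import GuidedTemporalVAE
from .preprocess import EncodedCohort, EncodedPatient


def umap_export(train_embeddings: list[TrajectoryEmbedding],
                test_embeddings: list[TrajectoryEmbedding] | None = None,
                seed: int = 0, n_neighbors: int = 15,
                min_dist: float = 0.1) -> pd.DataFrame:
    """2-d coordinates per (patient, visit): fit on train, transform test."""
    import umap  # heavy import kept local

    def flatten(embs, split):
        rows, mats = [], []
        for e in embs:
            for tau in range(e.Z.shape[1]):
                rows.append({"patient_id": e.patient_id, "visit": tau + 1,
                             "split": split})
                mats.append(e.Z[:, tau])
        return rows, np.stack(mats) if mats else np.empty((0, 0))

    tr_rows, tr_X = flatten(train_embeddings, "train")
    reducer = umap.UMAP(n_neighbors=min(n_neighbors, len(tr_X) - 1),
                        min_dist=min_dist, random_state=seed)
    tr_xy = reducer.fit_transform(tr_X)
    rows = tr_rows
    xy = [tr_xy]
    if test_embeddings:
        te_rows, te_X = flatten(test_embeddings, "test")
        xy.append(reducer.transform(te_X))
        rows = tr_rows + te_rows
    coords = np.concatenate(xy, axis=0)
    df = pd.DataFrame(rows)
    df["umap_1"] = coords[:, 0]
    df["umap_2"] = coords[:, 1]
    return df


@dataclass
class CdssReport:
    """Early-trajectory prediction plus similar-patient retrieval for one
    index patient."""

    patient_id: str
    anchor: int
    predicted_embedding: np.ndarray     # from x_{1:anchor}, (L, T)
    final_embedding: np.ndarray         # from the full history, (L, T)
    predicted_assignment: dict          # branch/leaf/distances
    final_assignment: dict
    neighbors: list = field(default_factory=list)   # (id, dtw distance)
    neighbor_label_curves: dict = field(default_factory=dict)
    predicted_label_curves: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "anchor": self.anchor,
            "predicted_embedding": self.predicted_embedding.tolist(),
            "final_embedding": self.final_embedding.tolist(),
            "predicted_assignment": self.predicted_assignment,
            "final_assignment": self.final_assignment,
            "neighbors": [[pid, float(d)] for pid, d in self.neighbors],
            "neighbor_label_curves": {
                pid: {k: np.asarray(v).tolist() for k, v in curves.items()}
                for pid, curves in self.neighbor_label_curves.items()},
            "predicted_label_curves": {
                k: np.asarray(v).tolist()
                for k, v in self.predicted_label_curves.items()},
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "CdssReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            patient_id=d["patient_id"], anchor=d["anchor"],
            predicted_embedding=np.asarray(d["predicted_embedding"]),
            final_embedding=np.asarray(d["final_embedding"]),
            predicted_assignment=d["predicted_assignment"],
            final_assignment=d["final_assignment"],
            neighbors=[(pid, float(dd)) for pid, dd in d["neighbors"]],
            neighbor_label_curves={
                pid: {k: np.asarray(v) for k, v in curves.items()}
                for pid, curves in d["neighbor_label_curves"].items()},
            predicted_label_curves={
                k: np.asarray(v)
                for k, v in d["predicted_label_curves"].items()})


def cdss_report(patient: EncodedPatient, anchor: int,
                model: GuidedTemporalVAE, tree: ClusterTree,
                train_embeddings: list[TrajectoryEmbedding],
                train_cohort: EncodedCohort | None = None,
                k: int = 3) -> CdssReport:
    """Build the decision-support view for one index patient.

    Contains the predicted-from-anchor versus final latent trajectory with
    both tree assignments, the k nearest training trajectories by DTW, and
    the model-inferred label curves for the patient and neighbors.
    """
    if not (1 <= anchor <= patient.T):
        raise ValueError(f"anchor {anchor} outside 1..{patient.T}")
    pred_Z = model.encode(patient, anchor=anchor).means
    final_Z = model.embed(patient)
    pred_assign = assign([TrajectoryEmbedding(patient.patient_id, pred_Z)],
                         tree, provenance="predicted").rows[0]
    final_assign = assign([TrajectoryEmbedding(patient.patient_id, final_Z)],
                          tree, provenance="final").rows[0]
    neighbors = knn_similar(final_Z, train_embeddings, k=k)
    neighbor_curves = {}
    if train_cohort is not None:
        by_id = {p.patient_id: p for p in train_cohort}
        for pid, _d in neighbors:
            if pid in by_id:
                neighbor_curves[pid] = model.predict_labels(by_id[pid], 1)
    return CdssReport(
        patient_id=patient.patient_id, anchor=anchor,
        predicted_embedding=pred_Z, final_embedding=final_Z,
        predicted_assignment=pred_assign, final_assignment=final_assign,
        neighbors=neighbors,
        neighbor_label_curves=neighbor_curves,
        predicted_label_curves=model.predict_labels(patient, anchor))
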