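"""Evaluation experiments: prediction tables, missingness robustness,
cluster recovery and early subtype prediction.

All metrics are pooled strictly over observed targets.  Continuous MAE is
reported on the standardized scale (raw clinical scales are heterogeneous);
ordinal labels are scored both as regression (MAE on the integer level
scale) and as classification (weighted F1), and pooled rows are provided
for both groupings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .cluster import ClusterTree, TrajectoryEmbedding, assign
from .metrics import mae, weighted_f1
from .model import GuidedTemporalVAE, apply_feature_masking
from .preprocess import EncodedCohort, EncodedPatient, EncodingLayout


def mask_patient_inputs(patient: EncodedPatient, rate: float,
                        rng: np.random.Generator,
                        layout: EncodingLayout) -> EncodedPatient:
    """A copy of ``patient`` with extra test-time masking on its inputs.

    Used for robustness curves: predictors see the degraded record, while
    the untouched original supplies the evaluation targets.
    """
    x2, m2, hidden = apply_feature_masking(
        patient.x, patient.m, patient.t_obs, rate, rng, layout)
    return EncodedPatient(
        patient_id=patient.patient_id, x=x2, m=m2,
        t_val=patient.t_val.copy(), t_obs=patient.t_obs & ~hidden,
        s=patient.s.copy(), times=patient.times.copy())


def _anchor_list(T: int, scheme: str = "all") -> list[int]:
    if scheme == "all":
        return list(range(1, T)) if T > 1 else [1]
    if scheme == "half":
        return [max(1, int(np.ceil(T / 2)))]
    raise ValueError(f"unknown anchor scheme {scheme!r}")


def _collect(layout: EncodingLayout, predictions: dict,
             targets: EncodedCohort, anchor_sets: dict) -> dict:
    """Pool (pred, truth) pairs per variable kind over observed targets."""
    pools: dict = {"continuous": ([], []), "binary": ([], []),
                   "ordinal": ([], []), "ordinal_class": ([], [])}
    for p in targets:
        g_val = p.g_val(targets.layout)
        g_obs = p.g_obs(targets.layout)
        for t in anchor_sets[p.patient_id]:
            pred = predictions[(p.patient_id, t)]
            for g_pos, spec in enumerate(layout.guided_specs):
                curve = pred[spec.name]
                obs = g_obs[t - 1:, g_pos]
                truth = g_val[t - 1:, g_pos][obs]
                if truth.size == 0:
                    continue
                if spec.kind == "continuous":
                    pools["continuous"][0].extend(curve[obs])
                    pools["continuous"][1].extend(truth)
                else:
                    cls = curve[obs].argmax(axis=1)
                    key = "binary" if spec.kind == "binary" else "ordinal"
                    if spec.kind == "ordinal":
                        pools["ordinal"][0].extend(cls)
                        pools["ordinal"][1].extend(truth)
                        pools["ordinal_class"][0].extend(cls)
                        pools["ordinal_class"][1].extend(truth)
                    else:
                        pools["binary"][0].extend(cls)
                        pools["binary"][1].extend(truth)
    return pools


def _metric_rows(model_name: str, pools: dict) -> list[dict]:
    rows = []

    def add(group, metric, value, n):
        rows.append({"model": model_name, "group": group,
                     "metric": metric, "value": value, "n_targets": n})

    cont_p, cont_t = pools["continuous"]
    ord_p, ord_t = pools["ordinal"]
    bin_p, bin_t = pools["binary"]
    ordc_p, ordc_t = pools["ordinal_class"]
    if cont_t:
        add("continuous", "mae", mae(cont_p, cont_t), len(cont_t))
    if ord_t:
        add("ordinal", "mae", mae(ord_p, ord_t), len(ord_t))
    if cont_t or ord_t:
        add("continuous+ordinal", "mae",
            mae(list(cont_p) + list(ord_p), list(cont_t) + list(ord_t)),
            len(cont_t) + len(ord_t))
    if bin_t:
        add("binary", "weighted_f1", weighted_f1(bin_p, bin_t), len(bin_t))
    if ordc_t:
        add("ordinal", "weighted_f1", weighted_f1(ordc_p, ordc_t),
            len(ordc_t))
    if bin_t or ordc_t:
        add("categorical", "weighted_f1",
            weighted_f1(list(bin_p) + list(ordc_p),
                        list(bin_t) + list(ordc_t)),
            len(bin_t) + len(ordc_t))
    return rows


def evaluate_predictions(models: dict, test: EncodedCohort,
                         anchor_scheme: str = "all",
                         input_cohort: EncodedCohort | None = None
                         ) -> pd.DataFrame:
    """MAE / weighted-F1 table over all (patient, anchor, horizon) targets.

    ``models`` maps a display name to any object with the shared
    ``predict_labels(patient, anchor)`` interface.  ``input_cohort``
    optionally supplies degraded inputs (same ids) while ``test`` supplies
    the targets.
    """
    layout = test.layout
    inputs = input_cohort if input_cohort is not None else test
    in_by_id = {p.patient_id: p for p in inputs}
    anchor_sets = {p.patient_id: _anchor_list(p.T, anchor_scheme)
                   for p in test}
    rows = []
    for name, predictor in models.items():
        if isinstance(predictor, GuidedTemporalVAE):
            pats = [in_by_id[p.patient_id] for p in test]
            sets = [anchor_sets[p.patient_id] for p in test]
            predictions = predictor.predict_labels_many(pats, sets)
        else:
            predictions = {}
            for p in test:
                ip = in_by_id[p.patient_id]
                for t in anchor_sets[p.patient_id]:
                    predictions[(p.patient_id, t)] = \
                        predictor.predict_labels(ip, t)
        pools = _collect(layout, predictions, test, anchor_sets)
        rows.extend(_metric_rows(name, pools))
    return pd.DataFrame(rows)


def aggregate_cv(fold_frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean ± std of each metric across the fold models."""
    allf = pd.concat(fold_frames, ignore_index=True)
    out = (allf.groupby(["model", "group", "metric"])["value"]
           .agg(["mean", "std", "count"]).reset_index())
    return out.rename(columns={"count": "n_folds"})


def robustness_to_missingness(models: dict, test: EncodedCohort,
                              rates=(0.0, 0.25, 0.5), seed: int = 0
                              ) -> pd.DataFrame:
    """Metrics under increasing additional test-time input masking.

    Targets are never masked; rate 0 reproduces
    :func:`evaluate_predictions` on the clean inputs.
    """
    if 0.0 not in rates:
        raise ValueError("rates must include 0")
    frames = []
    for rate in rates:
        rng = np.random.default_rng(seed)
        if rate == 0.0:
            degraded = test
        else:
            degraded = EncodedCohort(test.layout, test.stats, [
                mask_patient_inputs(p, rate, rng, test.layout)
                for p in test])
        df = evaluate_predictions(models, test, input_cohort=degraded)
        df["rate"] = rate
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def cluster_recovery(pred_branch: dict, pred_leaf: dict,
                     true_branch: dict, true_leaf: dict) -> dict:
    """Adjusted Rand index at both hierarchy levels plus contingency tables."""
    ids = sorted(pred_branch)
    pb = [pred_branch[i] for i in ids]
    tb = [true_branch[i] for i in ids]
    pl = [pred_leaf[i] for i in ids]
    tl = [true_leaf[i] for i in ids]
    return {
        "ari_root": float(adjusted_rand_score(tb, pb)),
        "ari_leaf": float(adjusted_rand_score(tl, pl)),
        "confusion_root": pd.crosstab(pd.Series(tb, name="truth"),
                                      pd.Series(pb, name="predicted")),
        "confusion_leaf": pd.crosstab(pd.Series(tl, name="truth"),
                                      pd.Series(pl, name="predicted")),
    }


def early_cluster_prediction(model: GuidedTemporalVAE, tree: ClusterTree,
                             cohort: EncodedCohort,
                             fractions=(0.25, 0.5, 0.75, 1.0)
                             ) -> pd.DataFrame:
    """Weighted F1 of anchor-stage cluster prediction vs final assignment.

    For each fraction f the anchor is ceil(f*T) per patient; the patient is
    embedded from x_{1:anchor} (posterior over the full trajectory) and
    assigned through the fitted tree, then compared with the full-history
    assignment.  f=1 is self-consistent by construction.
    """
    pats = list(cohort.patients)
    final_emb = [TrajectoryEmbedding(p.patient_id, Z)
                 for p, Z in zip(pats, model.embed_many(pats))]
    final = assign(final_emb, tree, provenance="final").leaf_of()
    rows = []
    for frac in fractions:
        anchors = [max(1, int(np.ceil(frac * p.T))) for p in pats]
        embs = [TrajectoryEmbedding(p.patient_id, Z) for p, Z in
                zip(pats, model.embed_many(pats, anchors=anchors))]
        pred = assign(embs, tree, provenance=f"anchor_{frac}").leaf_of()
        ids = [p.patient_id for p in pats]
        f1 = weighted_f1([pred[i] for i in ids], [final[i] for i in ids])
        rows.append({"fraction": frac, "weighted_f1": f1,
                     "n_patients": len(ids)})
    return pd.DataFrame(rows)
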