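# trajsubtype

Semi-supervised trajectory modelling and hierarchical subtyping for
multi-organ longitudinal clinical cohorts.

Registries of chronic multi-organ diseases (the motivating case is systemic
sclerosis) record mixed-type clinical variables at irregular visits with
heavy missingness. `trajsubtype` learns an organ-interpretable latent
trajectory for every patient with a guided temporal variational
autoencoder, then stratifies patients into a strict two-level hierarchy of
disease subtypes by k-means clustering with dynamic time warping (DTW)
distance in the latent space. A synthetic registry generator with a planted
subtype hierarchy makes the whole pipeline testable end to end without
access to any private registry.

## Model

For patient data x_{1:T} ∈ R^{D×T} (temporal variables), masks
m_{1:T} ∈ {0,1}^{D×T}, statics s ∈ R^N and guided organ labels
g_{1:T} ∈ R^{P×T} with G ⊆ X, the model learns latent trajectories
z_{1:T} ∈ R^{L×T}:

- **Encoder** (per-visit MLP + LSTM): given x_{1:t} and m_{1:t} up to an
  anchor visit t, outputs a diagonal-Gaussian posterior q(z_{1:T} | x_{1:t},
  m_{1:t}, s) over the *full* trajectory, future visits included.
- **Guidance decoders**: one small MLP per guided label, reading only its
  organ's latent block, trained to reconstruct and predict g_{t:T}. This
  dedicates separate latent dimensions to each organ's dynamics.
- **Reconstruction decoder**: maps sampled z to distributions over all of
  x (Gaussian with constant variance / categorical), trained on x_{1:t}.
- **Learned prior**: p(z_1 | s), p(z_τ | z_{τ−1}, s), regularizing the
  posterior through a closed-form KL term.

Losses (cross-entropy / MSE) are computed strictly over observed entries,
and 20% of observed inputs are hidden per batch during training while still
being scored ("feature masking"), which teaches model-based imputation.
Subtyping fits DTW k-means with DBA barycenter centroids on training
embeddings: a mild/severe root split (k=2, branch named by mean predicted
severity), then 2 leaves within mild and 3 within severe; held-out patients
are assigned to the nearest centroids without refitting. The package also
provides non-ML baselines (cohort mean, carry-forward), a non-temporal MLP
baseline, prediction/robustness metrics, UMAP latent-space exports, and a
clinical-decision-support report (early subtype prediction plus k=3
nearest-neighbour patient retrieval).

## Worked example

```python
import trajsubtype as ts
from trajsubtype.cluster import TrajectoryEmbedding, fit_hierarchy, assign
from trajsubtype.evaluate import cluster_recovery

# simulate a registry with a planted 2->(2,3) subtype hierarchy
cohort, truth = ts.generate_cohort(ts.SimConfig(n_patients=600, seed=1))
cohort, _ = ts.apply_inclusion_filters(cohort)
plan = ts.make_split(cohort.ids(), seed=1)                  # 85/15 + 5 folds
stats = ts.fit_normalization(cohort.subset(plan.train_ids))
enc = ts.encode(cohort, stats)

model = ts.train(enc.subset(plan.train_ids), ts.ModelConfig(epochs=40, seed=1))

train_pats = list(enc.subset(plan.train_ids).patients)
embs = [TrajectoryEmbedding(p.patient_id, Z)
        for p, Z in zip(train_pats, model.embed_many(train_pats))]
tree = fit_hierarchy(embs, model.severity_scores(train_pats), seed=1)
table = assign(embs, tree, provenance="train")
rec = cluster_recovery(table.branch_of(), table.leaf_of(),
                       truth.branch_of(), truth.leaf_of())
print(f"root ARI {rec['ari_root']:.3f}  leaf ARI {rec['ari_leaf']:.3f}")
```

Output:

```
root ARI 1.000  leaf ARI 0.877
```

The root adjusted Rand index of 1.0 means the mild/severe split is
recovered exactly; the leaf ARI of 0.88 means the five planted subtypes are
recovered nearly cleanly from 30%-missing mixed-type observations.

The same pipeline is available from the shell:

```sh
trajsubtype simulate --out run/ --n-patients 600 --seed 1
trajsubtype preprocess --run run/
trajsubtype train --run run/ --epochs 40
trajsubtype cluster --run run/
trajsubtype evaluate --run run/
trajsubtype cdss --run run/ --patient p0007 --anchor 2
```

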