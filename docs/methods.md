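# Methods

## Problem setting

Multi-center disease registries record mixed-type clinical variables at
irregular visit times, with heavy and uneven missingness. The goal of this
package is to (i) learn a smooth, organ-interpretable latent trajectory for
every patient from such records, and (ii) stratify patients into a strict
two-level hierarchy of disease subtypes by clustering those trajectories.
The motivating disease is systemic sclerosis, where multi-organ involvement
and severity dynamics are believed to define subtypes beyond the
traditional skin-based classification, but nothing in the implementation is
specific to one disease: the variable schema, organ assignment and
label-derivation rules are user configuration.

## Data model

A cohort is a set of patient records; each record holds strictly increasing
visit times (years since first visit), a (T, D) matrix of temporal
variables with a boolean observedness mask (`True` = measured), and static
demographics. Variables are continuous, binary or ordinal and carry one of
three roles: plain encoder inputs (X), guided organ labels (G), or statics
(S). Guided labels are a subset of the temporal inputs (G ⊆ X): their
observed values are fed to the encoder like any other variable *and* serve
as supervision targets. Labels may be derived per visit from raw variables
by rule expressions (comparators combined with any/all/not, plus ordered
severity stages); a derived label is set only when every referenced
variable is observed at that visit, so rules propagate missingness instead
of guessing.

Inclusion filters mirror registry practice: patients need 2–14 visits
(more heavily sampled trajectories would dominate training) and age ≥ 18 at
the first recorded visit. Outlying continuous values (|standardized
value| > 5 by default) are set to unobserved rather than dropping the
patient — conservative, and it preserves trajectories. Because outlier
masking shrinks the standard deviation it is computed from, the operation
is idempotent only when the caller passes fixed normalization statistics;
the `stats=None` path estimates them once from the cohort given.

Continuous variables are standardized with train-split moments (a constant
training variable gets sd 1 and a degeneracy flag); binary and ordinal
variables are one-hot expanded. Unobserved cells hold the train-derived
placeholder — 0 for a standardized continuous variable, the training class
frequency vector for a one-hot block — and the mask channel records true
observedness.

## The guided temporal VAE

Per visit, the encoder MLP embeds the value and mask channels (plus a
time-since-baseline channel, scaled by 10 years); an LSTM accumulates the
visit embeddings. Conditioned on the recurrent state at an anchor visit t,
a static embedding, and a one-hot encoding of the target visit index, a
posterior head outputs the mean and variance of a diagonal Gaussian over
the *full* latent trajectory z_{1:T} — including future visits. This
single-pass design matches one encoder serving every anchor; the recurrent
state is causal, so one LSTM pass per patient serves all anchors.

The latent space is partitioned into contiguous per-organ blocks, two
dimensions per organ by default — one per guided dynamic (involvement,
severity). Each guided label has its own small guidance MLP that reads
*only* its organ's block, which is what makes the blocks organ-specific;
this isolation is structural (a column slice), so it holds bit-exactly. A
reconstruction decoder maps z_tau to distributions over all temporal
inputs: Gaussian with constant variance for continuous variables (so the
negative log-likelihood is mean squared error up to a constant), and
categorical distributions for one-hot blocks. A learned prior
p(z_1 | s), p(z_tau | z_{tau-1}, s) is conditioned on a single
reparameterized sample of the previous latent, and the KL against it is the
closed-form diagonal-Gaussian expression.

### Objective

For every patient and every anchor t = 1..T: encode the (feature-masked)
history x_{1:t}, sample z_{1:T} once, score reconstruction of x_{1:t} and
guidance prediction of g_{t:T} over *observed targets only* (observedness
taken before feature masking), and add the KL. Likelihood terms are
averaged per observed entry. The KL is normalized per latent dimension and
visit: the raw summed KL is two orders of magnitude larger than the
entry-averaged likelihood terms and, at full weight, was observed to
collapse the latent space onto a single severity continuum (the first
principal component carried 99% of the variance), which destroys the
within-branch subtype structure even though headline losses look fine. The
default KL weight is 0.2 on this normalized scale, annealed linearly over
the first half of training.

### Missing data

Unobserved inputs enter as placeholders flagged by the mask channel.
During training, an exact `round(0.2 × observed)` of the observed cells in
each batch is additionally hidden ("feature masking") — replaced by the
placeholder with mask set to unobserved — while the loss still scores them
as targets. This teaches model-based imputation: downstream imputation
returns observed entries unchanged and fills unobserved ones with the
decoder's predictive mean or modal class from the full-history posterior.

### Optimization and initialization

Adam over mini-batches of 16 patients, learning rate 3e-3, 40 epochs by
default; weights use the uniform fan-in scheme with the LSTM forget-gate
bias at +1. The Gaussian output heads (posterior and both prior heads) are
zero-initialized with the variance bias set so both start at the same small
variance (0.05). Matched small variances keep the initial KL near zero and
give the decoders a high signal-to-noise latent sample; without this the
optimization sits on a long saddle — the sampled-latent noise drowns the
mean signal and the decoders learn only population marginals for roughly
the first 150 epochs, far beyond the intended training budget. Non-finite
losses abort training with a diagnostic. Everything is driven by a single
integer seed and is bit-reproducible.

### Splits and model selection

85/15 train/test split (test count floored) with five disjoint CV folds
partitioning the training ids, all reproducible under a seed. Random
hyperparameter search samples configurations, trains per fold and returns
the configuration minimizing the fold-averaged validation loss (computed
without feature masking at full KL weight).

## Subtyping

Patients are embedded as the posterior mean trajectory (L × T) given the
full history. Distances between trajectories of different lengths use
classic dynamic time warping — boundary-matched monotone paths with steps
{(1,0),(0,1),(1,1)} over squared Euclidean frame costs, distance the square
root of the optimal accumulated cost. Sequences are at most 14 frames, so
no warping window is used and the dynamic program is exact.

k-means uses DTW-barycenter (DBA) centroids of fixed length equal to the
median member length, one DBA refinement pass per k-means iteration, best
of 10 restarts seeded k-means++-style on DTW distances. Inertia (sum of
squared assigned distances) is guarded to be non-increasing within a
restart: a DBA update that would raise it is rolled back and the restart
stops. Empty clusters are reseeded from the farthest point.

The hierarchy is strict and top-down: a k=2 root split, the branch with
the higher mean model-predicted severity (mean probability of any
non-zero severity stage across organs and visits) labelled "severe", then
k-means within the mild branch (2 leaves) and the severe branch (3
leaves). Leaves therefore nest in branches by construction, and the fit
asserts it. Held-out patients are assigned nearest-branch-then-
nearest-leaf without refitting centroids. A nesting score between
independently fitted flat k=2 and k=5 partitions — the fraction of
patients whose coarse label matches their fine cluster's majority parent —
quantifies how hierarchical the flat solutions already are. Similar-patient
retrieval is plain k-nearest-neighbours on DTW distance (k=3 by default,
ties broken by patient id).

## Synthetic registry

The generator is first-class, tested code that defines the study
conditions. Each patient draws a leaf subtype (proportions 0.30/0.20 mild,
0.20/0.15/0.15 severe), a visit count uniform on {2..14}, and visit gaps
uniform on 0.3–1.2 years. Per organ, two latent logit processes
(involvement, severity) follow the leaf prototype line in visit index plus
a patient-level random intercept (sd 0.5) and stationary AR(1) noise
(rho 0.7, sd 0.5). Involvement labels are Bernoulli draws of the logistic
involvement logit; severity stages threshold the severity logit at 0 and 2.
Three observed features per organ are linear-Gaussian (noise sd 0.5) or
logistic emissions of the two organ latents; age is uniform 18–80 and one
binary demographic is balanced. Missingness is 30% MCAR per cell by
default, with an optional value-dependent (MNAR) mode whose masking
probability rises with the standardized value.

The planted hierarchy is genuinely nested: each branch carries a shared
logit signature (scaled by the separation parameter, default 3.0) and each
leaf adds a smaller deviation (scale 0.6 of the branch scale). An earlier
flat design — five unrelated leaf patterns — did not behave as a
hierarchy: the top-level split carved out the single most extreme leaf
instead of the two branches. With the nested design, clustering the *true*
latent curves recovers the root split perfectly and the leaves with ARI
0.75–0.96 across seeds; that ceiling is what the model-based recovery is
compared against.

What the generator does not emulate: treatment effects, informative visit
timing, cross-organ correlation beyond the branch signature, label noise in
the rule definitions themselves, and real registries' non-MCAR missingness
(except through the optional MNAR mode). Passing recovery tests on this
generator therefore demonstrates that the pipeline recovers planted
structure of realistic shape and noise scale — not that it would find the
same structure in any particular real registry.

## Evaluation choices

Prediction metrics pool all (patient, anchor, horizon) targets with
anchors t = 1..T-1 and horizons tau = t..T, strictly over observed
targets. MAE for continuous variables is on the standardized scale (raw
clinical scales are heterogeneous); ordinal labels are scored both as
regression (MAE on the integer level scale) and classification
(weighted F1), and pooled rows are reported for both groupings. Weighted
F1 and the adjusted Rand index delegate to scikit-learn behind this
package's interface; the test suite checks them against independent
brute-force confusion-matrix computations. Robustness curves add test-time
masking to encoder inputs only — evaluation targets are never masked — so
rate 0 reproduces the clean evaluation exactly.

On the default synthetic cohort the carry-forward heuristic is a strong
label predictor — the planted labels are highly persistent within patients
(persistent random intercepts plus rho = 0.7 autocorrelation) — so the
trained model's advantage over it is small or absent there; the model
clearly beats the cohort-mean baseline on both metrics, and its advantage
is in imputation, trajectory embedding and forecasting under degraded
inputs rather than raw one-step label persistence.

Early subtype prediction embeds each held-out patient from the first
ceil(f·T) visits (the posterior still spans the full trajectory), assigns
through the fitted tree, and scores weighted F1 against the full-history
assignment; f = 1 is exact by construction.

## Numerical choices and limitations

The neural stack runs on an in-repo reverse-mode autodiff core over numpy
(dense layers, LSTM, gathers, masked reductions), checked against central
finite differences. Posterior/prior variances use softplus with a 1e-4
floor. Categorical encodings reject levels outside the schema's declared
range by name. Ties in k-NN and cluster bookkeeping break by ascending
patient id for determinism. DBA is a local optimizer: centroids depend on
initialization, which the restart scheme and the inertia guard mitigate but
do not eliminate. The hierarchy supports exactly two levels with a 2 →
(mild, severe) branching; deeper trees are out of scope. Probabilities are
raw model outputs with no calibration step. Training cost grows with the
square of the visit count per patient (all anchors are enumerated), which
is acceptable at T ≤ 14.

Study sizes used by the reproduction script and acceptance tests — 600
patients per replicate, three replicates, 40 training epochs — were chosen
as the smallest sizes at which subtype recovery is stable seed to seed.
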