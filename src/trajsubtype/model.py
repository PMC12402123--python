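"""Semi-supervised guided temporal VAE for multi-organ trajectories.

The generative story: a patient's state at every visit is an L-dimensional
latent vector partitioned into per-organ blocks.  An LSTM encoder reads the
visit history (values concatenated with their missingness mask, plus static
demographics) up to an anchor visit t and outputs a diagonal-Gaussian
posterior over the *full* latent trajectory z_{1:T} — past, current and
future visits alike.  Three families of decoders constrain the latents:

* an unsupervised reconstruction decoder mapping z_tau to distributions over
  every temporal input variable (Gaussian with constant variance for
  continuous, categorical for one-hot blocks), trained on x_{1:t};
* one small guidance decoder per organ label, reading *only* its organ's
  latent block and trained to reconstruct/predict the label at visits
  t..T — this is what makes individual latent blocks organ-interpretable;
* an autoregressive learned prior p(z_1 | s), p(z_tau | z_{tau-1}, s)
  regularizing the posterior through a closed-form Gaussian KL.

All likelihood terms are computed exclusively over genuinely observed
entries, and a fraction of observed inputs is hidden ("feature masking")
during training while still being scored, which teaches the model to impute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._autodiff import Tensor, concat, stack_rows
from ._nn import LSTM, MLP, Adam
from .preprocess import EncodedCohort, EncodedPatient, EncodingLayout, \
    NormalizationStats, SplitPlan, build_layout
from .schema import ORGANS, CohortSchema

_VAR_FLOOR = 1e-4


# ---------------------------------------------------------------------------
# Latent partition and Gaussian sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatentPartition:
    """Contiguous per-organ index ranges within 1..L (plus optional shared
    block at the end that no guidance decoder reads)."""

    per_organ: int = 3
    shared: int = 0

    @property
    def L(self) -> int:
        return self.per_organ * len(ORGANS) + self.shared

    def organ_slice(self, organ: str) -> slice:
        i = ORGANS.index(organ)
        return slice(i * self.per_organ, (i + 1) * self.per_organ)


@dataclass
class GaussianSequence:
    """Diagonal Gaussian over a latent trajectory; (L, T) means/variances."""

    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self):
        self.means = np.asarray(self.means, float)
        self.variances = np.asarray(self.variances, float)
        if self.means.shape != self.variances.shape:
            raise ValueError("means and variances must share a shape")
        if not np.all(np.isfinite(self.variances)) or \
                np.any(self.variances <= 0):
            raise ValueError("variances must be strictly positive and finite")

    @property
    def L(self):
        return self.means.shape[0]

    @property
    def T(self):
        return self.means.shape[1]


def kl_term(q: GaussianSequence, p: GaussianSequence) -> float:
    """Closed-form KL(q || p) for diagonal Gaussians, summed over dims and
    visits; nonnegative, zero iff q equals p."""
    if q.means.shape != p.means.shape:
        raise ValueError("shape mismatch between q and p")
    vq, vp = q.variances, p.variances
    kl = 0.5 * (np.log(vp / vq) + (vq + (q.means - p.means) ** 2) / vp - 1.0)
    return float(kl.sum())


def sample(q: GaussianSequence, seed: int | np.random.Generator) -> np.ndarray:
    """Reparameterized draw z = mean + sqrt(var) * eps."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    eps = rng.standard_normal(q.means.shape)
    return q.means + np.sqrt(q.variances) * eps


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture and training settings.

    Two latent dimensions per organ (one per guided dynamic: involvement
    and severity) keep the organ blocks compact; the KL weight applies to a
    KL normalized per latent dimension and visit, so it is on the same
    per-unit scale as the entry-averaged likelihood terms — a full-strength
    per-unit KL was observed to collapse the latent space onto a single
    severity continuum, hence the moderate default.
    """

    latent_per_organ: int = 2
    shared_latent: int = 0
    visit_embed_width: int = 48
    rnn_width: int = 48
    static_embed_width: int = 8
    posterior_hidden: int = 48
    prior_hidden: int = 32
    decoder_hidden: int = 48
    guidance_hidden: int = 16
    feature_mask_rate: float = 0.20
    w_recon: float = 1.0
    w_guide: float = 1.0
    w_kl: float = 0.2
    kl_anneal_frac: float = 0.5
    recon_variance: float = 1.0     # constant-variance Gaussian => MSE
    init_latent_var: float = 0.05   # initial posterior/prior variance
    learning_rate: float = 3e-3
    batch_size: int = 16
    epochs: int = 40
    max_T: int = 14
    include_time_feature: bool = True
    time_scale: float = 10.0        # years; keeps the time channel O(1)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.feature_mask_rate < 1.0):
            raise ValueError("feature_mask_rate must be in [0, 1)")


@dataclass
class LossBreakdown:
    recon_x: float
    guide_g: float
    kl: float
    total: float
    n_recon_targets: int
    n_guide_targets: int
    details: dict | None = None


# ---------------------------------------------------------------------------
# Feature masking
# ---------------------------------------------------------------------------

def apply_feature_masking(x: np.ndarray, m: np.ndarray, t_obs: np.ndarray,
                          rate: float, rng, layout: EncodingLayout
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hide an exact ``round(rate * n_observed)`` of observed cells.

    Cells are (visit, variable) pairs; hidden cells get the training
    placeholder and mask=False in the returned (x', m'), while the caller
    keeps scoring them as targets.  Originally unobserved cells are never
    touched.  Returns (x', m', hidden) where ``hidden`` is the (T, D)
    boolean matrix of newly hidden cells.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must be in [0, 1)")
    x2, m2 = x.copy(), m.copy()
    hidden = np.zeros_like(t_obs)
    if rate == 0.0:
        return x2, m2, hidden
    obs_cells = np.argwhere(t_obs)
    n_hide = int(round(rate * len(obs_cells)))
    if n_hide == 0:
        return x2, m2, hidden
    pick = rng.choice(len(obs_cells), size=n_hide, replace=False)
    for i, j in obs_cells[pick]:
        sl = layout.col_slices[j]
        x2[i, sl] = layout.placeholder[sl]
        m2[i, sl] = False
        hidden[i, j] = True
    return x2, m2, hidden


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

class GuidedTemporalVAE:
    """Encoder + learned prior + reconstruction and guidance decoders."""

    def __init__(self, layout: EncodingLayout, config: ModelConfig,
                 stats: NormalizationStats | None = None):
        self.layout = layout
        self.config = config
        self.stats = stats
        self.partition = LatentPartition(config.latent_per_organ,
                                         config.shared_latent)
        self.loss_history: list[dict] = []
        L = self.partition.L
        rng = np.random.default_rng(config.seed)

        Dx = layout.D_enc + (1 if config.include_time_feature else 0)
        self._Dx = Dx
        self.visit_mlp = MLP(2 * Dx, [config.visit_embed_width],
                             config.visit_embed_width, rng)
        self.lstm = LSTM(config.visit_embed_width, config.rnn_width, rng)
        self.static_mlp = MLP(max(layout.S_enc, 1),
                              [config.static_embed_width],
                              config.static_embed_width, rng)
        post_in = config.rnn_width + config.static_embed_width + config.max_T
        self.posterior_head = MLP(post_in, [config.posterior_hidden],
                                  2 * L, rng)
        self.prior_init = MLP(config.static_embed_width,
                              [config.prior_hidden], 2 * L, rng)
        self.prior_trans = MLP(L + config.static_embed_width,
                               [config.prior_hidden], 2 * L, rng)
        # Gaussian head initialization: zero weights, with the variance half
        # of the bias set so posterior and prior both start at the same small
        # variance.  Matched small variances keep the initial KL near zero
        # while giving the decoders a high signal-to-noise latent sample,
        # which avoids the long saddle where the decoder ignores z.
        b_var = float(np.log(np.expm1(config.init_latent_var)))
        for head in (self.posterior_head, self.prior_init, self.prior_trans):
            head.layers[-1].W.data[:] = 0.0
            head.layers[-1].b.data[:] = 0.0
            head.layers[-1].b.data[L:] = b_var
        self.decoder = MLP(L, [config.decoder_hidden], layout.D_enc, rng)
        self.guidance: dict[str, MLP] = {}
        for spec in layout.guided_specs:
            width = 1 if spec.kind == "continuous" else spec.levels
            self.guidance[spec.name] = MLP(
                config.latent_per_organ, [config.guidance_hidden], width, rng)

        # variable groupings reused by the loss
        self._groups = self._build_groups()

    # -- parameters --------------------------------------------------------
    def parameters(self, include_guidance: bool = True) -> list[Tensor]:
        mods = [self.visit_mlp, self.lstm, self.static_mlp,
                self.posterior_head, self.prior_init, self.prior_trans,
                self.decoder]
        params = [p for m in mods for p in m.parameters()]
        if include_guidance:
            for name in sorted(self.guidance):
                params += self.guidance[name].parameters()
        return params

    def _build_groups(self):
        """Group temporal variables by (kind, width) for batched losses."""
        groups: dict[tuple, list[int]] = {}
        for j, v in enumerate(self.layout.schema.temporal):
            w = 1 if v.kind == "continuous" else v.levels
            groups.setdefault((v.kind == "continuous", w), []).append(j)
        return groups

    # -- encoder machinery --------------------------------------------------
    def _batch_inputs(self, pats: list[EncodedPatient],
                      inputs: list[tuple[np.ndarray, np.ndarray]] | None
                      ) -> tuple[np.ndarray, np.ndarray, int]:
        """Pad encoder inputs to (B, T_max, 2*Dx) value+mask channels."""
        cfg = self.config
        B = len(pats)
        T_list = [p.T for p in pats]
        T_max = max(T_list)
        if T_max > cfg.max_T:
            raise ValueError(f"trajectory length {T_max} exceeds the "
                             f"configured maximum {cfg.max_T}")
        X = np.zeros((B, T_max, 2 * self._Dx))
        S = np.zeros((B, max(self.layout.S_enc, 1)))
        for b, p in enumerate(pats):
            x, m = (p.x, p.m) if inputs is None else inputs[b]
            T = p.T
            X[b, :T, :self.layout.D_enc] = x
            X[b, :T, self._Dx:self._Dx + self.layout.D_enc] = m.astype(float)
            if cfg.include_time_feature:
                X[b, :T, self._Dx - 1] = p.times / cfg.time_scale
                X[b, :T, -1] = 1.0      # time channel is always observed
            if self.layout.S_enc:
                S[b] = p.s
        return X, S, T_max

    def _encoder_states(self, X: np.ndarray, S: np.ndarray, T_max: int
                        ) -> tuple[Tensor, Tensor]:
        """(T_max*B, rnn_width) hidden states (row t*B+b) and static embeds."""
        B = X.shape[0]
        flat = Tensor(X.reshape(B * T_max, -1))
        E = self.visit_mlp(flat)                     # (B*T_max, w)
        steps = [E[np.arange(B) * T_max + t] for t in range(T_max)]
        h_steps = self.lstm(steps)                   # list of (B, W)
        H = stack_rows(h_steps).reshape(T_max * B, self.config.rnn_width)
        U = self.static_mlp(Tensor(S)).tanh()
        return H, U

    def _posterior_rows(self, H: Tensor, U: Tensor, B: int,
                        rb: np.ndarray, rt: np.ndarray, rtau: np.ndarray
                        ) -> tuple[Tensor, Tensor, Tensor]:
        """Posterior (mu, var) for rows (patient rb, anchor rt, visit rtau)."""
        cfg = self.config
        h_rows = H[(rt - 1) * B + rb]
        u_rows = U[rb]
        onehot = np.zeros((len(rb), cfg.max_T))
        onehot[np.arange(len(rb)), rtau - 1] = 1.0
        post = self.posterior_head(concat([h_rows, u_rows, Tensor(onehot)],
                                          axis=1))
        L = self.partition.L
        mu = post[:, :L]
        var = post[:, L:].softplus() + _VAR_FLOOR
        return mu, var, u_rows

    # -- public single-patient operations -----------------------------------
    def encode(self, patient: EncodedPatient, anchor: int | None = None,
               inputs: tuple[np.ndarray, np.ndarray] | None = None
               ) -> GaussianSequence:
        """Posterior q(z_{1:T} | x_{1:anchor}, m, s) as an (L, T) Gaussian.

        ``anchor`` defaults to T (full history).  Deterministic given the
        parameters and inputs.
        """
        T = patient.T
        t = T if anchor is None else int(anchor)
        if not (1 <= t <= T):
            raise ValueError(f"anchor {t} outside 1..{T}")
        X, S, T_max = self._batch_inputs([patient],
                                         None if inputs is None else [inputs])
        # the LSTM is causal, so the state at the anchor sees only x_{1:t}
        H, U = self._encoder_states(X, S, T_max)
        rb = np.zeros(T, dtype=int)
        rt = np.full(T, t, dtype=int)
        rtau = np.arange(1, T + 1)
        mu, var, _ = self._posterior_rows(H, U, 1, rb, rt, rtau)
        return GaussianSequence(mu.data.T.copy(), var.data.T.copy())

    def prior(self, s_enc: np.ndarray,
              z_samples: np.ndarray | None = None,
              T: int | None = None) -> GaussianSequence:
        """Autoregressive prior p(z_1 | s), p(z_tau | z_{tau-1}, s).

        ``z_samples`` is an (L, T-1) matrix of sampled previous latents; when
        omitted, T must be 1.
        """
        L = self.partition.L
        if z_samples is None:
            if T not in (None, 1):
                raise ValueError("z_samples required for T > 1")
            T = 1
        else:
            z_samples = np.asarray(z_samples, float)
            T = z_samples.shape[1] + 1
        S = np.asarray(s_enc, float).reshape(1, -1)
        U = self.static_mlp(Tensor(S)).tanh()
        p0 = self.prior_init(U)
        means = [p0.data[0, :L]]
        varis = [np.logaddexp(0.0, p0.data[0, L:]) + _VAR_FLOOR]
        for tau in range(1, T):
            inp = np.concatenate([z_samples[:, tau - 1], U.data[0]])
            pt = self.prior_trans(Tensor(inp.reshape(1, -1)))
            means.append(pt.data[0, :L])
            varis.append(np.logaddexp(0.0, pt.data[0, L:]) + _VAR_FLOOR)
        return GaussianSequence(np.stack(means, axis=1),
                                np.stack(varis, axis=1))

    def decode_inputs(self, z: np.ndarray) -> dict:
        """Predictive distributions over the temporal inputs given (L, T) z.

        Continuous: Gaussian mean (constant variance); binary/ordinal:
        categorical probabilities summing to one.
        """
        z = np.asarray(z, float)
        out = self.decoder(Tensor(z.T)).data        # (T, D_enc)
        result = {}
        for j, v in enumerate(self.layout.schema.temporal):
            sl = self.layout.col_slices[j]
            block = out[:, sl]
            if v.kind == "continuous":
                result[v.name] = block[:, 0]
            else:
                e = np.exp(block - block.max(axis=1, keepdims=True))
                result[v.name] = e / e.sum(axis=1, keepdims=True)
        return result

    def guidance_predict(self, z: np.ndarray, name: str) -> np.ndarray:
        """Label distribution sequence from the organ's latent block only."""
        if name not in self.guidance:
            raise KeyError(f"{name!r} is not a guided variable")
        spec = self.layout.schema[name]
        z = np.asarray(z, float)
        block = z[self.partition.organ_slice(spec.organ), :]
        out = self.guidance[name](Tensor(block.T)).data
        if spec.kind == "continuous":
            return out[:, 0]
        e = np.exp(out - out.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def embed(self, patient: EncodedPatient) -> np.ndarray:
        """Full-history latent mean trajectory, (L, T)."""
        return self.encode(patient).means

    def predict_labels(self, patient: EncodedPatient, anchor: int,
                       inputs=None) -> dict:
        """Guided-label curves for visits anchor..T from posterior means."""
        q = self.encode(patient, anchor=anchor, inputs=inputs)
        out = {}
        for name in self.guidance:
            pred = self.guidance_predict(q.means, name)
            out[name] = pred[anchor - 1:]
        return out

    def embed_many(self, pats: list[EncodedPatient],
                   anchors: list[int] | None = None,
                   batch_size: int = 256) -> list[np.ndarray]:
        """Latent mean trajectories for many patients in one encoder pass.

        ``anchors`` gives the per-patient anchor visit (default: full
        history T); each returned matrix is (L, T_i).
        """
        if anchors is None:
            anchors = [p.T for p in pats]
        out: list[np.ndarray] = []
        for start in range(0, len(pats), batch_size):
            chunk = pats[start:start + batch_size]
            a_chunk = anchors[start:start + batch_size]
            X, S, T_max = self._batch_inputs(chunk, None)
            H, U = self._encoder_states(X, S, T_max)
            rb = np.concatenate([np.full(p.T, b)
                                 for b, p in enumerate(chunk)])
            rt = np.concatenate([np.full(p.T, a)
                                 for p, a in zip(chunk, a_chunk)])
            rtau = np.concatenate([np.arange(1, p.T + 1) for p in chunk])
            mu, _, _ = self._posterior_rows(H, U, len(chunk), rb, rt, rtau)
            offs = np.cumsum([0] + [p.T for p in chunk])
            for b, p in enumerate(chunk):
                out.append(mu.data[offs[b]:offs[b + 1]].T.copy())
        return out

    def predict_labels_many(self, pats: list[EncodedPatient],
                            anchor_sets: list[list[int]],
                            batch_size: int = 256) -> dict:
        """Guided-label curves for many (patient, anchor) pairs at once.

        Returns {(patient_id, anchor): {label: curve over visits
        anchor..T}} computed from posterior means, as in
        :meth:`predict_labels`.
        """
        result: dict = {}
        for start in range(0, len(pats), batch_size):
            chunk = pats[start:start + batch_size]
            sets = anchor_sets[start:start + batch_size]
            X, S, T_max = self._batch_inputs(chunk, None)
            H, U = self._encoder_states(X, S, T_max)
            rb, rt, rtau = [], [], []
            for b, (p, a_set) in enumerate(zip(chunk, sets)):
                for t in a_set:
                    n = p.T - t + 1
                    rb.append(np.full(n, b))
                    rt.append(np.full(n, t))
                    rtau.append(np.arange(t, p.T + 1))
            rb = np.concatenate(rb)
            rt = np.concatenate(rt)
            rtau = np.concatenate(rtau)
            mu, _, _ = self._posterior_rows(H, U, len(chunk), rb, rt, rtau)
            z = mu.data                                      # (R, L)
            preds = {}
            for spec in self.layout.guided_specs:
                block = z[:, self.partition.organ_slice(spec.organ)]
                out = self.guidance[spec.name](Tensor(block)).data
                if spec.kind != "continuous":
                    e = np.exp(out - out.max(axis=1, keepdims=True))
                    out = e / e.sum(axis=1, keepdims=True)
                else:
                    out = out[:, 0]
                preds[spec.name] = out
            pos = 0
            for b, (p, a_set) in enumerate(zip(chunk, sets)):
                for t in a_set:
                    n = p.T - t + 1
                    result[(p.patient_id, t)] = {
                        name: preds[name][pos:pos + n]
                        for name in preds}
                    pos += n
        return result

    def impute(self, patient: EncodedPatient) -> np.ndarray:
        """Complete the (T, D) target matrix: observed entries unchanged,
        unobserved filled with the decoder's predictive mean / modal class."""
        q = self.encode(patient)
        dec = self.decode_inputs(q.means)
        out = patient.t_val.copy()
        for j, v in enumerate(self.layout.schema.temporal):
            pred = dec[v.name]
            fill = pred if v.kind == "continuous" else pred.argmax(axis=1)
            missing = ~patient.t_obs[:, j]
            out[missing, j] = fill[missing]
        return out

    def severity_score(self, patient: EncodedPatient) -> float:
        """Mean predicted probability of any non-zero severity stage,
        averaged over severity labels and visits; used to name the severe
        branch of the cluster hierarchy."""
        q = self.encode(patient)
        scores = []
        for spec in self.layout.guided_specs:
            if spec.label_type != "severity":
                continue
            probs = self.guidance_predict(q.means, spec.name)
            scores.append(1.0 - probs[:, 0])
        return float(np.mean(scores))

    def severity_scores(self, pats: list[EncodedPatient]) -> dict:
        """Batched :meth:`severity_score` over many patients."""
        Zs = self.embed_many(pats)
        sev_specs = [s for s in self.layout.guided_specs
                     if s.label_type == "severity"]
        out = {}
        for p, Z in zip(pats, Zs):
            scores = [float(np.mean(
                1.0 - self.guidance_predict(Z, s.name)[:, 0]))
                for s in sev_specs]
            out[p.patient_id] = float(np.mean(scores)) if scores else 0.0
        return out

    # -- loss ----------------------------------------------------------------
    def loss(self, pats: list[EncodedPatient],
             rng: np.random.Generator | int = 0,
             kl_weight: float = 1.0,
             inputs: list[tuple[np.ndarray, np.ndarray]] | None = None,
             target_obs: list[np.ndarray] | None = None,
             details: bool = False,
             build_graph: bool = True) -> tuple[LossBreakdown, Tensor | None]:
        """Per-anchor-time training objective on a batch.

        For every patient and every anchor t=1..T the encoder posterior over
        z_{1:T} is sampled once; reconstruction scores x_{1:t} and guidance
        scores g_{t:T}, both only over observed targets (``target_obs``
        overrides the stored pre-masking observedness); the KL aligns the
        posterior with the autoregressive prior.  Returns the breakdown and,
        when ``build_graph``, the total-loss Tensor for backprop.
        """
        if not pats:
            raise ValueError("empty batch")
        rng = rng if isinstance(rng, np.random.Generator) \
            else np.random.default_rng(rng)
        cfg = self.config
        B = len(pats)
        T_list = [p.T for p in pats]
        X, S, T_max = self._batch_inputs(pats, inputs)
        H, U = self._encoder_states(X, S, T_max)

        rb = np.concatenate([np.full(T * T, b)
                             for b, T in enumerate(T_list)])
        rt = np.concatenate([np.repeat(np.arange(1, T + 1), T)
                             for T in T_list])
        rtau = np.concatenate([np.tile(np.arange(1, T + 1), T)
                               for T in T_list])
        R = len(rb)
        mu, var, u_rows = self._posterior_rows(H, U, B, rb, rt, rtau)
        L = self.partition.L
        eps = rng.standard_normal((R, L))
        z = mu + var.sqrt() * Tensor(eps)

        n_anchors = int(sum(T_list))

        # -- KL against the autoregressive prior --------------------------
        first = rtau == 1
        later = ~first
        kl_sum = Tensor(np.zeros(()))
        p_init = self.prior_init(U)                  # (B, 2L)
        mu_p1 = p_init[:, :L][rb[first]]
        var_p1 = (p_init[:, L:].softplus() + _VAR_FLOOR)[rb[first]]
        kl_sum = kl_sum + self._kl_rows(mu[first], var[first], mu_p1, var_p1)
        if later.any():
            idx_later = np.flatnonzero(later)
            z_prev = z[idx_later - 1]                # row order: tau contiguous
            pt = self.prior_trans(concat([z_prev, u_rows[idx_later]], axis=1))
            mu_pt = pt[:, :L]
            var_pt = pt[:, L:].softplus() + _VAR_FLOOR
            kl_sum = kl_sum + self._kl_rows(mu[later], var[later],
                                            mu_pt, var_pt)
        # normalized per latent dim and visit so the KL is on the same
        # per-unit scale as the entry-averaged likelihood terms
        kl_mean = kl_sum / float(R * L)

        # -- reconstruction of x_{1:t} -------------------------------------
        tvals = np.concatenate(
            [np.repeat(p.t_val[None], p.T, axis=0).reshape(-1, p.t_val.shape[1])
             for p in pats])             # row (b,t,tau) -> t_val[b, tau-1]
        tobs_src = [p.t_obs if target_obs is None else target_obs[b]
                    for b, p in enumerate(pats)]
        tobs = np.concatenate(
            [np.repeat(o[None], T, axis=0).reshape(-1, o.shape[1])
             for o, T in zip(tobs_src, T_list)])
        det: dict | None = {} if details else None

        rec_rows = np.flatnonzero(rtau <= rt)
        z_rec = z[rec_rows]
        dec = self.decoder(z_rec)
        recon_sum, recon_cnt, rec_entry = self._recon_terms(
            dec, tvals[rec_rows], tobs[rec_rows], details)
        if det is not None:
            det["recon_rows"] = np.stack(
                [rb[rec_rows], rt[rec_rows], rtau[rec_rows]], axis=1)
            det["recon_entry"] = rec_entry

        # -- guidance on g_{t:T} -------------------------------------------
        gd_rows = np.flatnonzero(rtau >= rt)
        if cfg.w_guide != 0.0:
            z_gd = z[gd_rows]
            guide_sum, guide_cnt, gd_entry = self._guidance_terms(
                z_gd, tvals[gd_rows], tobs[gd_rows], details)
            if det is not None:
                det["guide_rows"] = np.stack(
                    [rb[gd_rows], rt[gd_rows], rtau[gd_rows]], axis=1)
                det["guide_entry"] = gd_entry
        else:
            guide_sum, guide_cnt = Tensor(np.zeros(())), 0

        recon = recon_sum / max(recon_cnt, 1)
        guide = guide_sum / max(guide_cnt, 1)
        total = (cfg.w_recon * recon + cfg.w_guide * guide
                 + cfg.w_kl * kl_weight * kl_mean)
        breakdown = LossBreakdown(
            recon_x=float(recon.data), guide_g=float(guide.data),
            kl=float(kl_mean.data), total=float(total.data),
            n_recon_targets=int(recon_cnt), n_guide_targets=int(guide_cnt),
            details=det)
        return breakdown, (total if build_graph else None)

    @staticmethod
    def _kl_rows(mu_q, var_q, mu_p, var_p) -> Tensor:
        d = mu_q - mu_p
        kl = (var_p.log() - var_q.log() - 1.0
              + (var_q + d.square()) / var_p) * 0.5
        return kl.sum()

    def _recon_terms(self, dec: Tensor, tvals, tobs, details):
        """Masked per-entry likelihood terms for the input decoder."""
        total = Tensor(np.zeros(()))
        count = 0
        entry_store = {} if details else None
        for (is_cont, w), var_idx in self._groups.items():
            cols = np.concatenate(
                [np.arange(self.layout.col_slices[j].start,
                           self.layout.col_slices[j].stop)
                 for j in var_idx])
            mask = tobs[:, var_idx].astype(float)
            count += int(mask.sum())
            if is_cont:
                target = np.nan_to_num(tvals[:, var_idx])
                pred = dec[:, cols]
                # constant-variance Gaussian likelihood: NLL ∝ squared error
                entry = (pred - Tensor(target)).square() * Tensor(mask)
                entry = entry / self.config.recon_variance
            else:
                n_g = len(var_idx)
                logits = dec[:, cols].reshape(dec.shape[0], n_g, w)
                logp = logits.log_softmax(axis=-1)
                lev = np.nan_to_num(tvals[:, var_idx]).astype(int)
                onehot = np.zeros((dec.shape[0], n_g, w))
                rows = np.repeat(np.arange(dec.shape[0]), n_g)
                onehot[rows, np.tile(np.arange(n_g), dec.shape[0]),
                       lev.ravel()] = 1.0
                entry = -(logp * Tensor(onehot)).sum(axis=-1) * Tensor(mask)
            total = total + entry.sum()
            if entry_store is not None:
                entry_store[(is_cont, w)] = (var_idx, entry.data.copy())
        return total, count, entry_store

    def _guidance_terms(self, z_gd: Tensor, tvals, tobs, details):
        total = Tensor(np.zeros(()))
        count = 0
        entry_store = {} if details else None
        for g_pos, spec in enumerate(self.layout.guided_specs):
            j = self.layout.guided_idx[g_pos]
            block = z_gd[:, self.partition.organ_slice(spec.organ)]
            out = self.guidance[spec.name](block)
            mask = tobs[:, j].astype(float)
            count += int(mask.sum())
            if spec.kind == "continuous":
                target = np.nan_to_num(tvals[:, j])
                entry = (out[:, 0] - Tensor(target)).square() * Tensor(mask)
            else:
                logp = out.log_softmax(axis=-1)
                lev = np.nan_to_num(tvals[:, j]).astype(int)
                onehot = np.zeros((out.shape[0], spec.levels))
                onehot[np.arange(out.shape[0]), lev] = 1.0
                entry = -(logp * Tensor(onehot)).sum(axis=-1) * Tensor(mask)
            total = total + entry.sum()
            if entry_store is not None:
                entry_store[spec.name] = entry.data.copy()
        return total, count, entry_store

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        """Single-archive checkpoint: parameters + config + schema hash."""
        meta = {
            "config": asdict(self.config),
            "schema": self.layout.schema.to_dict(),
            "schema_hash": self.layout.schema.content_hash(),
            "stats": self.stats.to_dict() if self.stats else None,
            "loss_history": self.loss_history,
        }
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path, expect_schema: CohortSchema | None = None
             ) -> "GuidedTemporalVAE":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            arrays = [data[f"p{i}"] for i in range(len(data.files) - 1)]
        schema = CohortSchema.from_dict(meta["schema"])
        if expect_schema is not None and \
                expect_schema.content_hash() != meta["schema_hash"]:
            raise ValueError("checkpoint schema hash does not match the "
                             "requested schema")
        if meta["stats"] is None:
            raise ValueError("checkpoint lacks normalization statistics")
        stats = NormalizationStats.from_dict(meta["stats"])
        layout = build_layout(schema, stats)
        model = cls(layout, ModelConfig(**meta["config"]), stats)
        model.loss_history = meta["loss_history"]
        params = model.parameters()
        for p, a in zip(params, arrays):
            p.data = a.astype(np.float64)
        return model


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(cohort: EncodedCohort, config: ModelConfig,
          log_path=None, verbose: bool = False) -> GuidedTemporalVAE:
    """Fit the model with Adam over mini-batches of patients.

    Feature masking is re-drawn per batch per epoch; the KL weight is
    annealed linearly over the first ``kl_anneal_frac`` of epochs; per-epoch
    recon/guide/KL averages are recorded in ``model.loss_history``.
    Divergence (non-finite loss) aborts with a diagnostic.
    """
    if len(cohort) == 0:
        raise ValueError("empty training cohort")
    model = GuidedTemporalVAE(cohort.layout, config, cohort.stats)
    params = model.parameters(include_guidance=config.w_guide != 0.0)
    opt = Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    pats = list(cohort.patients)
    anneal_epochs = max(int(np.ceil(config.kl_anneal_frac * config.epochs)), 1)

    for epoch in range(config.epochs):
        order = rng.permutation(len(pats))
        kl_w = min(1.0, (epoch + 1) / anneal_epochs) \
            if config.kl_anneal_frac > 0 else 1.0
        ep = {"total": 0.0, "recon": 0.0, "guide": 0.0, "kl": 0.0, "n": 0}
        for start in range(0, len(pats), config.batch_size):
            batch = [pats[i] for i in order[start:start + config.batch_size]]
            if config.feature_mask_rate > 0:
                inputs = []
                for p in batch:
                    x2, m2, _ = apply_feature_masking(
                        p.x, p.m, p.t_obs, config.feature_mask_rate, rng,
                        cohort.layout)
                    inputs.append((x2, m2))
            else:
                inputs = None
            breakdown, total = model.loss(batch, rng, kl_weight=kl_w,
                                          inputs=inputs)
            if not np.isfinite(breakdown.total):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: "
                    f"total={breakdown.total}, kl={breakdown.kl}")
            opt.zero_grad()
            total.backward()
            opt.step()
            ep["total"] += breakdown.total * len(batch)
            ep["recon"] += breakdown.recon_x * len(batch)
            ep["guide"] += breakdown.guide_g * len(batch)
            ep["kl"] += breakdown.kl * len(batch)
            ep["n"] += len(batch)
        rec = {k: ep[k] / ep["n"] for k in ("total", "recon", "guide", "kl")}
        rec["epoch"] = epoch
        rec["kl_weight"] = kl_w
        model.loss_history.append(rec)
        if verbose:
            print(f"epoch {epoch:3d}  total {rec['total']:.4f}  "
                  f"recon {rec['recon']:.4f}  guide {rec['guide']:.4f}  "
                  f"kl {rec['kl']:.4f}")
    if log_path is not None:
        with open(log_path, "w") as fh:
            fh.write("epoch\ttotal\trecon\tguide\tkl\tkl_weight\n")
            for rec in model.loss_history:
                fh.write(f"{rec['epoch']}\t{rec['total']:.6f}\t"
                         f"{rec['recon']:.6f}\t{rec['guide']:.6f}\t"
                         f"{rec['kl']:.6f}\t{rec['kl_weight']:.3f}\n")
    return model


def validation_loss(model: GuidedTemporalVAE, cohort: EncodedCohort) -> float:
    """Objective on held-out patients: no feature masking, full KL weight,
    deterministic sampling seed."""
    breakdown, _ = model.loss(list(cohort.patients),
                              rng=np.random.default_rng(0),
                              build_graph=False)
    return breakdown.total


def hyperparameter_search(cohort: EncodedCohort, plan: SplitPlan,
                          space: dict, n_trials: int, seed: int = 0,
                          base_config: ModelConfig | None = None,
                          max_folds: int | None = None):
    """Random search over ``space`` (field -> candidate list), scored by the
    fold-averaged validation loss; returns (best ModelConfig, trial records).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    base = asdict(base_config) if base_config else asdict(ModelConfig())
    folds = plan.folds[:max_folds] if max_folds else plan.folds
    records = []
    for trial in range(n_trials):
        cfg_dict = dict(base)
        for key, choices in space.items():
            cfg_dict[key] = choices[int(rng.integers(len(choices)))]
        cfg_dict["seed"] = int(rng.integers(2**31 - 1))
        cfg = ModelConfig(**cfg_dict)
        fold_losses = []
        for fold_ids in folds:
            val = cohort.subset(fold_ids)
            train_ids = [pid for pid in plan.train_ids
                         if pid not in set(fold_ids)]
            model = train(cohort.subset(train_ids), cfg)
            fold_losses.append(validation_loss(model, val))
        records.append({"trial": trial, "config": cfg,
                        "fold_losses": fold_losses,
                        "val_loss": float(np.mean(fold_losses))})
    best = min(records, key=lambda r: r["val_loss"])
    return best["config"], records
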