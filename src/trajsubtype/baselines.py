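"""Comparison predictors sharing the guided model's prediction interface.

Every predictor implements ``predict_labels(patient, anchor, inputs=None)``
returning, per guided variable, the predicted sequence for visits
anchor..T: a (T-anchor+1,) array of means for continuous variables or a
(T-anchor+1, n_levels) array of class probabilities otherwise — the same
convention as :meth:`GuidedTemporalVAE.predict_labels`, so the evaluation
suite is model-agnostic.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor
from ._nn import MLP, Adam
from .preprocess import EncodedCohort, EncodedPatient, EncodingLayout


def _onehot_prob(level: int, width: int) -> np.ndarray:
    out = np.zeros(width)
    out[level] = 1.0
    return out


class CohortMean:
    """Predicts the training mean (continuous) or the training class
    frequencies (categorical) regardless of the patient — by construction
    its classification score equals the always-majority classifier's."""

    def __init__(self, layout: EncodingLayout, stats):
        self.layout = layout
        self.stats = stats

    def predict_labels(self, patient: EncodedPatient, anchor: int,
                       inputs=None) -> dict:
        horizon = patient.T - anchor + 1
        out = {}
        for spec in self.layout.guided_specs:
            if spec.kind == "continuous":
                # targets are standardized, so the train mean is 0
                out[spec.name] = np.zeros(horizon)
            else:
                probs = np.asarray(self.stats.freqs[spec.name], float)
                out[spec.name] = np.tile(probs, (horizon, 1))
        return out


class CarryForward:
    """Patient-specific heuristic: the future equals the most recent
    observed value at or before the anchor; falls back to the cohort mean
    (or modal class) when the variable was never observed."""

    def __init__(self, layout: EncodingLayout, stats):
        self.layout = layout
        self.stats = stats

    def predict_labels(self, patient: EncodedPatient, anchor: int,
                       inputs=None) -> dict:
        horizon = patient.T - anchor + 1
        out = {}
        obs_mask = patient.t_obs if inputs is None else inputs
        for g_pos, spec in enumerate(self.layout.guided_specs):
            j = self.layout.guided_idx[g_pos]
            seen = np.flatnonzero(obs_mask[:anchor, j])
            if spec.kind == "continuous":
                val = patient.t_val[seen[-1], j] if len(seen) else 0.0
                out[spec.name] = np.full(horizon, val)
            else:
                if len(seen):
                    level = int(patient.t_val[seen[-1], j])
                    probs = _onehot_prob(level, spec.levels)
                else:
                    probs = np.asarray(self.stats.freqs[spec.name], float)
                out[spec.name] = np.tile(probs, (horizon, 1))
        return out


class MLPBaseline:
    """Non-temporal network: most recent visit only, no recurrent state.

    Input is (x_t, m_t, s, one-hot horizon); one network serves every
    prediction horizon.  Editing earlier visits cannot change its output.
    """

    def __init__(self, layout: EncodingLayout, hidden: int = 64,
                 max_T: int = 14, include_time: bool = True,
                 seed: int = 0):
        self.layout = layout
        self.max_T = max_T
        self.include_time = include_time
        rng = np.random.default_rng(seed)
        n_in = 2 * layout.D_enc + max(layout.S_enc, 1) + max_T \
            + (1 if include_time else 0)
        self._heads: list[tuple[str, slice]] = []
        off = 0
        for spec in layout.guided_specs:
            w = 1 if spec.kind == "continuous" else spec.levels
            self._heads.append((spec.name, slice(off, off + w)))
            off += w
        self.net = MLP(n_in, [hidden, hidden], off, rng)
        self.loss_history: list[float] = []

    def _features(self, x_t, m_t, s, horizon: int, time_val: float
                  ) -> np.ndarray:
        hvec = np.zeros(self.max_T)
        hvec[min(horizon, self.max_T - 1)] = 1.0
        parts = [x_t, m_t.astype(float), s if s.size else np.zeros(1), hvec]
        if self.include_time:
            parts.append(np.array([time_val / 10.0]))
        return np.concatenate(parts)

    def _batch_rows(self, pats: list[EncodedPatient], inputs=None):
        feats, targ, tobs = [], [], []
        for b, p in enumerate(pats):
            x, m = (p.x, p.m) if inputs is None else inputs[b]
            for t in range(1, p.T + 1):
                for tau in range(t, p.T + 1):
                    feats.append(self._features(
                        x[t - 1], m[t - 1], p.s, tau - t, p.times[t - 1]))
                    targ.append(p.t_val[tau - 1, self.layout.guided_idx])
                    tobs.append(p.t_obs[tau - 1, self.layout.guided_idx])
        return (np.stack(feats), np.stack(targ), np.stack(tobs))

    def _loss(self, feats, targ, tobs):
        out = self.net(Tensor(feats))
        total = Tensor(np.zeros(()))
        count = 0
        for g_pos, spec in enumerate(self.layout.guided_specs):
            name, sl = self._heads[g_pos]
            mask = tobs[:, g_pos].astype(float)
            count += int(mask.sum())
            if spec.kind == "continuous":
                target = np.nan_to_num(targ[:, g_pos])
                entry = (out[:, sl.start] - Tensor(target)).square() \
                    * Tensor(mask)
            else:
                logp = out[:, sl].log_softmax(axis=-1)
                lev = np.nan_to_num(targ[:, g_pos]).astype(int)
                onehot = np.zeros((feats.shape[0], spec.levels))
                onehot[np.arange(feats.shape[0]), lev] = 1.0
                entry = -(logp * Tensor(onehot)).sum(axis=-1) * Tensor(mask)
            total = total + entry.sum()
        return total / max(count, 1)

    def fit(self, cohort: EncodedCohort, epochs: int = 30,
            batch_size: int = 512, lr: float = 3e-3, seed: int = 0
            ) -> "MLPBaseline":
        feats, targ, tobs = self._batch_rows(list(cohort.patients))
        opt = Adam(self.net.parameters(), lr=lr)
        rng = np.random.default_rng(seed)
        n = feats.shape[0]
        for _epoch in range(epochs):
            order = rng.permutation(n)
            ep_loss, nb = 0.0, 0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                loss = self._loss(feats[idx], targ[idx], tobs[idx])
                if not np.isfinite(loss.data):
                    raise FloatingPointError("MLP baseline diverged")
                opt.zero_grad()
                loss.backward()
                opt.step()
                ep_loss += float(loss.data)
                nb += 1
            self.loss_history.append(ep_loss / max(nb, 1))
        return self

    def predict_labels(self, patient: EncodedPatient, anchor: int,
                       inputs=None) -> dict:
        x, m = (patient.x, patient.m) if inputs is None else inputs
        feats = np.stack([
            self._features(x[anchor - 1], m[anchor - 1], patient.s,
                           tau - anchor, patient.times[anchor - 1])
            for tau in range(anchor, patient.T + 1)])
        out = self.net(Tensor(feats)).data
        result = {}
        for g_pos, spec in enumerate(self.layout.guided_specs):
            name, sl = self._heads[g_pos]
            block = out[:, sl]
            if spec.kind == "continuous":
                result[name] = block[:, 0]
            else:
                e = np.exp(block - block.max(axis=1, keepdims=True))
                result[name] = e / e.sum(axis=1, keepdims=True)
        return result
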