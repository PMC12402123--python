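"""Guided temporal VAE: posteriors, prior, KL, sampling, decoders,
feature masking, the observed-only loss and training behaviour."""

import numpy as np
import pytest

import trajsubtype as ts
from trajsubtype.model import (GaussianSequence, GuidedTemporalVAE,
                               LatentPartition, ModelConfig,
                               apply_feature_masking, hyperparameter_search,
                               kl_term, sample, train, validation_loss)
from trajsubtype.schema import ORGANS


class TestLatentPartition:
    def test_blocks_disjoint_and_cover(self):
        part = LatentPartition(per_organ=2)
        seen = []
        for organ in ORGANS:
            sl = part.organ_slice(organ)
            seen.extend(range(sl.start, sl.stop))
        assert sorted(seen) == list(range(part.L))


class TestGaussianSequence:
    def test_rejects_bad_variances(self):
        with pytest.raises(ValueError):
            GaussianSequence(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(ValueError):
            GaussianSequence(np.zeros((2, 3)), -np.ones((2, 3)))


class TestKL:
    def test_identity_is_zero(self):
        q = GaussianSequence(np.ones((3, 4)), np.full((3, 4), 0.5))
        assert kl_term(q, q) == 0.0

    def test_unit_gaussian_closed_form(self):
        # KL(N(1,1) || N(0,1)) = 0.5 for a single dimension
        q = GaussianSequence([[1.0]], [[1.0]])
        p = GaussianSequence([[0.0]], [[1.0]])
        assert kl_term(q, p) == pytest.approx(0.5)

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(0)
        n = 100_000
        for _ in range(20):
            mq = rng.normal(size=(2, 2))
            vq = rng.uniform(0.3, 2.0, size=(2, 2))
            mp = rng.normal(size=(2, 2))
            vp = rng.uniform(0.3, 2.0, size=(2, 2))
            q = GaussianSequence(mq, vq)
            p = GaussianSequence(mp, vp)
            z = mq[None] + np.sqrt(vq)[None] * rng.standard_normal(
                (n, 2, 2))
            log_ratio = (-0.5 * np.log(2 * np.pi * vq)
                         - (z - mq) ** 2 / (2 * vq)
                         + 0.5 * np.log(2 * np.pi * vp)
                         + (z - mp) ** 2 / (2 * vp))
            samples = log_ratio.sum(axis=(1, 2))
            se = samples.std(ddof=1) / np.sqrt(n)
            assert abs(kl_term(q, p) - samples.mean()) < 3 * se


class TestSample:
    def test_zero_variance_returns_mean(self):
        q = GaussianSequence(np.arange(6.0).reshape(2, 3),
                             np.full((2, 3), 1e-30))
        np.testing.assert_allclose(sample(q, 0), q.means, atol=1e-10)

    def test_seeded_determinism(self):
        q = GaussianSequence(np.zeros((3, 4)), np.ones((3, 4)))
        np.testing.assert_array_equal(sample(q, 5), sample(q, 5))
        assert not np.array_equal(sample(q, 5), sample(q, 6))

    def test_sample_mean_clt(self):
        q = GaussianSequence(np.array([[2.0]]), np.array([[0.25]]))
        rng = np.random.default_rng(1)
        draws = np.array([sample(q, rng)[0, 0] for _ in range(10_000)])
        se = 0.5 / np.sqrt(draws.size)
        assert abs(draws.mean() - 2.0) < 3 * se


class TestEncode:
    def test_shapes_determinism_positivity(self, untrained_model,
                                           tiny_encoded):
        enc, _ = tiny_encoded
        p = enc.patients[0]
        q1 = untrained_model.encode(p, anchor=1)
        q2 = untrained_model.encode(p, anchor=1)
        assert q1.means.shape == (untrained_model.partition.L, p.T)
        np.testing.assert_array_equal(q1.means, q2.means)
        assert np.all(q1.variances > 0)
        # full trajectory predicted from a partial history (T > t)
        assert q1.T == p.T

    def test_anchor_out_of_range(self, untrained_model, tiny_encoded):
        enc, _ = tiny_encoded
        p = enc.patients[0]
        with pytest.raises(ValueError):
            untrained_model.encode(p, anchor=p.T + 1)

    def test_embed_many_matches_single(self, untrained_model, tiny_encoded):
        enc, _ = tiny_encoded
        pats = enc.patients[:4]
        batched = untrained_model.embed_many(pats)
        for p, Z in zip(pats, batched):
            np.testing.assert_allclose(Z, untrained_model.embed(p),
                                       atol=1e-10)


class TestPrior:
    def test_zero_weight_network_gives_constant_mean(self, tiny_encoded):
        enc, _ = tiny_encoded
        model = GuidedTemporalVAE(enc.layout, ModelConfig(seed=0),
                                  enc.stats)
        # default init zeroes the Gaussian heads, so the prior mean is the
        # same at every step
        z = np.zeros((model.partition.L, 3))
        p = model.prior(enc.patients[0].s, z_samples=z)
        assert p.means.shape == (model.partition.L, 4)
        assert np.allclose(p.means, p.means[:, :1])

    def test_depends_on_statics(self, untrained_model, tiny_encoded):
        enc, _ = tiny_encoded
        s1 = enc.patients[0].s
        s2 = s1 + 1.0
        p1 = untrained_model.prior(s1, T=1)
        p2 = untrained_model.prior(s2, T=1)
        assert not np.allclose(p1.means, p2.means)

    def test_variances_positive(self, untrained_model, tiny_encoded):
        enc, _ = tiny_encoded
        rng = np.random.default_rng(2)
        z = rng.normal(size=(untrained_model.partition.L, 5))
        p = untrained_model.prior(enc.patients[0].s, z_samples=z)
        assert np.all(p.variances > 0)


class TestDecoders:
    def test_categorical_rows_normalized(self, untrained_model):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(untrained_model.partition.L, 4))
        out = untrained_model.decode_inputs(z)
        schema = untrained_model.layout.schema
        for v in schema.temporal:
            if v.kind != "continuous":
                np.testing.assert_allclose(out[v.name].sum(axis=1), 1.0,
                                           atol=1e-6)
                assert np.all(out[v.name] > 0) and np.all(out[v.name] < 1)

    def test_outputs_respond_to_latents(self, untrained_model):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(untrained_model.partition.L, 3))
        a = untrained_model.decode_inputs(z)
        b = untrained_model.decode_inputs(z + 0.5)
        changed = [k for k in a if not np.allclose(a[k], b[k])]
        assert changed


class TestGuidanceIsolation:
    def test_outside_perturbation_bit_identical(self, untrained_model):
        model = untrained_model
        rng = np.random.default_rng(5)
        z = rng.normal(size=(model.partition.L, 4))
        for spec in model.layout.guided_specs:
            sl = model.partition.organ_slice(spec.organ)
            base = model.guidance_predict(z, spec.name)
            z_out = z.copy()
            outside = np.ones(model.partition.L, bool)
            outside[sl] = False
            z_out[outside] += rng.normal(size=(outside.sum(), 4))
            np.testing.assert_array_equal(
                base, model.guidance_predict(z_out, spec.name))

    def test_inside_perturbation_changes_output(self, untrained_model):
        model = untrained_model
        rng = np.random.default_rng(6)
        z = rng.normal(size=(model.partition.L, 4))
        for spec in model.layout.guided_specs:
            sl = model.partition.organ_slice(spec.organ)
            base = model.guidance_predict(z, spec.name)
            z_in = z.copy()
            z_in[sl] += 1.0
            assert not np.array_equal(
                base, model.guidance_predict(z_in, spec.name))

    def test_unknown_variable_raises(self, untrained_model):
        z = np.zeros((untrained_model.partition.L, 2))
        with pytest.raises(KeyError):
            untrained_model.guidance_predict(z, "not_a_label")

    def test_probabilities_in_open_interval(self, untrained_model):
        rng = np.random.default_rng(7)
        z = rng.normal(size=(untrained_model.partition.L, 5))
        for spec in untrained_model.layout.guided_specs:
            probs = untrained_model.guidance_predict(z, spec.name)
            assert np.all(probs > 0) and np.all(probs < 1)


class TestFeatureMasking:
    def test_rate_zero_is_identity(self, tiny_encoded):
        enc, _ = tiny_encoded
        p = enc.patients[0]
        rng = np.random.default_rng(0)
        x2, m2, hidden = apply_feature_masking(p.x, p.m, p.t_obs, 0.0, rng,
                                               enc.layout)
        np.testing.assert_array_equal(x2, p.x)
        np.testing.assert_array_equal(m2, p.m)
        assert not hidden.any()

    def test_exact_count_and_missing_untouched(self, tiny_encoded):
        enc, _ = tiny_encoded
        p = enc.patients[0]
        rng = np.random.default_rng(1)
        n_obs = int(p.t_obs.sum())
        x2, m2, hidden = apply_feature_masking(p.x, p.m, p.t_obs, 0.2, rng,
                                               enc.layout)
        assert hidden.sum() == round(0.2 * n_obs)
        assert not (hidden & ~p.t_obs).any()
        # total observedness after masking
        remaining = (p.t_obs & ~hidden).sum()
        assert remaining == n_obs - round(0.2 * n_obs)

    def test_hidden_entries_hold_training_placeholder(self, tiny_encoded):
        enc, _ = tiny_encoded
        p = enc.patients[0]
        rng = np.random.default_rng(2)
        x2, m2, hidden = apply_feature_masking(p.x, p.m, p.t_obs, 0.3, rng,
                                               enc.layout)
        for i, j in np.argwhere(hidden):
            sl = enc.layout.col_slices[j]
            np.testing.assert_allclose(x2[i, sl], enc.layout.placeholder[sl])
            assert not m2[i, sl].any()


class TestLoss:
    def test_fully_unobserved_variable_contributes_zero(self, tiny_encoded,
                                                        untrained_model):
        enc, _ = tiny_encoded
        p = enc.patients[0]
        j = 0                       # first temporal variable
        t_obs = p.t_obs.copy()
        t_obs[:, j] = False
        bd, _ = untrained_model.loss([p], rng=0, target_obs=[t_obs],
                                     details=True)
        var_entries = []
        for (is_cont, w), (var_idx, entries) in bd.details[
                "recon_entry"].items():
            if j in var_idx:
                var_entries.append(entries[:, var_idx.index(j)])
        assert all(np.all(e == 0.0) for e in var_entries)

    def test_observed_only_invariant_exact(self, tiny_encoded,
                                           untrained_model):
        """Flipping one target entry's observedness zeroes exactly its own
        contributions and leaves every other per-entry term unchanged."""
        enc, _ = tiny_encoded
        model = untrained_model
        p = enc.patients[0]
        i, j = map(int, np.argwhere(p.t_obs)[5])
        # keep the encoder input fixed: hide the entry from the input in
        # both runs, toggle only the target mask
        x2, m2 = p.x.copy(), p.m.copy()
        sl = enc.layout.col_slices[j]
        x2[i, sl] = enc.layout.placeholder[sl]
        m2[i, sl] = False
        t_obs_off = p.t_obs.copy()
        t_obs_off[i, j] = False
        bd_on, _ = model.loss([p], rng=0, inputs=[(x2, m2)], details=True)
        bd_off, _ = model.loss([p], rng=0, inputs=[(x2, m2)],
                               target_obs=[t_obs_off], details=True)
        # identical sampling: compare per-entry arrays
        for key in bd_on.details["recon_entry"]:
            var_idx, e_on = bd_on.details["recon_entry"][key]
            _, e_off = bd_off.details["recon_entry"][key]
            rows = bd_on.details["recon_rows"]
            for pos, vj in enumerate(var_idx):
                mask_this = (rows[:, 2] == i + 1) & (vj == j)
                np.testing.assert_array_equal(
                    e_on[:, pos][~mask_this], e_off[:, pos][~mask_this])
                if vj == j:
                    assert np.all(e_off[:, pos][mask_this] == 0.0)
        g_rows = bd_on.details["guide_rows"]
        for name in bd_on.details["guide_entry"]:
            e_on = bd_on.details["guide_entry"][name]
            e_off = bd_off.details["guide_entry"][name]
            spec_j = enc.layout.guided_idx[
                [s.name for s in enc.layout.guided_specs].index(name)]
            mask_this = (g_rows[:, 2] == i + 1) & (spec_j == j)
            np.testing.assert_array_equal(e_on[~mask_this],
                                          e_off[~mask_this])
            if spec_j == j:
                assert np.all(e_off[mask_this] == 0.0)
        assert bd_off.n_recon_targets < bd_on.n_recon_targets

    def test_loss_matches_public_primitive_composition(self, tiny_encoded):
        """Independent oracle: recompute the objective for one patient from
        the public encode/prior/decode/guidance operations and the same
        noise draw."""
        enc, _ = tiny_encoded
        cfg = ModelConfig(seed=1, feature_mask_rate=0.0)
        model = GuidedTemporalVAE(enc.layout, cfg, enc.stats)
        rng = np.random.default_rng(9)
        for head in (model.posterior_head, model.prior_init,
                     model.prior_trans):
            head.layers[-1].W.data[:] = rng.normal(
                0, 0.05, head.layers[-1].W.data.shape)
        p = enc.patients[1]
        T = p.T
        L = model.partition.L
        bd, _ = model.loss([p], rng=np.random.default_rng(42))

        eps = np.random.default_rng(42).standard_normal((T * T, L))
        recon_sum = guide_sum = kl_sum = 0.0
        recon_cnt = guide_cnt = 0
        schema = enc.layout.schema
        g_names = [s.name for s in enc.layout.guided_specs]
        for t in range(1, T + 1):
            q = model.encode(p, anchor=t)
            rows = slice((t - 1) * T, t * T)
            z = (q.means.T + np.sqrt(q.variances.T) * eps[rows]).T  # (L, T)
            prior = model.prior(p.s, z_samples=z[:, :-1])
            kl_sum += kl_term(q, prior)
            dec = model.decode_inputs(z)
            for j, v in enumerate(schema.temporal):
                for tau in range(t):       # reconstruct x_{1:t}
                    if not p.t_obs[tau, j]:
                        continue
                    recon_cnt += 1
                    if v.kind == "continuous":
                        recon_sum += (dec[v.name][tau]
                                      - p.t_val[tau, j]) ** 2
                    else:
                        recon_sum += -np.log(
                            dec[v.name][tau, int(p.t_val[tau, j])])
            for name in g_names:
                j = enc.layout.guided_idx[g_names.index(name)]
                probs = model.guidance_predict(z, name)
                for tau in range(t - 1, T):   # predict g_{t:T}
                    if not p.t_obs[tau, j]:
                        continue
                    guide_cnt += 1
                    guide_sum += -np.log(probs[tau, int(p.t_val[tau, j])])
        expected_recon = recon_sum / recon_cnt
        expected_guide = guide_sum / guide_cnt
        expected_kl = kl_sum / (T * T * L)
        assert bd.recon_x == pytest.approx(expected_recon, rel=1e-8)
        assert bd.guide_g == pytest.approx(expected_guide, rel=1e-8)
        assert bd.kl == pytest.approx(expected_kl, rel=1e-8)
        assert bd.total == pytest.approx(
            cfg.w_recon * expected_recon + cfg.w_guide * expected_guide
            + cfg.w_kl * expected_kl, rel=1e-8)

    def test_empty_batch_raises(self, untrained_model):
        with pytest.raises(ValueError):
            untrained_model.loss([], rng=0)


class TestTraining:
    def test_loss_decreases_and_is_deterministic(self, small_trained,
                                                 tiny_encoded):
        model, enc, plan = small_trained
        hist = model.loss_history
        assert hist[-1]["total"] < hist[0]["total"]
        cfg = ModelConfig(epochs=5, seed=0)
        again = train(enc.subset(plan.train_ids), cfg)
        for p1, p2 in zip(model.parameters(), again.parameters()):
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_guidance_untouched_when_weight_zero(self, tiny_encoded):
        enc, plan = tiny_encoded
        cfg = ModelConfig(epochs=2, seed=0, w_guide=0.0)
        model = train(enc.subset(plan.train_ids), cfg)
        fresh = GuidedTemporalVAE(enc.layout, cfg, enc.stats)
        for name in model.guidance:
            for p1, p2 in zip(model.guidance[name].parameters(),
                              fresh.guidance[name].parameters()):
                np.testing.assert_array_equal(p1.data, p2.data)

    def test_checkpoint_round_trip_and_schema_guard(self, small_trained,
                                                    tmp_path):
        model, enc, _ = small_trained
        path = tmp_path / "model.npz"
        model.save(path)
        back = GuidedTemporalVAE.load(path,
                                      expect_schema=enc.layout.schema)
        p = enc.patients[0]
        np.testing.assert_allclose(back.embed(p), model.embed(p))
        from trajsubtype.schema import CohortSchema, VariableSpec
        other = CohortSchema([
            VariableSpec("x", "continuous", "temporal_input"),
            VariableSpec("g", "binary", "guided_label", organ="skin",
                         label_type="involvement")])
        with pytest.raises(ValueError):
            GuidedTemporalVAE.load(path, expect_schema=other)


class TestInferenceOps:
    def test_impute_identity_on_observed_and_finite(self, small_trained):
        model, enc, _ = small_trained
        p = enc.patients[0]
        out = model.impute(p)
        np.testing.assert_array_equal(out[p.t_obs], p.t_val[p.t_obs])
        assert np.all(np.isfinite(out))
        cont = [j for j, v in enumerate(enc.layout.schema.temporal)
                if v.kind == "continuous"]
        assert np.all(np.abs(out[:, cont]) < 6.0)

    def test_predict_labels_boundary_and_range(self, small_trained):
        model, enc, _ = small_trained
        p = enc.patients[0]
        at_T = model.predict_labels(p, p.T)
        for name, curve in at_T.items():
            assert curve.shape[0] == 1
        full = model.predict_labels(p, 1)
        for name, curve in full.items():
            assert curve.shape[0] == p.T
            assert np.all(curve > 0) and np.all(curve < 1)

    def test_predict_labels_many_matches_single(self, small_trained):
        model, enc, _ = small_trained
        pats = enc.patients[:3]
        sets = [[1, p.T] for p in pats]
        many = model.predict_labels_many(pats, sets)
        for p in pats:
            for t in (1, p.T):
                single = model.predict_labels(p, t)
                for name in single:
                    np.testing.assert_allclose(
                        many[(p.patient_id, t)][name], single[name],
                        atol=1e-10)


class TestHyperparameterSearch:
    def test_single_trial_and_argmin_bookkeeping(self, tiny_encoded):
        enc, plan = tiny_encoded
        space = {"rnn_width": [8, 16], "epochs": [2]}
        best, records = hyperparameter_search(
            enc, plan, space, n_trials=1, seed=0, max_folds=2)
        assert len(records) == 1
        assert best == records[0]["config"]
        best2, records2 = hyperparameter_search(
            enc, plan, space, n_trials=2, seed=1, max_folds=1)
        losses = [r["val_loss"] for r in records2]
        assert min(losses) == [r for r in records2
                               if r["config"] == best2][0]["val_loss"]

    def test_validation_loss_finite(self, small_trained):
        model, enc, plan = small_trained
        val = validation_loss(model, enc.subset(plan.folds[0]))
        assert np.isfinite(val)
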